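"""Pattern-search filter algebra and chained evaluation.

Filters are stateless predicates over a :class:`~genecontext.mapper.GenePanel`.
A chain applies them in order, each stage only to the survivors of the
previous one, records the surviving-gene count per stage, and communicates
the final result by toggling each panel's ``show`` flag — panel data is never
mutated.  Because every filter type is stateless, the surviving set equals
the intersection of the filters applied independently, and is invariant to
filter order (only the trace depends on order).

Conventions (documented because off-by-one choices matter here):

* a peak is "in" a window iff it overlaps it by >= 1 bp (not containment);
* "presence" is count >= 1 and "absence" is count = 0, both expressed via
  :class:`FeatureCountFilter`;
* :func:`interval_gap` of overlapping or abutting half-open intervals is 0,
  so a "near" relation with ``max_distance=0`` means overlapping-or-abutting;
* a gene with no expression value for the queried cell type fails an
  :class:`ExpressionFilter` (missing is not zero).
"""

from __future__ import annotations

import fnmatch
import json
import operator
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .feature_io import TrackKey
from .mapper import GenePanel, RelativeInterval

__all__ = [
    "NameFilter",
    "GeneSizeFilter",
    "ChromFilter",
    "ExpressionFilter",
    "FeatureCountFilter",
    "FeatureOverlapFilter",
    "FilterChain",
    "UnknownTrackError",
    "interval_gap",
    "eval_filter",
    "apply_chain",
    "filter_to_dict",
    "filter_from_dict",
]

OPS = {
    "<": operator.lt,
    "<=": operator.le,
    "=": operator.eq,
    "==": operator.eq,
    ">=": operator.ge,
    ">": operator.gt,
}

RELATIONS = ("near", "a_upstream_of_b", "a_downstream_of_b")


class UnknownTrackError(KeyError):
    """A filter referenced a (cell type, mark) track that was never loaded."""

    def __init__(self, key: TrackKey):
        self.key = key
        super().__init__(f"track not loaded: {key}")


def _check_op(op: str) -> None:
    if op not in OPS:
        raise ValueError(f"unknown comparison operator {op!r}")


def _check_window(window_rel) -> None:
    if window_rel is not None and not window_rel[0] < window_rel[1]:
        raise ValueError("window_rel must satisfy a < b")


@dataclass(frozen=True)
class NameFilter:
    """Match gene id or any alias against an explicit list and/or a glob
    pattern (case-insensitive)."""

    names: tuple[str, ...] = ()
    pattern: str | None = None

    def __post_init__(self):
        if not self.names and self.pattern is None:
            raise ValueError("NameFilter needs names or a pattern")
        object.__setattr__(self, "names", tuple(self.names))


@dataclass(frozen=True)
class GeneSizeFilter:
    op: str = ">="
    bp: int = 0

    def __post_init__(self):
        _check_op(self.op)


@dataclass(frozen=True)
class ChromFilter:
    chroms: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "chroms", tuple(self.chroms))


@dataclass(frozen=True)
class ExpressionFilter:
    cell_type: str = ""
    op: str = ">="
    value: float = 0.0

    def __post_init__(self):
        _check_op(self.op)


@dataclass(frozen=True)
class FeatureCountFilter:
    """Compare the number of (cell_type, mark) peaks overlapping a
    TSS-relative window; ``window_rel=None`` means the whole panel window."""

    cell_type: str = ""
    mark: str = ""
    op: str = ">="
    count: int = 1
    window_rel: tuple[int, int] | None = None

    def __post_init__(self):
        _check_op(self.op)
        if self.count < 0:
            raise ValueError("count must be >= 0")
        _check_window(self.window_rel)
        if self.window_rel is not None:
            object.__setattr__(self, "window_rel", tuple(self.window_rel))


@dataclass(frozen=True)
class FeatureOverlapFilter:
    """Spatial relation between a mark's peaks and a second mark (or the
    gene's exons) inside a TSS-relative window.

    ``relation="near"`` with ``max_distance=0`` detects overlapping or
    abutting pairs — the bivalent-domain query; ``a_upstream_of_b`` /
    ``a_downstream_of_b`` require the ordered juxtaposition with the gap at
    most ``max_distance``.
    """

    cell_type: str = ""
    mark_a: str = ""
    target: str = "exons"  # a second mark name, or the literal "exons"
    relation: str = "near"
    max_distance: int = 0
    window_rel: tuple[int, int] | None = None

    def __post_init__(self):
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if self.max_distance < 0:
            raise ValueError("max_distance must be >= 0")
        _check_window(self.window_rel)
        if self.window_rel is not None:
            object.__setattr__(self, "window_rel", tuple(self.window_rel))


FilterSpec = (
    NameFilter
    | GeneSizeFilter
    | ChromFilter
    | ExpressionFilter
    | FeatureCountFilter
    | FeatureOverlapFilter
)


def interval_gap(a: RelativeInterval, b: RelativeInterval) -> int:
    """Bases strictly between two half-open intervals (0 if they overlap or
    abut): ``max(0, max(starts) - min(ends))``."""
    return max(0, max(a.rel_start, b.rel_start) - min(a.rel_end, b.rel_end))


def _effective_window(
    window_rel: tuple[int, int] | None, panel: GenePanel
) -> tuple[int, int] | None:
    """Intersect the filter window with the panel window; None = empty."""
    lo, hi = panel.window
    if window_rel is not None:
        lo, hi = max(lo, window_rel[0]), min(hi, window_rel[1])
    if lo >= hi:
        return None
    return (lo, hi)


def _track(panel: GenePanel, cell_type: str, mark: str) -> list[RelativeInterval]:
    key = TrackKey(cell_type, mark)
    try:
        return panel.tracks[key]
    except KeyError:
        raise UnknownTrackError(key) from None


def _in_window(
    ivs: list[RelativeInterval], window: tuple[int, int]
) -> list[RelativeInterval]:
    lo, hi = window
    return [iv for iv in ivs if iv.rel_start < hi and iv.rel_end > lo]


def eval_filter(f: FilterSpec, panel: GenePanel) -> bool:
    """Evaluate one filter on one panel.  Raises
    :class:`UnknownTrackError` when a referenced track was never loaded."""
    gene = panel.gene
    if isinstance(f, NameFilter):
        ids = [s.lower() for s in gene.all_ids()]
        if any(n.lower() in ids for n in f.names):
            return True
        if f.pattern is not None:
            return any(fnmatch.fnmatch(i, f.pattern.lower()) for i in ids)
        return False
    if isinstance(f, GeneSizeFilter):
        return OPS[f.op](gene.length, f.bp)
    if isinstance(f, ChromFilter):
        return gene.chrom in f.chroms
    if isinstance(f, ExpressionFilter):
        v = panel.expression.get(f.cell_type)
        return v is not None and OPS[f.op](v, f.value)
    if isinstance(f, FeatureCountFilter):
        track = _track(panel, f.cell_type, f.mark)
        window = _effective_window(f.window_rel, panel)
        n = 0 if window is None else len(_in_window(track, window))
        return OPS[f.op](n, f.count)
    if isinstance(f, FeatureOverlapFilter):
        window = _effective_window(f.window_rel, panel)
        if window is None:
            return False
        a_ivs = _in_window(_track(panel, f.cell_type, f.mark_a), window)
        if f.target == "exons":
            b_all = panel.exons_rel
        else:
            b_all = _track(panel, f.cell_type, f.target)
        b_ivs = _in_window(b_all, window)
        for p in a_ivs:
            for q in b_ivs:
                if f.relation == "near":
                    if interval_gap(p, q) <= f.max_distance:
                        return True
                elif f.relation == "a_upstream_of_b":
                    if p.rel_end <= q.rel_start and q.rel_start - p.rel_end <= f.max_distance:
                        return True
                else:  # a_downstream_of_b
                    if q.rel_end <= p.rel_start and p.rel_start - q.rel_end <= f.max_distance:
                        return True
        return False
    raise TypeError(f"not a filter spec: {type(f).__name__}")


@dataclass
class FilterChain:
    """Ordered filters plus the per-stage surviving-gene trace of the last
    application (non-increasing; same length as ``filters``)."""

    filters: list[FilterSpec] = field(default_factory=list)
    trace: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.filters)


def apply_chain(
    chain: FilterChain, panels: list[GenePanel]
) -> tuple[list[GenePanel], list[int]]:
    """Apply the chain stage by stage, each filter evaluated only on the
    survivors of the previous one.

    Sets ``show`` True on survivors and False on everything else, records
    the per-stage survivor counts into ``chain.trace``, and returns
    ``(surviving_panels, trace)``.  An empty chain keeps every panel.
    """
    survivors = list(panels)
    trace: list[int] = []
    for f in chain.filters:
        survivors = [p for p in survivors if eval_filter(f, p)]
        trace.append(len(survivors))
    surviving_ids = {id(p) for p in survivors}
    for p in panels:
        p.show = id(p) in surviving_ids
    chain.trace = trace
    return survivors, trace


# --- JSON (de)serialization -------------------------------------------------

_TYPE_TAGS = {
    NameFilter: "name",
    GeneSizeFilter: "gene_size",
    ChromFilter: "chrom",
    ExpressionFilter: "expression",
    FeatureCountFilter: "feature_count",
    FeatureOverlapFilter: "feature_overlap",
}
_TAG_TYPES = {v: k for k, v in _TYPE_TAGS.items()}


def filter_to_dict(f: FilterSpec) -> dict:
    d = asdict(f)
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
    d["type"] = _TYPE_TAGS[type(f)]
    return d


def filter_from_dict(d: dict) -> FilterSpec:
    d = dict(d)
    tag = d.pop("type", None)
    if tag not in _TAG_TYPES:
        raise ValueError(f"unknown filter type {tag!r}")
    cls = _TAG_TYPES[tag]
    for k in ("names", "chroms"):
        if k in d and d[k] is not None:
            d[k] = tuple(d[k])
    if d.get("window_rel") is not None:
        d["window_rel"] = tuple(d["window_rel"])
    return cls(**d)


def chain_to_json(chain: FilterChain) -> str:
    return json.dumps([filter_to_dict(f) for f in chain.filters], indent=2)


def chain_from_json(text: str) -> FilterChain:
    data = json.loads(text)
    if not isinstance(data, list):
        raise ValueError("filter chain document must be a JSON array")
    return FilterChain(filters=[filter_from_dict(d) for d in data])


def load_chain(path: str | Path) -> FilterChain:
    return chain_from_json(Path(path).read_text())


def save_chain(chain: FilterChain, path: str | Path) -> None:
    Path(path).write_text(chain_to_json(chain) + "\n")
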