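"""Self-contained session serialization plus text and SVG exports.

A session file carries everything needed to re-open an analysis without any
of the original input files: the settings, every gene panel with its mapped
TSS-relative tracks, expression, neighbors and exons, the filter chain with
its trace, and a provenance-only file manifest.  JSON output is canonical —
sorted keys, compact separators, shortest round-tripping floats — so that
save -> load -> save is byte-identical.

The on-disk schema is documented in ``docs/session_schema.json`` in the
repository; :func:`validate_session` checks incoming documents structurally
and reports every failing JSON path.
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

from .annotation import GeneModel
from .feature_io import TrackKey
from .mapper import GenePanel, RelativeInterval, Settings
from .pattern_search import FilterChain, filter_from_dict, filter_to_dict

__all__ = [
    "SessionState",
    "SessionSchemaError",
    "UnsupportedVersionError",
    "FORMAT_VERSION",
    "save_session",
    "load_session",
    "validate_session",
    "export_summary",
    "parse_summary_gene_list",
    "export_svg",
]

FORMAT_VERSION = "1.0.0"

#: opacity range for peak bars: scores map linearly onto [floor, 1.0]
OPACITY_FLOOR = 0.3

_MARK_COLORS = [
    "#1b9e77", "#d95f02", "#7570b3", "#e7298a",
    "#66a61e", "#e6ab02", "#a6761d", "#666666",
]


class SessionSchemaError(ValueError):
    """Session document failed structural validation; lists failing paths."""

    def __init__(self, paths: list[str]):
        self.paths = paths
        super().__init__("invalid session document: " + "; ".join(paths))


class UnsupportedVersionError(ValueError):
    pass


@dataclass
class SessionState:
    settings: Settings
    panels: list[GenePanel]
    filter_chain: FilterChain = field(default_factory=FilterChain)
    genome_label: str = ""
    file_manifest: list[dict] = field(default_factory=list)
    format_version: str = FORMAT_VERSION


# --- dict <-> dataclass -----------------------------------------------------

def _interval_to_dict(iv: RelativeInterval) -> dict:
    return {
        "rel_start": iv.rel_start,
        "rel_end": iv.rel_end,
        "score": float(iv.score),
        "name": iv.name,
    }


def _interval_from_dict(d: dict) -> RelativeInterval:
    return RelativeInterval(d["rel_start"], d["rel_end"], float(d["score"]), d["name"])


def _gene_to_dict(g: GeneModel) -> dict:
    return {
        "gene_id": g.gene_id,
        "aliases": list(g.aliases),
        "chrom": g.chrom,
        "strand": g.strand,
        "span_start": g.span_start,
        "span_end": g.span_end,
        "exons": [list(e) for e in g.exons],
        "description": g.description,
    }


def _gene_from_dict(d: dict) -> GeneModel:
    return GeneModel(
        gene_id=d["gene_id"],
        aliases=tuple(d["aliases"]),
        chrom=d["chrom"],
        strand=d["strand"],
        span_start=d["span_start"],
        span_end=d["span_end"],
        exons=tuple((s, e) for s, e in d["exons"]),
        description=d["description"],
    )


def _panel_to_dict(p: GenePanel) -> dict:
    return {
        "gene": _gene_to_dict(p.gene),
        "flank_up": p.flank_up,
        "flank_down": p.flank_down,
        "tracks": [
            {
                "cell_type": k.cell_type,
                "mark": k.mark,
                "intervals": [_interval_to_dict(iv) for iv in ivs],
            }
            for k, ivs in sorted(p.tracks.items())
        ],
        "expression": {c: float(v) for c, v in p.expression.items()},
        "neighbors": [
            {"interval": _interval_to_dict(iv), "orientation": o}
            for iv, o in p.neighbors
        ],
        "exons_rel": [_interval_to_dict(iv) for iv in p.exons_rel],
        "show": p.show,
    }


def _panel_from_dict(d: dict) -> GenePanel:
    return GenePanel(
        gene=_gene_from_dict(d["gene"]),
        flank_up=d["flank_up"],
        flank_down=d["flank_down"],
        tracks={
            TrackKey(t["cell_type"], t["mark"]): [
                _interval_from_dict(iv) for iv in t["intervals"]
            ]
            for t in d["tracks"]
        },
        expression=dict(d["expression"]),
        neighbors=[
            (_interval_from_dict(n["interval"]), n["orientation"])
            for n in d["neighbors"]
        ],
        exons_rel=[_interval_from_dict(iv) for iv in d["exons_rel"]],
        show=d["show"],
    )


def _settings_to_dict(s: Settings) -> dict:
    return {
        "flank_up": s.flank_up,
        "flank_down": s.flank_down,
        "min_peak_score": float(s.min_peak_score),
        "min_peak_size": s.min_peak_size,
        # JSON has no infinity; null means "no upper size cutoff"
        "max_peak_size": None if math.isinf(s.max_peak_size) else s.max_peak_size,
        "expr_scale_lo": s.expr_scale_lo,
        "expr_scale_hi": s.expr_scale_hi,
    }


def _settings_from_dict(d: dict) -> Settings:
    return Settings(
        flank_up=d["flank_up"],
        flank_down=d["flank_down"],
        min_peak_score=d["min_peak_score"],
        min_peak_size=d["min_peak_size"],
        max_peak_size=math.inf if d["max_peak_size"] is None else d["max_peak_size"],
        expr_scale_lo=d["expr_scale_lo"],
        expr_scale_hi=d["expr_scale_hi"],
    )


def session_to_dict(state: SessionState) -> dict:
    return {
        "format_version": state.format_version,
        "genome_label": state.genome_label,
        "settings": _settings_to_dict(state.settings),
        "panels": [_panel_to_dict(p) for p in state.panels],
        "filter_chain": {
            "filters": [filter_to_dict(f) for f in state.filter_chain.filters],
            "trace": list(state.filter_chain.trace),
        },
        "file_manifest": state.file_manifest,
    }


def session_from_dict(d: dict) -> SessionState:
    major = str(d["format_version"]).split(".")[0]
    if major != FORMAT_VERSION.split(".")[0]:
        raise UnsupportedVersionError(
            f"session format_version {d['format_version']!r} is not supported "
            f"(this build reads {FORMAT_VERSION.split('.')[0]}.x)"
        )
    return SessionState(
        format_version=d["format_version"],
        genome_label=d["genome_label"],
        settings=_settings_from_dict(d["settings"]),
        panels=[_panel_from_dict(p) for p in d["panels"]],
        filter_chain=FilterChain(
            filters=[filter_from_dict(f) for f in d["filter_chain"]["filters"]],
            trace=list(d["filter_chain"]["trace"]),
        ),
        file_manifest=list(d["file_manifest"]),
    )


# --- structural validation --------------------------------------------------

def _check(errors, cond, path, want):
    if not cond:
        errors.append(f"{path}: expected {want}")


def validate_session(d: object) -> list[str]:
    """Structural validation of a session document; returns the list of
    failing JSON paths (empty when valid)."""
    errors: list[str] = []
    if not isinstance(d, dict):
        return ["$: expected object"]
    for key, typ in (
        ("format_version", str),
        ("genome_label", str),
        ("settings", dict),
        ("panels", list),
        ("filter_chain", dict),
        ("file_manifest", list),
    ):
        if key not in d:
            errors.append(f"$.{key}: missing")
        else:
            _check(errors, isinstance(d[key], typ), f"$.{key}", typ.__name__)
    if errors:
        return errors
    s = d["settings"]
    for key in (
        "flank_up", "flank_down", "min_peak_score", "min_peak_size",
        "max_peak_size", "expr_scale_lo", "expr_scale_hi",
    ):
        if key not in s:
            errors.append(f"$.settings.{key}: missing")
    fc = d["filter_chain"]
    _check(errors, isinstance(fc.get("filters"), list), "$.filter_chain.filters", "array")
    _check(errors, isinstance(fc.get("trace"), list), "$.filter_chain.trace", "array")
    for i, p in enumerate(d["panels"]):
        path = f"$.panels[{i}]"
        if not isinstance(p, dict):
            errors.append(f"{path}: expected object")
            continue
        for key, typ in (
            ("gene", dict), ("flank_up", int), ("flank_down", int),
            ("tracks", list), ("expression", dict), ("neighbors", list),
            ("exons_rel", list), ("show", bool),
        ):
            if key not in p:
                errors.append(f"{path}.{key}: missing")
            else:
                _check(errors, isinstance(p[key], typ), f"{path}.{key}", typ.__name__)
        if isinstance(p.get("gene"), dict):
            for key in ("gene_id", "chrom", "strand", "span_start", "span_end",
                        "exons", "aliases", "description"):
                if key not in p["gene"]:
                    errors.append(f"{path}.gene.{key}: missing")
        for j, t in enumerate(p.get("tracks") or []):
            tp = f"{path}.tracks[{j}]"
            if not isinstance(t, dict):
                errors.append(f"{tp}: expected object")
                continue
            for key in ("cell_type", "mark", "intervals"):
                if key not in t:
                    errors.append(f"{tp}.{key}: missing")
            for k, iv in enumerate(t.get("intervals") or []):
                if not (isinstance(iv, dict)
                        and {"rel_start", "rel_end", "score", "name"} <= iv.keys()):
                    errors.append(f"{tp}.intervals[{k}]: malformed interval")
    return errors


# --- canonical I/O ----------------------------------------------------------

def dumps_canonical(d: dict) -> str:
    return json.dumps(
        d, sort_keys=True, separators=(",", ":"), ensure_ascii=False,
        allow_nan=False,
    ) + "\n"


def save_session(state: SessionState, path: str | Path) -> None:
    """Write the session as canonical JSON (validated before writing)."""
    d = session_to_dict(state)
    errors = validate_session(d)
    if errors:
        raise SessionSchemaError(errors)
    Path(path).write_text(dumps_canonical(d))


def load_session(path: str | Path) -> SessionState:
    """Read and validate a session file.

    Raises :class:`SessionSchemaError` (listing every failing path) on a
    malformed document and :class:`UnsupportedVersionError` on a future
    major format version.
    """
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SessionSchemaError([f"$: not valid JSON ({exc.msg} at line {exc.lineno})"])
    if isinstance(d, dict) and "format_version" in d:
        major = str(d["format_version"]).split(".")[0]
        if major != FORMAT_VERSION.split(".")[0]:
            raise UnsupportedVersionError(
                f"session format_version {d['format_version']!r} is not supported"
            )
    errors = validate_session(d)
    if errors:
        raise SessionSchemaError(errors)
    return session_from_dict(d)


# --- summary text -----------------------------------------------------------

_GENE_LIST_HEADER = "## Surviving genes"
_GENE_LIST_FOOTER = "## End of gene list"


def export_summary(state: SessionState, path: str | Path | None = None) -> str:
    """Human-readable analysis report: inputs, settings, each filter with its
    per-stage survivor count, and the final gene list (machine-parseable via
    :func:`parse_summary_gene_list`)."""
    shown = [p for p in state.panels if p.show]
    lines = [
        "# Analysis summary",
        f"genome: {state.genome_label or '(unlabelled)'}",
        f"genes: {len(state.panels)} loaded, {len(shown)} passing",
        "",
        "## Settings",
        f"flank_up: {state.settings.flank_up} bp",
        f"flank_down: {state.settings.flank_down} bp",
        f"min_peak_score: {state.settings.min_peak_score}",
        f"peak_size: [{state.settings.min_peak_size}, {state.settings.max_peak_size}]",
        "",
        "## Input files",
    ]
    if state.file_manifest:
        for entry in state.file_manifest:
            lines.append(
                f"- {entry.get('path', '?')} "
                f"({entry.get('cell_type', '?')}/{entry.get('mark', entry.get('role', '?'))})"
            )
    else:
        lines.append("- (none recorded)")
    lines += ["", "## Filters"]
    if state.filter_chain.filters:
        trace = state.filter_chain.trace or [None] * len(state.filter_chain.filters)
        for i, (f, n) in enumerate(zip(state.filter_chain.filters, trace), start=1):
            survivors = "?" if n is None else n
            lines.append(f"{i}. {filter_to_dict(f)} -> survivors: {survivors}")
    else:
        lines.append("(no filters; all genes pass)")
    lines += ["", _GENE_LIST_HEADER]
    lines += [p.gene.gene_id for p in shown]
    lines += [_GENE_LIST_FOOTER, ""]
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text


def parse_summary_gene_list(text: str) -> list[str]:
    """Recover the surviving gene IDs from an exported summary."""
    genes: list[str] = []
    in_list = False
    for line in text.splitlines():
        if line.strip() == _GENE_LIST_HEADER:
            in_list = True
            continue
        if line.strip() == _GENE_LIST_FOOTER:
            break
        if in_list and line.strip():
            genes.append(line.strip())
    return genes


# --- SVG export -------------------------------------------------------------

_PANEL_W = 340
_TRACK_H = 10
_GENE_H = 12
_PAD = 14


def _opacity(score: float, smin: float, smax: float) -> float:
    """Linear map of peak score onto [OPACITY_FLOOR, 1.0]; a degenerate
    score range renders fully opaque."""
    if smax <= smin:
        return 1.0
    t = (score - smin) / (smax - smin)
    return round(OPACITY_FLOOR + (1.0 - OPACITY_FLOOR) * min(max(t, 0.0), 1.0), 4)


def _grey(value: float, lo: float, hi: float) -> str:
    if hi <= lo:
        t = 1.0
    else:
        t = min(max((value - lo) / (hi - lo), 0.0), 1.0)
    level = int(round(255 * (1.0 - t)))  # high expression -> dark
    return f"#{level:02x}{level:02x}{level:02x}"


def export_svg(
    panels: list[GenePanel],
    settings: Settings,
    path: str | Path | None = None,
) -> str:
    """Render every shown panel: per gene and cell type, a TSS-anchored scale
    line, the gene as a black bar, neighbors as grey bars offset by relative
    orientation, one colored track per mark with bar opacity a linear
    function of peak score, and an expression swatch on the settings scale.
    Returns the SVG text (and writes it when ``path`` is given)."""
    shown = [p for p in panels if p.show]
    if not shown:
        raise ValueError("no shown panels to render")
    marks = sorted({k.mark for p in shown for k in p.tracks})
    cells = sorted(
        {k.cell_type for p in shown for k in p.tracks}
        | {c for p in shown for c in p.expression}
    )
    colors = {m: _MARK_COLORS[i % len(_MARK_COLORS)] for i, m in enumerate(marks)}
    scores = [iv.score for p in shown for ivs in p.tracks.values() for iv in ivs]
    smin, smax = (min(scores), max(scores)) if scores else (0.0, 0.0)
    expr_vals = [v for p in shown for v in p.expression.values()]
    lo = settings.expr_scale_lo
    hi = settings.expr_scale_hi
    if lo is None or hi is None:
        if expr_vals:
            from .summaries import expression_scale

            auto_lo, auto_hi = expression_scale(expr_vals)
            lo = auto_lo if lo is None else lo
            hi = auto_hi if hi is None else hi
        else:
            lo, hi = 0.0, 1.0

    cell_h = _GENE_H + _TRACK_H * (len(marks) + 1) + 3 * _PAD
    total_w = _PAD + len(cells) * (_PANEL_W + 3 * _PAD)
    total_h = _PAD + len(shown) * cell_h + _PAD

    svg = ET.Element(
        "svg",
        xmlns="http://www.w3.org/2000/svg",
        version="1.1",
        width=str(total_w),
        height=str(total_h),
    )
    for ci, cell in enumerate(cells):
        x0 = _PAD + ci * (_PANEL_W + 3 * _PAD)
        label = ET.SubElement(
            svg, "text", x=str(x0), y=str(_PAD), attrib={"class": "cell-label"}
        )
        label.text = cell

    for gi, panel in enumerate(shown):
        wlo, whi = panel.window
        span = whi - wlo
        y0 = _PAD + gi * cell_h + _PAD
        group = ET.SubElement(
            svg, "g",
            attrib={"class": "gene-panel", "id": f"panel-{panel.gene.gene_id}"},
        )
        for ci, cell in enumerate(cells):
            x0 = _PAD + ci * (_PANEL_W + 3 * _PAD)

            def sx(rel: int) -> float:
                rel = min(max(rel, wlo), whi)
                return round(x0 + (rel - wlo) / span * _PANEL_W, 2)

            cgroup = ET.SubElement(group, "g", attrib={"class": "cell-panel"})
            name = ET.SubElement(
                cgroup, "text", x=str(x0), y=str(y0),
                attrib={"class": "gene-label"},
            )
            name.text = panel.gene.gene_id
            y_gene = y0 + _TRACK_H * (len(marks) + 1) + _PAD
            ET.SubElement(  # scale line with the TSS tick at rel 0
                cgroup, "line",
                x1=str(sx(wlo)), x2=str(sx(whi)),
                y1=str(y_gene + _GENE_H // 2), y2=str(y_gene + _GENE_H // 2),
                attrib={"class": "scale-line", "stroke": "#7fb2e5"},
            )
            ET.SubElement(
                cgroup, "line",
                x1=str(sx(0)), x2=str(sx(0)),
                y1=str(y_gene - 3), y2=str(y_gene + _GENE_H + 3),
                attrib={"class": "tss-tick", "stroke": "#333333"},
            )
            ET.SubElement(
                cgroup, "rect",
                x=str(sx(0)), y=str(y_gene),
                width=str(max(sx(panel.gene_length) - sx(0), 1.0)),
                height=str(_GENE_H),
                attrib={"class": "gene-body", "fill": "#000000"},
            )
            for iv, orientation in panel.neighbors:
                dy = 0 if orientation == "same" else _GENE_H // 2
                ET.SubElement(
                    cgroup, "rect",
                    x=str(sx(iv.rel_start)), y=str(y_gene + dy),
                    width=str(max(sx(iv.rel_end) - sx(iv.rel_start), 1.0)),
                    height=str(_GENE_H // 2),
                    attrib={
                        "class": f"neighbor neighbor-{orientation}",
                        "fill": "#9e9e9e",
                    },
                )
            for mi, mark in enumerate(marks):
                y_track = y0 + mi * _TRACK_H + _PAD // 2
                key = TrackKey(cell, mark)
                for iv in panel.tracks.get(key, []):
                    ET.SubElement(
                        cgroup, "rect",
                        x=str(sx(iv.rel_start)), y=str(y_track),
                        width=str(max(sx(iv.rel_end) - sx(iv.rel_start), 1.0)),
                        height=str(_TRACK_H - 2),
                        attrib={
                            "class": f"peak peak-{mark}",
                            "fill": colors[mark],
                            "fill-opacity": str(_opacity(iv.score, smin, smax)),
                        },
                    )
            v = panel.expression.get(cell)
            swatch_attrib = {"class": "expr-swatch", "stroke": "#555555"}
            swatch_attrib["fill"] = "none" if v is None else _grey(v, lo, hi)
            ET.SubElement(
                cgroup, "rect",
                x=str(x0 + _PANEL_W + _PAD // 2), y=str(y_gene),
                width=str(_GENE_H), height=str(_GENE_H),
                attrib=swatch_attrib,
            )
    text = '<?xml version="1.0" encoding="UTF-8"?>\n' + ET.tostring(
        svg, encoding="unicode"
    ) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
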