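"""TSS-relative, orientation-corrected coordinate mapping and gene panels.

Every genomic feature is re-expressed relative to the transcription start
site of each target gene: position 0 is the TSS, negative positions are
upstream of the TSS after strand correction, and the gene body occupies
``[0, gene_length)`` on both strands.  For minus-strand genes the TSS anchor
is ``span_end`` (the exclusive bound of the half-open span), which is what
makes the body exactly ``[0, L)`` under reflection.

A :class:`GenePanel` is one gene's analysis window ``[-flank_up,
gene_length + flank_down)`` holding the mapped feature tracks, expression
values, neighboring genes and exons, plus the ``show`` flag that filters
toggle.  Peaks are admitted into a panel by >= 1 bp overlap with the window
and are stored unclipped, sorted by (rel_start, rel_end) so panel content is
independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import inf

from .annotation import AnnotationSet, GeneModel, find_neighbors
from .feature_io import ExpressionTable, PeakSet, TrackKey, apply_cutoffs

__all__ = [
    "RelativeInterval",
    "GenePanel",
    "Settings",
    "to_relative",
    "to_absolute",
    "build_panels",
    "set_flanks",
]

DEFAULT_FLANK = 20_000  # bp up- and downstream included by default


@dataclass(frozen=True, order=True)
class RelativeInterval:
    """Half-open interval in TSS-relative bp, with the source peak's score."""

    rel_start: int
    rel_end: int
    score: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.rel_start >= self.rel_end:
            raise ValueError("rel_start >= rel_end")

    @property
    def size(self) -> int:
        return self.rel_end - self.rel_start


@dataclass
class Settings:
    """Analysis settings: window flanks, peak quality cutoffs, expression
    display scale (None bounds mean "compute from the 5th-95th percentile")."""

    flank_up: int = DEFAULT_FLANK
    flank_down: int = DEFAULT_FLANK
    min_peak_score: float = 0.0
    min_peak_size: int = 0
    max_peak_size: float = inf
    expr_scale_lo: float | None = None
    expr_scale_hi: float | None = None

    def __post_init__(self) -> None:
        if self.flank_up < 0 or self.flank_down < 0:
            raise ValueError("flanks must be >= 0")
        if not (0 <= self.min_peak_size <= self.max_peak_size):
            raise ValueError("require 0 <= min_peak_size <= max_peak_size")
        if (
            self.expr_scale_lo is not None
            and self.expr_scale_hi is not None
            and self.expr_scale_lo > self.expr_scale_hi
        ):
            raise ValueError("expr_scale_lo > expr_scale_hi")


@dataclass
class GenePanel:
    gene: GeneModel
    flank_up: int
    flank_down: int
    tracks: dict[TrackKey, list[RelativeInterval]] = field(default_factory=dict)
    expression: dict[str, float] = field(default_factory=dict)
    neighbors: list[tuple[RelativeInterval, str]] = field(default_factory=list)
    exons_rel: list[RelativeInterval] = field(default_factory=list)
    show: bool = True

    @property
    def gene_length(self) -> int:
        return self.gene.length

    @property
    def window(self) -> tuple[int, int]:
        """TSS-relative analysis window, half-open."""
        return (-self.flank_up, self.gene_length + self.flank_down)


def to_relative(
    interval: tuple[int, int], gene: GeneModel, chrom: str | None = None
) -> tuple[int, int]:
    """Map a genomic half-open interval to TSS-relative coordinates.

    Plus strand: ``rel = (start - span_start, end - span_start)``; minus
    strand reflects about ``span_end``: ``rel = (span_end - end,
    span_end - start)``.  The gene body maps to ``[0, L)`` either way.
    Passing the interval's ``chrom`` enables the cross-chromosome guard.
    """
    start, end = interval
    if chrom is not None and chrom != gene.chrom:
        raise ValueError(
            f"interval on {chrom} cannot be mapped to gene "
            f"{gene.gene_id} on {gene.chrom}"
        )
    if start >= end:
        raise ValueError("interval start >= end")
    if gene.strand == "+":
        return (start - gene.span_start, end - gene.span_start)
    return (gene.span_end - end, gene.span_end - start)


def to_absolute(rel: tuple[int, int], gene: GeneModel) -> tuple[int, int]:
    """Exact inverse of :func:`to_relative`."""
    rel_start, rel_end = rel
    if rel_start >= rel_end:
        raise ValueError("interval start >= end")
    if gene.strand == "+":
        return (gene.span_start + rel_start, gene.span_start + rel_end)
    return (gene.span_end - rel_end, gene.span_end - rel_start)


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and a[1] > b[0]


def _sorted_intervals(ivs: list[RelativeInterval]) -> list[RelativeInterval]:
    return sorted(ivs, key=lambda r: (r.rel_start, r.rel_end, r.score, r.name))


def build_panels(
    genes: list[GeneModel],
    peaksets: list[PeakSet],
    expr: list[ExpressionTable],
    settings: Settings | None = None,
    ann: AnnotationSet | None = None,
) -> list[GenePanel]:
    """Assemble one :class:`GenePanel` per gene.

    Peak cutoffs from ``settings`` are applied first; a peak enters a panel
    iff its TSS-relative interval overlaps the window.  Expression is joined
    through any gene alias (case-insensitive); genes absent from a table get
    no entry rather than a zero.  Neighbor/overlapping genes are looked up in
    ``ann`` when provided.  Every loaded track key appears in every panel
    (possibly with an empty interval list), so filters can distinguish
    "track has no peaks here" from "track was never loaded".
    """
    if settings is None:
        settings = Settings()
    filtered = [
        apply_cutoffs(
            ps,
            min_score=settings.min_peak_score,
            min_size=settings.min_peak_size,
            max_size=settings.max_peak_size,
        )
        for ps in peaksets
    ]
    by_chrom: dict[TrackKey, dict[str, list]] = {}
    for ps in filtered:
        chrom_map = by_chrom.setdefault(ps.key, {})
        for p in ps.peaks:
            chrom_map.setdefault(p.chrom, []).append(p)

    panels: list[GenePanel] = []
    for gene in genes:
        window = (-settings.flank_up, gene.length + settings.flank_down)
        tracks: dict[TrackKey, list[RelativeInterval]] = {}
        for key, chrom_map in by_chrom.items():
            ivs = []
            for p in chrom_map.get(gene.chrom, ()):
                rel = to_relative((p.start, p.end), gene)
                if _overlaps(rel, window):
                    ivs.append(
                        RelativeInterval(rel[0], rel[1], score=p.score, name=p.name)
                    )
            tracks[key] = _sorted_intervals(ivs)
        expression: dict[str, float] = {}
        for table in expr:
            v = table.get(*gene.all_ids())
            if v is not None:
                expression[table.cell_type] = v
        neighbors: list[tuple[RelativeInterval, str]] = []
        if ann is not None:
            for other, orientation in find_neighbors(
                gene, settings.flank_up, settings.flank_down, ann
            ):
                rel = to_relative((other.span_start, other.span_end), gene)
                neighbors.append(
                    (RelativeInterval(rel[0], rel[1], name=other.gene_id), orientation)
                )
        exon_ivs = []
        for i, (s, e) in enumerate(gene.exons):
            rs, re_ = to_relative((s, e), gene)
            exon_ivs.append(RelativeInterval(rs, re_, name=f"exon{i}"))
        panels.append(
            GenePanel(
                gene=gene,
                flank_up=settings.flank_up,
                flank_down=settings.flank_down,
                tracks=tracks,
                expression=expression,
                neighbors=neighbors,
                exons_rel=_sorted_intervals(exon_ivs),
                show=True,
            )
        )
    return panels


def set_flanks(
    panels: list[GenePanel],
    genes: list[GeneModel],
    peaksets: list[PeakSet],
    expr: list[ExpressionTable],
    settings: Settings,
    ann: AnnotationSet | None,
    flank_up: int,
    flank_down: int,
) -> list[GenePanel]:
    """Re-map all panels under new flanks.

    Defined (and tested) as equivalent to rebuilding from scratch with the
    new window; existing show flags are preserved so a flank change does not
    silently clear an active filter result.
    """
    new_settings = replace(settings, flank_up=flank_up, flank_down=flank_down)
    rebuilt = build_panels(genes, peaksets, expr, new_settings, ann)
    shown = {p.gene.gene_id: p.show for p in panels}
    for p in rebuilt:
        p.show = shown.get(p.gene.gene_id, True)
    return rebuilt
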