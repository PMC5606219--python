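"""Deterministic synthetic genomes, peak landscapes and expression tables.

Everything downstream of file ingest is testable without any downloads:
:func:`make_annotation` lays out non-overlapping genes with random strands
and exon structures, :func:`make_background_peaks` scatters Poisson
background peaks, and :func:`plant_pattern` inserts peak/expression motifs
guaranteed to satisfy a given filter — and, just as important, removes any
accidental instance of the motif from non-target genes, so that a filter
chain recovers *exactly* the planted gene set.

Genes are separated by a minimum gap (default 50 kb) larger than the default
20 kb analysis flank, so a peak planted for one gene can never fall inside
another gene's window; this is what turns exact recovery from a
probabilistic statement into a guarantee.

One integer seed drives each generator through a single numpy Generator
stream with a fixed draw order, so every artifact is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .annotation import AnnotationSet, GeneModel, gene_window
from .feature_io import ExpressionTable, Peak, PeakSet, TrackKey
from .mapper import DEFAULT_FLANK, to_absolute, to_relative

__all__ = [
    "PatternSpec",
    "make_annotation",
    "make_background_peaks",
    "make_expression",
    "plant_pattern",
    "mirror_genome",
    "write_annotation",
    "write_id_map",
    "write_gene_list",
]

PATTERN_KINDS = ("bivalent_tss", "exon_proximal", "upstream_pair", "expression_high")

PLANTED_PREFIX = "planted_"


@dataclass(frozen=True)
class PatternSpec:
    """A plantable motif: which genes must (exclusively) satisfy which filter.

    ``params`` supplies the matching filter's parameters — e.g. for
    ``bivalent_tss``: ``cell_type``, ``mark_a``, ``mark_b``, ``window_rel``,
    optionally ``absent_marks``; for ``exon_proximal``: ``cell_type``,
    ``mark``, ``max_distance``; for ``expression_high``: ``cell_type`` and
    ``threshold``.
    """

    kind: str
    target_genes: tuple[str, ...]
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in PATTERN_KINDS:
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        object.__setattr__(self, "target_genes", tuple(self.target_genes))


def make_annotation(
    n_genes: int,
    n_chroms: int = 3,
    length_range: tuple[int, int] = (2_000, 20_000),
    seed: int = 0,
    min_gap: int = 50_000,
    max_exons: int = 10,
    chrom_length: int | None = None,
) -> AnnotationSet:
    """Generate ``n_genes`` non-overlapping genes across ``n_chroms``
    chromosomes with random strands and 1..``max_exons`` exons each.

    Genes are placed left to right with an inter-gene gap of at least
    ``min_gap`` bp.  With a fixed ``chrom_length`` the layout is checked to
    fit and a ValueError raised otherwise; by default chromosomes are sized
    to their content.  Fully deterministic given ``seed``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    cursor = {c: min_gap for c in chroms}
    transcripts: dict[str, list[GeneModel]] = {}
    for i in range(n_genes):
        chrom = chroms[i % n_chroms]
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        gap = int(rng.integers(min_gap, min_gap + min_gap // 2 + 1))
        start = cursor[chrom] + gap
        end = start + length
        cursor[chrom] = end
        n_ex = int(rng.integers(1, max_exons + 1))
        n_ex = min(n_ex, max(1, length // 4))
        if n_ex == 1:
            exons = ((start, end),)
        else:
            cuts = rng.choice(length - 1, size=2 * n_ex - 2, replace=False) + 1
            bounds = [0, *sorted(int(c) for c in cuts), length]
            exons = tuple(
                (start + bounds[2 * j], start + bounds[2 * j + 1])
                for j in range(n_ex)
            )
        gid = f"G{i + 1:04d}"
        transcripts[gid] = [
            GeneModel(
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                span_start=start,
                span_end=end,
                exons=exons,
                aliases=(f"TX{i + 1:05d}",),
                description=f"synthetic gene {i + 1}",
            )
        ]
    if chrom_length is not None:
        worst = max(cursor.values()) + min_gap
        if worst > chrom_length:
            raise ValueError(
                f"chrom_length={chrom_length} too small: need {worst} bp"
            )
        sizes = {c: chrom_length for c in chroms}
    else:
        sizes = {c: cursor[c] + min_gap for c in chroms}
    return AnnotationSet(transcripts=transcripts, chrom_sizes=sizes)


def make_background_peaks(
    ann: AnnotationSet,
    key: TrackKey,
    rate_per_100kb: float = 3.0,
    size_range: tuple[int, int] = (200, 2_000),
    score_range: tuple[float, float] = (100, 1000),
    seed: int = 0,
) -> PeakSet:
    """Poisson-placed background peaks, independent of gene positions.

    The expected peak count per chromosome is ``rate_per_100kb *
    chrom_size / 1e5``; positions, sizes and scores are uniform.
    """
    if rate_per_100kb < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    peaks: list[Peak] = []
    for chrom in sorted(ann.chrom_sizes):
        csize = ann.chrom_sizes[chrom]
        n = int(rng.poisson(rate_per_100kb * csize / 1e5))
        for j in range(n):
            size = int(rng.integers(size_range[0], size_range[1] + 1))
            start = int(rng.integers(0, max(1, csize - size)))
            score = float(np.round(rng.uniform(*score_range), 1))
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=start,
                    end=start + size,
                    name=f"bg_{key.cell_type}_{key.mark}_{chrom}_{j}",
                    score=score,
                    signal_value=float(np.round(score / 100.0, 3)),
                )
            )
    return PeakSet(key=key, peaks=peaks, source="synthetic")


def make_expression(
    ann: AnnotationSet,
    cell_type: str,
    seed: int = 0,
    mean_log: float = 0.0,
    sigma_log: float = 1.2,
) -> ExpressionTable:
    """Log-normal FPKM-like values, one per gene, deterministic per seed."""
    rng = np.random.default_rng(seed)
    values = {
        g.gene_id: float(np.round(rng.lognormal(mean_log, sigma_log), 3))
        for g in sorted(ann.genes, key=lambda g: g.gene_id)
    }
    return ExpressionTable(cell_type=cell_type, values=values, source="synthetic")


# --- pattern planting -------------------------------------------------------

def _copy_peaksets(peaksets: list[PeakSet]) -> list[PeakSet]:
    return [replace(ps, peaks=list(ps.peaks)) for ps in peaksets]


def _get_track(peaksets: list[PeakSet], key: TrackKey) -> PeakSet:
    for ps in peaksets:
        if ps.key == key:
            return ps
    ps = PeakSet(key=key, peaks=[], source="synthetic")
    peaksets.append(ps)
    return ps


def _abs_query_window(
    gene: GeneModel, window_rel: tuple[int, int] | None,
    flank_up: int, flank_down: int,
) -> tuple[int, int]:
    if window_rel is None:
        window_rel = (-flank_up, gene.length + flank_down)
    lo, hi = to_absolute(window_rel, gene)
    return max(0, lo), hi


def _remove_overlapping(
    ps: PeakSet, chrom: str, window: tuple[int, int]
) -> None:
    lo, hi = window
    ps.peaks[:] = [
        p
        for p in ps.peaks
        if p.name.startswith(PLANTED_PREFIX)
        or p.chrom != chrom
        or not (p.start < hi and p.end > lo)
    ]


def _planted_peak(gene: GeneModel, rel: tuple[int, int], name: str,
                  score: float) -> Peak:
    start, end = to_absolute(rel, gene)
    return Peak(chrom=gene.chrom, start=start, end=end, name=name, score=score,
                signal_value=round(score / 100.0, 3))


def plant_pattern(
    ann: AnnotationSet,
    peaksets: list[PeakSet],
    expr: list[ExpressionTable],
    spec: PatternSpec,
    seed: int = 0,
    flank_up: int = DEFAULT_FLANK,
    flank_down: int = DEFAULT_FLANK,
) -> tuple[list[PeakSet], list[ExpressionTable]]:
    """Insert the motif of ``spec`` into its target genes and scrub it from
    every other gene.

    Target genes receive peaks (or expression values) constructed to satisfy
    the matching filter inside its window; non-target genes have every peak
    of the motif's primary mark removed from their query window (conflicting
    intervals removed rather than resampled), so the corresponding filter
    returns exactly ``spec.target_genes``.  Inputs are not modified; updated
    copies are returned.
    """
    by_id = {g.gene_id: g for g in ann.genes}
    unknown = [g for g in spec.target_genes if g not in by_id]
    if unknown:
        raise ValueError(f"target genes not in annotation: {unknown}")
    rng = np.random.default_rng(seed)
    new_peaksets = _copy_peaksets(peaksets)
    new_expr = [
        ExpressionTable(t.cell_type, dict(t.values), t.source, list(t.parse_reports))
        for t in expr
    ]
    targets = set(spec.target_genes)
    p = spec.params

    if spec.kind in ("bivalent_tss", "upstream_pair"):
        cell = p["cell_type"]
        mark_a, mark_b = p["mark_a"], p["mark_b"]
        window_rel = tuple(p.get("window_rel") or (-5_000, 2_000))
        if window_rel[1] - window_rel[0] < 2_000:
            raise ValueError("window_rel too small to plant a peak pair")
        max_gap = int(p.get("max_distance", 0))
        ps_a = _get_track(new_peaksets, TrackKey(cell, mark_a))
        ps_b = _get_track(new_peaksets, TrackKey(cell, mark_b))
        for gid in spec.target_genes:
            gene = by_id[gid]
            wlo, whi = window_rel
            width_a = int(rng.integers(300, 800))
            width_b = int(rng.integers(300, 800))
            anchor = int(rng.integers(wlo, whi - width_a - width_b - max_gap))
            a_rel = (anchor, anchor + width_a)
            if spec.kind == "bivalent_tss":
                # overlapping pair: b starts inside a
                b_start = anchor + max(1, width_a // 2)
                b_rel = (b_start, b_start + width_b)
            else:
                gap = int(rng.integers(0, max_gap + 1))
                b_rel = (a_rel[1] + gap, a_rel[1] + gap + width_b)
            # keep the planted pair inside the query window
            if b_rel[1] > whi:
                shift = b_rel[1] - whi
                a_rel = (a_rel[0] - shift, a_rel[1] - shift)
                b_rel = (b_rel[0] - shift, b_rel[1] - shift)
            score = float(rng.integers(400, 1000))
            ps_a.peaks.append(_planted_peak(
                gene, a_rel, f"{PLANTED_PREFIX}{spec.kind}_{gid}_a", score))
            ps_b.peaks.append(_planted_peak(
                gene, b_rel, f"{PLANTED_PREFIX}{spec.kind}_{gid}_b", score))
        for gene in ann.genes:
            if gene.gene_id in targets:
                for mark in p.get("absent_marks", ()):
                    win = _abs_query_window(gene, window_rel, flank_up, flank_down)
                    _remove_overlapping(
                        _get_track(new_peaksets, TrackKey(cell, mark)),
                        gene.chrom, win,
                    )
            else:
                win = _abs_query_window(gene, window_rel, flank_up, flank_down)
                _remove_overlapping(ps_a, gene.chrom, win)

    elif spec.kind == "exon_proximal":
        cell, mark = p["cell_type"], p["mark"]
        max_distance = int(p.get("max_distance", 500))
        window_rel = p.get("window_rel")  # None = whole panel window
        ps_m = _get_track(new_peaksets, TrackKey(cell, mark))
        for gid in spec.target_genes:
            gene = by_id[gid]
            exon = gene.exons[int(rng.integers(0, len(gene.exons)))]
            e_rel = to_relative(exon, gene)
            gap = int(rng.integers(0, max_distance + 1))
            width = int(rng.integers(200, 1_000))
            rel = (e_rel[1] + gap, e_rel[1] + gap + width)
            score = float(rng.integers(400, 1000))
            ps_m.peaks.append(_planted_peak(
                gene, rel, f"{PLANTED_PREFIX}exon_proximal_{gid}", score))
        for gene in ann.genes:
            if gene.gene_id not in targets:
                win = _abs_query_window(gene, window_rel, flank_up, flank_down)
                _remove_overlapping(ps_m, gene.chrom, win)

    elif spec.kind == "expression_high":
        cell = p["cell_type"]
        threshold = float(p["threshold"])
        lo, hi = p.get("value_range", (threshold * 1.05, threshold * 5.0))
        table = next((t for t in new_expr if t.cell_type == cell), None)
        if table is None:
            table = ExpressionTable(cell_type=cell, values={}, source="synthetic")
            new_expr.append(table)
        for gene in sorted(ann.genes, key=lambda g: g.gene_id):
            gid = gene.gene_id
            if gid in targets:
                table.values[gid] = float(np.round(rng.uniform(lo, hi), 3))
            elif table.values.get(gid, 0.0) >= threshold:
                table.values[gid] = float(
                    np.round(rng.uniform(0.0, threshold * 0.9), 3)
                )
        new_expr = [
            ExpressionTable(t.cell_type, dict(t.values), t.source,
                            list(t.parse_reports))
            for t in new_expr
        ]

    return new_peaksets, new_expr


# --- genome mirroring (orientation-correctness oracle transform) ------------

def mirror_genome(
    ann: AnnotationSet, peaksets: list[PeakSet]
) -> tuple[AnnotationSet, list[PeakSet]]:
    """Reflect every chromosome (x -> C - x), flipping strands and exon order.

    TSS-relative panel content must be invariant under this transform — it is
    the defining property of correct orientation handling.
    """
    sizes = ann.chrom_sizes

    def flip_gene(g: GeneModel) -> GeneModel:
        C = sizes[g.chrom]
        exons = tuple(sorted((C - e, C - s) for s, e in g.exons))
        return GeneModel(
            gene_id=g.gene_id,
            aliases=g.aliases,
            chrom=g.chrom,
            strand="-" if g.strand == "+" else "+",
            span_start=C - g.span_end,
            span_end=C - g.span_start,
            exons=exons,
            description=g.description,
        )

    new_transcripts = {
        gid: [flip_gene(t) for t in models]
        for gid, models in ann.transcripts.items()
    }
    new_ann = AnnotationSet(transcripts=new_transcripts, chrom_sizes=dict(sizes))
    new_peaksets = []
    for ps in peaksets:
        flipped = [
            replace(
                pk,
                start=sizes[pk.chrom] - pk.end,
                end=sizes[pk.chrom] - pk.start,
                strand={"+": "-", "-": "+", ".": "."}[pk.strand],
                summit_offset=(
                    pk.size - 1 - pk.summit_offset if pk.summit_offset >= 0 else -1
                ),
            )
            for pk in ps.peaks
        ]
        new_peaksets.append(replace(ps, peaks=flipped))
    return new_ann, new_peaksets


# --- file writers (round-trip through the real parsers) ---------------------

def write_annotation(ann: AnnotationSet, path: str | Path) -> None:
    """Write every transcript row in the UCSC Table Browser dialect."""
    header = ["name", "chrom", "strand", "txStart", "txEnd",
              "exonStarts", "exonEnds", "name2", "description"]
    lines = ["\t".join(header)]
    for gid in ann.transcripts:
        for t in ann.transcripts[gid]:
            tx_id = t.aliases[0] if t.aliases else t.gene_id
            lines.append("\t".join([
                tx_id, t.chrom, t.strand, str(t.span_start), str(t.span_end),
                "".join(f"{s}," for s, _ in t.exons),
                "".join(f"{e}," for _, e in t.exons),
                t.gene_id, t.description,
            ]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_id_map(path: str | Path) -> None:
    import json

    from .annotation import DEFAULT_ID_MAP

    Path(path).write_text(json.dumps(DEFAULT_ID_MAP, indent=2) + "\n")


def write_gene_list(gene_ids: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(gene_ids) + "\n")
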