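"""Aggregate views over gene panels: metagene profiles, peak histograms,
expression scatter data and the gene table.

The profile statistic is per-bin *gene occupancy*: the fraction of
contributing genes that have at least one peak of the track overlapping the
bin.  Peak files carry no base-resolution signal, so occupancy (a binary
per-gene, per-bin quantity) is the well-defined average; an optional
score-weighted variant is exposed as a flag.  All aggregates respect each
panel's ``show`` flag when ``shown_only`` is set — hidden genes contribute
nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .feature_io import PeakSet, TrackKey
from .mapper import GenePanel
from .pattern_search import UnknownTrackError

__all__ = [
    "Profile",
    "Histogram",
    "average_feature_profile",
    "feature_histogram",
    "expression_scale",
    "expression_scatter",
    "gene_table",
]


@dataclass
class Profile:
    """Binned occupancy profile.

    ``mode="tss"``: bins tile the common window ``[-flank_up, flank_down)``
    in absolute bp around the TSS.  ``mode="genebody"``: each gene body
    ``[0, L)`` is rescaled to ``n_bins`` equal fractions, so ``bin_edges``
    are percent-of-body.  Values are occupancy fractions in [0, 1].
    """

    mode: str
    bin_edges: np.ndarray
    values: np.ndarray
    n_genes: int


@dataclass
class Histogram:
    attribute: str
    bin_edges: np.ndarray
    counts: np.ndarray
    underflow: int = 0
    overflow: int = 0


def _contributing(panels: list[GenePanel], shown_only: bool) -> list[GenePanel]:
    return [p for p in panels if p.show or not shown_only]


def average_feature_profile(
    panels: list[GenePanel],
    key: TrackKey,
    mode: str = "tss",
    bin_size: int = 1000,
    n_bins: int = 100,
    shown_only: bool = True,
    score_weighted: bool = False,
) -> Profile:
    """Average occupancy of one track across the contributing genes.

    In tss mode, bins of ``bin_size`` bp tile ``[-flank_up, flank_down)``
    anchored at 0 (all contributing panels must share flanks).  In genebody
    mode, each body is rescaled to ``n_bins`` fractions so genes of different
    lengths align.  A gene occupies a bin iff any track interval overlaps it;
    with ``score_weighted`` the gene contributes its maximal overlapping
    peak score (normalized by the track-wide maximum) instead of 1.
    """
    contrib = _contributing(panels, shown_only)
    if not contrib:
        raise ValueError("no contributing panels (is everything hidden?)")
    for p in contrib:
        if key not in p.tracks:
            raise UnknownTrackError(key)
    max_score = max(
        (iv.score for p in contrib for iv in p.tracks[key]), default=0.0
    )

    def weight(iv) -> float:
        if not score_weighted:
            return 1.0
        return iv.score / max_score if max_score > 0 else 1.0

    if mode == "tss":
        f_up = {p.flank_up for p in contrib}
        f_down = {p.flank_down for p in contrib}
        if len(f_up) != 1 or len(f_down) != 1:
            raise ValueError("tss-mode profile requires uniform flanks")
        lo, hi = -f_up.pop(), f_down.pop()
        edges = np.arange(lo, hi + bin_size, bin_size)
        edges = edges[edges <= hi]
        if edges[-1] < hi:
            edges = np.append(edges, hi)
        nb = len(edges) - 1
        acc = np.zeros(nb)
        for p in contrib:
            best = np.zeros(nb)
            for iv in p.tracks[key]:
                # bins overlapped by [rel_start, rel_end)
                i0 = np.searchsorted(edges, iv.rel_start, side="right") - 1
                i1 = np.searchsorted(edges, iv.rel_end, side="left")
                i0, i1 = max(i0, 0), min(i1, nb)
                if i0 < i1:
                    best[i0:i1] = np.maximum(best[i0:i1], weight(iv))
            acc += best
        return Profile("tss", edges, acc / len(contrib), len(contrib))

    if mode == "genebody":
        acc = np.zeros(n_bins)
        for p in contrib:
            L = p.gene_length
            best = np.zeros(n_bins)
            for iv in p.tracks[key]:
                s = max(iv.rel_start, 0)
                e = min(iv.rel_end, L)
                if s >= e:
                    continue
                # bin j = [j*L/n, (j+1)*L/n); overlap test in exact integers
                j0 = (s * n_bins) // L
                j1 = (e * n_bins + L - 1) // L  # ceil(e*n/L)
                best[j0:j1] = np.maximum(best[j0:j1], weight(iv))
            acc += best
        edges = np.linspace(0.0, 100.0, n_bins + 1)
        return Profile("genebody", edges, acc / len(contrib), len(contrib))

    raise ValueError(f"unknown profile mode {mode!r}")


def feature_histogram(
    ps: PeakSet, attribute: str, bin_edges: np.ndarray | list[float]
) -> Histogram:
    """Histogram of peak sizes or scores over right-open bins; values outside
    ``[edges[0], edges[-1])`` are tallied as underflow/overflow so that
    ``sum(counts) + underflow + overflow == len(peaks)``."""
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing, length >= 2")
    if attribute == "size":
        vals = np.array([p.size for p in ps.peaks], dtype=float)
    elif attribute == "score":
        vals = np.array([p.score for p in ps.peaks], dtype=float)
    else:
        raise ValueError(f"unknown attribute {attribute!r}")
    nb = len(edges) - 1
    if len(vals) == 0:
        return Histogram(attribute, edges, np.zeros(nb, dtype=int))
    idx = np.searchsorted(edges, vals, side="right") - 1
    under = int(np.sum(vals < edges[0]))
    over = int(np.sum(vals >= edges[-1]))
    in_range = (idx >= 0) & (vals < edges[-1])
    counts = np.bincount(idx[in_range], minlength=nb).astype(int)
    return Histogram(attribute, edges, counts, underflow=under, overflow=over)


def expression_scale(
    values: list[float] | np.ndarray, lo_pct: float = 5, hi_pct: float = 95
) -> tuple[float, float]:
    """Display bounds for the expression color scale: the 5th and 95th
    percentiles (linear interpolation) of the loaded values by default.
    A degenerate scale (lo == hi) is widened symmetrically for display."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("expression_scale needs at least one value")
    lo, hi = np.percentile(vals, [lo_pct, hi_pct], method="linear")
    if lo == hi:
        eps = max(0.5, abs(lo) * 0.05)
        return (float(lo - eps), float(hi + eps))
    return (float(lo), float(hi))


def expression_scatter(
    panels: list[GenePanel],
    cell_x: str,
    cell_y: str,
    shown_only: bool = True,
) -> tuple[list[tuple[str, float, float]], list[str]]:
    """Per-gene expression in two cell types.

    Returns ``(points, missing)``: one ``(gene_id, x, y)`` point per
    contributing gene with values in both cell types; genes lacking either
    value are listed in ``missing`` so nothing is dropped silently.
    """
    contrib = _contributing(panels, shown_only)
    loaded = {c for p in panels for c in p.expression}
    for cell in (cell_x, cell_y):
        if cell not in loaded:
            raise KeyError(f"no expression data loaded for cell type {cell!r}")
    points: list[tuple[str, float, float]] = []
    missing: list[str] = []
    for p in contrib:
        x = p.expression.get(cell_x)
        y = p.expression.get(cell_y)
        if x is None or y is None:
            missing.append(p.gene.gene_id)
        else:
            points.append((p.gene.gene_id, x, y))
    return points, missing


def gene_table(
    panels: list[GenePanel], filtered_only: bool = False
) -> pd.DataFrame:
    """Tabulate every (or every shown) gene: locus, length, per-track peak
    counts within the window and per-cell-type expression.

    The returned DataFrame sorts on any column; the ``gene_id`` column is a
    ready-made plain gene list for downstream GO or enrichment analysis.
    """
    rows = []
    track_keys = sorted({k for p in panels for k in p.tracks})
    cell_types = sorted({c for p in panels for c in p.expression})
    for p in panels:
        if filtered_only and not p.show:
            continue
        row: dict = {
            "gene_id": p.gene.gene_id,
            "chrom": p.gene.chrom,
            "start": p.gene.span_start,
            "end": p.gene.span_end,
            "strand": p.gene.strand,
            "length": p.gene.length,
        }
        for k in track_keys:
            row[f"peaks[{k}]"] = len(p.tracks.get(k, []))
        for c in cell_types:
            row[f"expr[{c}]"] = p.expression.get(c, np.nan)
        rows.append(row)
    cols = (
        ["gene_id", "chrom", "start", "end", "strand", "length"]
        + [f"peaks[{k}]" for k in track_keys]
        + [f"expr[{c}]" for c in cell_types]
    )
    return pd.DataFrame(rows, columns=cols)
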