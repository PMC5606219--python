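"""Profiles, histograms, expression scaling/scatter, gene table."""

import numpy as np
import pytest

from genecontext.feature_io import Peak, PeakSet, TrackKey
from genecontext.mapper import RelativeInterval
from genecontext.summaries import (
    average_feature_profile,
    expression_scale,
    expression_scatter,
    feature_histogram,
    gene_table,
)

from test_pattern_search import make_panel

KEY = TrackKey("H1", "H3K4me3")


class TestAverageFeatureProfile:
    def test_empty_track_gives_all_zero(self):
        panels = [make_panel(gene_id=f"G{i}", tracks={KEY: []}, flank=2_000)
                  for i in range(4)]
        for mode in ("tss", "genebody"):
            prof = average_feature_profile(panels, KEY, mode=mode, bin_size=500)
            assert np.all(prof.values == 0.0)
            assert prof.n_genes == 4

    def test_full_window_coverage_gives_all_one(self):
        panels = [
            make_panel(gene_id=f"G{i}", length=3_000 + 700 * i, flank=2_000,
                       tracks={KEY: [(-2_000, 3_000 + 700 * i + 2_000)]})
            for i in range(5)
        ]
        for mode in ("tss", "genebody"):
            prof = average_feature_profile(panels, KEY, mode=mode, bin_size=250)
            assert np.all(prof.values == 1.0)

    def test_half_occupancy_around_tss(self):
        # half the genes carry exactly [-50, 50): 0.5 in the two bins
        # adjoining 0, nothing anywhere else
        panels = [
            make_panel(gene_id=f"G{i}", flank=1_000,
                       tracks={KEY: [(-50, 50)] if i % 2 == 0 else []})
            for i in range(10)
        ]
        prof = average_feature_profile(panels, KEY, mode="tss", bin_size=100)
        centers = (prof.bin_edges[:-1] + prof.bin_edges[1:]) / 2
        for lo, v in zip(prof.bin_edges[:-1], prof.values):
            assert v == (0.5 if lo in (-100, 0) else 0.0), (lo, v)
        assert len(centers) == 20

    def test_genebody_scaling_is_length_invariant(self):
        # intervals exactly tiling each gene body -> identically 1.0
        lengths = [1_000, 3_333, 7_919, 10_000]
        panels = [
            make_panel(gene_id=f"G{i}", length=L, flank=500,
                       tracks={KEY: [(0, L // 2), (L // 2, L)]})
            for i, L in enumerate(lengths)
        ]
        prof = average_feature_profile(panels, KEY, mode="genebody", n_bins=100)
        assert np.all(prof.values == 1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_per_base_coverage_oracle(self, seed):
        rng = np.random.default_rng(seed)
        panels = []
        flank = 60
        for i in range(8):
            L = int(rng.integers(40, 200))
            ivs = []
            for _ in range(int(rng.integers(0, 5))):
                s = int(rng.integers(-flank - 50, L + flank))
                ivs.append((s, s + int(rng.integers(1, 80))))
            panels.append(make_panel(gene_id=f"G{i}", length=L, flank=flank,
                                     tracks={KEY: sorted(ivs)}))
        bin_size, n_bins = 25, 10
        tss = average_feature_profile(panels, KEY, "tss", bin_size=bin_size)
        body = average_feature_profile(panels, KEY, "genebody", n_bins=n_bins)
        # per-base oracle, tss mode
        for j, (lo, hi) in enumerate(zip(tss.bin_edges[:-1], tss.bin_edges[1:])):
            bin_bases = set(range(int(lo), int(hi)))
            occ = sum(
                1 for p in panels
                if any(set(range(iv.rel_start, iv.rel_end)) & bin_bases
                       for iv in p.tracks[KEY])
            )
            assert tss.values[j] == pytest.approx(occ / len(panels))
        # per-base oracle, genebody mode (bin j covers [j*L/n, (j+1)*L/n))
        for j in range(n_bins):
            occ = 0
            for p in panels:
                L = p.gene_length
                covered = set()
                for iv in p.tracks[KEY]:
                    covered |= set(range(max(iv.rel_start, 0),
                                         min(iv.rel_end, L)))
                if any(b < (j + 1) * L / n_bins and b + 1 > j * L / n_bins
                       for b in covered):
                    occ += 1
            assert body.values[j] == pytest.approx(occ / len(panels))

    def test_hidden_genes_do_not_contribute(self):
        shown = make_panel(gene_id="A", flank=1_000, tracks={KEY: [(-50, 50)]})
        hidden = make_panel(gene_id="B", flank=1_000, tracks={KEY: [(-50, 50)]})
        hidden.show = False
        prof = average_feature_profile([shown, hidden], KEY, "tss",
                                       bin_size=100, shown_only=True)
        assert prof.n_genes == 1
        both = average_feature_profile([shown, hidden], KEY, "tss",
                                       bin_size=100, shown_only=False)
        assert both.n_genes == 2

    def test_all_hidden_is_an_error(self):
        p = make_panel(tracks={KEY: []})
        p.show = False
        with pytest.raises(ValueError):
            average_feature_profile([p], KEY, "tss")


class TestFeatureHistogram:
    def _ps(self, sizes, scores=None):
        scores = scores or [100] * len(sizes)
        return PeakSet(key=KEY, peaks=[
            Peak("chr1", 10_000 * i, 10_000 * i + s, f"p{i}", sc)
            for i, (s, sc) in enumerate(zip(sizes, scores))])

    def test_size_counts(self):
        hist = feature_histogram(self._ps([100, 100, 300]), "size", [0, 200, 400])
        assert list(hist.counts) == [2, 1]

    def test_empty_peakset_all_zero(self):
        hist = feature_histogram(PeakSet(key=KEY, peaks=[]), "size", [0, 100, 200])
        assert list(hist.counts) == [0, 0]

    def test_conservation_with_overflow(self):
        ps = self._ps([50, 150, 250, 990, 5_000], scores=[1, 2, 3, 4, 5])
        hist = feature_histogram(ps, "size", [100, 300, 1_000])
        assert hist.counts.sum() + hist.underflow + hist.overflow == len(ps.peaks)
        assert hist.underflow == 1 and hist.overflow == 1
        score_hist = feature_histogram(ps, "score", [0, 3, 10])
        assert list(score_hist.counts) == [2, 3]

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            feature_histogram(self._ps([100]), "size", [10, 10, 20])


class TestExpressionScale:
    def test_matches_sort_and_interpolate_oracle(self):
        values = list(range(1, 101))
        lo, hi = expression_scale(values)
        # independent oracle: linear interpolation between order statistics
        srt = sorted(values)

        def pct(q):
            pos = (len(srt) - 1) * q / 100
            i = int(pos)
            frac = pos - i
            return srt[i] * (1 - frac) + srt[min(i + 1, len(srt) - 1)] * frac

        assert lo == pytest.approx(pct(5))
        assert hi == pytest.approx(pct(95))

    @pytest.mark.parametrize("values", [[4.0], [7.0] * 20])
    def test_degenerate_scale_is_widened(self, values):
        lo, hi = expression_scale(values)
        assert lo < values[0] < hi

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            expression_scale([])


class TestExpressionScatter:
    def _panels(self):
        a = make_panel(gene_id="A", expression={"H1": 2.0, "K562": 8.0})
        b = make_panel(gene_id="B", expression={"H1": 1.0})
        c = make_panel(gene_id="C", expression={"K562": 3.0})
        return [a, b, c]

    def test_points_and_missing_partition_the_panels(self):
        panels = self._panels()
        points, missing = expression_scatter(panels, "H1", "K562")
        assert points == [("A", 2.0, 8.0)]
        assert sorted(missing) == ["B", "C"]
        assert len(points) + len(missing) == len(panels)

    def test_unknown_cell_type_is_an_error(self):
        with pytest.raises(KeyError, match="GM12878"):
            expression_scatter(self._panels(), "H1", "GM12878")

    def test_respects_show_flag(self):
        panels = self._panels()
        panels[0].show = False
        points, missing = expression_scatter(panels, "H1", "K562")
        assert points == [] and sorted(missing) == ["B", "C"]


class TestGeneTable:
    def _panels(self):
        k2 = TrackKey("H1", "H3K27me3")
        a = make_panel(gene_id="A", length=4_000,
                       tracks={KEY: [(0, 100), (5, 60), (200, 300)], k2: []},
                       expression={"H1": 3.5})
        b = make_panel(gene_id="B", length=9_000, tracks={KEY: [], k2: []})
        return [a, b]

    def test_per_track_counts_and_expression(self):
        df = gene_table(self._panels())
        row = df[df.gene_id == "A"].iloc[0]
        assert row["peaks[H1/H3K27me3]"] == 0
        assert row["peaks[H1/H3K4me3]"] == 3
        assert row["expr[H1]"] == 3.5
        assert np.isnan(df[df.gene_id == "B"].iloc[0]["expr[H1]"])

    def test_filtered_only_respects_show(self):
        panels = self._panels()
        for p in panels:
            p.show = False
        assert gene_table(panels, filtered_only=True).empty
        panels[1].show = True
        df = gene_table(panels, filtered_only=True)
        assert list(df.gene_id) == ["B"]

    def test_sorting_is_a_permutation(self):
        df = gene_table(self._panels())
        by_len = df.sort_values("length", ascending=False)
        assert sorted(by_len.gene_id) == sorted(df.gene_id)
        assert list(by_len.gene_id) == ["B", "A"]
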