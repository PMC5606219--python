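"""Filter algebra: gap primitive, per-filter semantics, chain evaluation."""

import random

import pytest

from genecontext.annotation import AnnotationSet, GeneModel
from genecontext.feature_io import TrackKey
from genecontext.mapper import GenePanel, RelativeInterval
from genecontext.pattern_search import (
    ChromFilter,
    ExpressionFilter,
    FeatureCountFilter,
    FeatureOverlapFilter,
    FilterChain,
    GeneSizeFilter,
    NameFilter,
    UnknownTrackError,
    apply_chain,
    chain_from_json,
    chain_to_json,
    eval_filter,
    interval_gap,
)

from conftest import brute_gap

K4 = TrackKey("H1", "H3K4me3")
K27 = TrackKey("H1", "H3K27me3")
K36 = TrackKey("H1", "H3K36me3")


def make_panel(gene_id="G1", chrom="chr1", length=10_000, strand="+",
               tracks=None, expression=None, exons=None, flank=20_000):
    gene = GeneModel(gene_id, chrom, strand, 100_000, 100_000 + length)
    panel = GenePanel(
        gene=gene, flank_up=flank, flank_down=flank,
        tracks={k: [RelativeInterval(*iv) if isinstance(iv, tuple) else iv
                    for iv in ivs]
                for k, ivs in (tracks or {}).items()},
        expression=expression or {},
        exons_rel=[RelativeInterval(*e) for e in (exons or [])],
    )
    return panel


class TestIntervalGap:
    @pytest.mark.parametrize("a,b,expected", [
        (((0, 10)), ((5, 15)), 0),      # overlap
        (((0, 10)), ((10, 20)), 0),     # abutting half-open
        (((0, 10)), ((510, 520)), 500),  # bases 10..509 lie between
    ])
    def test_examples(self, a, b, expected):
        ia, ib = RelativeInterval(*a), RelativeInterval(*b)
        assert interval_gap(ia, ib) == expected
        assert interval_gap(ib, ia) == expected  # symmetric

    def test_agrees_with_enumeration_oracle(self):
        rng = random.Random(0)
        for _ in range(300):
            a = RelativeInterval(*sorted(rng.sample(range(-100, 100), 2)) or (0, 1))
            s, e = sorted(rng.sample(range(-100, 100), 2))
            b = RelativeInterval(s, e)
            assert interval_gap(a, b) == brute_gap(a, b)


class TestEvalFilter:
    def test_bivalent_overlap_detected(self):
        panel = make_panel(tracks={K4: [(-100, 300)], K27: [(0, 500)]})
        f = FeatureOverlapFilter("H1", "H3K4me3", "H3K27me3", "near", 0,
                                 (-5_000, 2_000))
        assert eval_filter(f, panel)

    def test_single_mark_is_not_bivalent(self):
        panel = make_panel(tracks={K4: [(-100, 300)], K27: []})
        f = FeatureOverlapFilter("H1", "H3K4me3", "H3K27me3", "near", 0,
                                 (-5_000, 2_000))
        assert not eval_filter(f, panel)

    def test_exon_proximal_within_max_distance(self):
        # peak ends 400 bp before the exon starts
        panel = make_panel(tracks={K36: [(1_000, 1_600)]},
                           exons=[(2_000, 3_000)])
        near = FeatureOverlapFilter("H1", "H3K36me3", "exons", "near", 500)
        far = FeatureOverlapFilter("H1", "H3K36me3", "exons", "near", 300)
        assert eval_filter(near, panel)
        assert not eval_filter(far, panel)

    def test_upstream_downstream_relations(self):
        panel = make_panel(tracks={K4: [(0, 100)], K27: [(150, 250)]})
        up = FeatureOverlapFilter("H1", "H3K4me3", "H3K27me3",
                                  "a_upstream_of_b", 50)
        down = FeatureOverlapFilter("H1", "H3K4me3", "H3K27me3",
                                    "a_downstream_of_b", 500)
        assert eval_filter(up, panel)       # gap 50 <= 50
        assert not eval_filter(down, panel)  # wrong order

    def test_count_filter_window_and_ops(self):
        panel = make_panel(tracks={K4: [(-6_000, -5_500), (-100, 50), (10, 900)]})
        in_window = FeatureCountFilter("H1", "H3K4me3", "=", 2, (-5_000, 2_000))
        absent = FeatureCountFilter("H1", "H3K4me3", "=", 0, (-5_000, 2_000))
        whole = FeatureCountFilter("H1", "H3K4me3", ">=", 3, None)
        assert eval_filter(in_window, panel)
        assert not eval_filter(absent, panel)
        assert eval_filter(whole, panel)

    def test_expression_missing_value_fails(self):
        panel = make_panel(expression={"K562": 9.0})
        assert not eval_filter(ExpressionFilter("H1", ">=", 0.0), panel)
        assert eval_filter(ExpressionFilter("K562", ">", 3.2), panel)

    def test_unknown_track_error_names_the_track(self):
        panel = make_panel(tracks={K4: []})
        f = FeatureCountFilter("HeLa", "H3K9ac", ">=", 1)
        with pytest.raises(UnknownTrackError, match="HeLa/H3K9ac"):
            eval_filter(f, panel)

    def test_name_size_chrom_predicates(self):
        panel = make_panel(gene_id="NANOG", length=4_000)
        assert eval_filter(NameFilter(names=("nanog",)), panel)
        assert eval_filter(NameFilter(pattern="NAN*"), panel)
        assert not eval_filter(NameFilter(names=("OCT4",)), panel)
        assert eval_filter(GeneSizeFilter("<", 5_000), panel)
        assert eval_filter(ChromFilter(("chr1", "chrX")), panel)
        assert not eval_filter(ChromFilter(("chr2",)), panel)


def _random_panels(seed, n=30):
    rng = random.Random(seed)
    panels = []
    for i in range(n):
        tracks = {}
        for k in (K4, K27):
            ivs = []
            for _ in range(rng.randint(0, 6)):
                s = rng.randint(-8_000, 8_000)
                ivs.append(RelativeInterval(s, s + rng.randint(50, 2_000)))
            tracks[k] = sorted(ivs)
        panels.append(make_panel(
            gene_id=f"G{i:03d}", length=rng.randint(1_000, 9_000),
            tracks=tracks,
            expression={"H1": rng.random() * 10} if rng.random() > 0.2 else {}))
    return panels


def _filter_pool():
    return [
        FeatureCountFilter("H1", "H3K4me3", ">=", 1, (-5_000, 2_000)),
        FeatureCountFilter("H1", "H3K27me3", "=", 0, (-2_000, 2_000)),
        FeatureOverlapFilter("H1", "H3K4me3", "H3K27me3", "near", 100,
                             (-5_000, 5_000)),
        ExpressionFilter("H1", ">=", 2.0),
        GeneSizeFilter(">", 3_000),
    ]


class TestApplyChain:
    def test_empty_chain_keeps_everything(self):
        panels = _random_panels(0, n=10)
        panels[3].show = False  # chain application resets show flags
        survivors, trace = apply_chain(FilterChain(), panels)
        assert survivors == panels and trace == []
        assert all(p.show for p in panels)

    @pytest.mark.parametrize("seed", range(10))
    def test_chained_equals_intersection_and_order_invariant(self, seed):
        rng = random.Random(seed)
        panels = _random_panels(seed)
        filters = rng.sample(_filter_pool(), 3)
        chained, trace = apply_chain(FilterChain(list(filters)), panels)
        individually = [
            {p.gene.gene_id for p in panels if eval_filter(f, p)}
            for f in filters
        ]
        expected = set.intersection(*individually)
        assert {p.gene.gene_id for p in chained} == expected
        # trace is non-increasing and ends at the survivor count
        assert all(a >= b for a, b in zip(trace, trace[1:]))
        assert trace[-1] == len(chained)
        # any permutation yields the same final set
        perm = list(filters)
        rng.shuffle(perm)
        re_chained, _ = apply_chain(FilterChain(perm), panels)
        assert {p.gene.gene_id for p in re_chained} == expected

    def test_show_flags_toggle_without_mutating_data(self):
        panels = _random_panels(1, n=15)
        before = [dict(p.tracks) for p in panels]
        survivors, _ = apply_chain(
            FilterChain([GeneSizeFilter(">", 5_000)]), panels)
        ids = {p.gene.gene_id for p in survivors}
        assert all(p.show == (p.gene.gene_id in ids) for p in panels)
        assert [dict(p.tracks) for p in panels] == before


class TestSerialization:
    def test_chain_json_round_trip(self):
        chain = FilterChain(_filter_pool())
        again = chain_from_json(chain_to_json(chain))
        assert again.filters == chain.filters

    def test_bad_document_rejected(self):
        with pytest.raises(ValueError):
            chain_from_json('{"type": "feature_count"}')
        with pytest.raises(ValueError, match="warp"):
            chain_from_json('[{"type": "warp"}]')
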