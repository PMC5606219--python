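"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's interval arithmetic: they
enumerate bases or pairs directly, so agreement with the implementation is a
real cross-check rather than a tautology.
"""

from __future__ import annotations

import pytest

from genecontext.annotation import AnnotationSet, GeneModel
from genecontext.feature_io import TrackKey


# --- tiny hand-built annotation --------------------------------------------

ANNOTATION_HEADER = (
    "name\tchrom\tstrand\ttxStart\ttxEnd\texonStarts\texonEnds\tname2\tdescription"
)


def make_table(rows: list[str]) -> str:
    return ANNOTATION_HEADER + "\n" + "\n".join(rows) + "\n"


@pytest.fixture
def annotation_file(tmp_path):
    """Three genes: plus-strand G1, minus-strand G2 (two isoforms), and a
    minus-strand G3 inside G1's downstream flank."""
    rows = [
        "tx1\tchr1\t+\t10000\t20000\t10000,15000,\t12000,20000,\tG1\tfirst gene",
        "tx2a\tchr1\t-\t40000\t45000\t40000,\t45000,\tG2\tshort isoform",
        "tx2b\tchr1\t-\t38000\t46000\t38000,\t46000,\tG2\tlong isoform",
        "tx3\tchr1\t-\t25000\t26000\t25000,\t26000,\tG3\tneighbor",
    ]
    path = tmp_path / "annotation.tsv"
    path.write_text(make_table(rows))
    return path


@pytest.fixture
def plus_gene():
    return GeneModel("G1", "chr1", "+", 1000, 4000, exons=((1000, 4000),))


@pytest.fixture
def minus_gene():
    return GeneModel("G2", "chr1", "-", 2000, 5000, exons=((2000, 5000),))


@pytest.fixture
def key():
    return TrackKey("H1", "H3K4me3")


def single_gene_ann(gene: GeneModel) -> AnnotationSet:
    return AnnotationSet(transcripts={gene.gene_id: [gene]})


# --- independent oracles ----------------------------------------------------

def bases(iv) -> set[int]:
    """The base positions a half-open interval covers (works for tuples and
    RelativeInterval)."""
    if hasattr(iv, "rel_start"):
        return set(range(iv.rel_start, iv.rel_end))
    return set(range(iv[0], iv[1]))


def brute_gap(a, b) -> int:
    """Gap oracle: count the bases strictly between two intervals by
    enumeration (0 when they share or abut)."""
    ba, bb = bases(a), bases(b)
    if ba & bb:
        return 0
    lo = min(max(ba), max(bb))
    hi = max(min(ba), min(bb))
    return len([x for x in range(lo + 1, hi) if x not in ba and x not in bb])


def brute_overlaps_window(iv, window: tuple[int, int]) -> bool:
    """Per-base window-admission oracle."""
    return bool(bases(iv) & set(range(window[0], window[1])))


def brute_count(track, window) -> int:
    return sum(1 for iv in track if brute_overlaps_window(iv, window))


def brute_overlap_filter(a_ivs, b_ivs, window, relation, max_distance) -> bool:
    """All-pairs oracle for the feature-overlap relations."""
    a_in = [p for p in a_ivs if brute_overlaps_window(p, window)]
    b_in = [q for q in b_ivs if brute_overlaps_window(q, window)]
    for p in a_in:
        for q in b_in:
            if relation == "near":
                if brute_gap(p, q) <= max_distance:
                    return True
            elif relation == "a_upstream_of_b":
                if p.rel_end <= q.rel_start and q.rel_start - p.rel_end <= max_distance:
                    return True
            elif relation == "a_downstream_of_b":
                if q.rel_end <= p.rel_start and p.rel_start - q.rel_end <= max_distance:
                    return True
    return False
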