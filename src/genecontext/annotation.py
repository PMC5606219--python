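"""Genome annotation: gene models, identifier resolution, neighbor lookup.

Annotation tables are UCSC Table Browser-style tab-separated exports (one row
per transcript) accompanied by an ID-map JSON document that names the columns
and any alias columns.  All coordinates are 0-based half-open (BED convention)
end to end.  "Largest isoform" collapse keeps, per gene, the transcript with
the greatest genomic span (txEnd - txStart), ties broken by first occurrence
in the file.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

from intervaltree import IntervalTree

__all__ = [
    "GeneModel",
    "AnnotationSet",
    "AnnotationError",
    "DEFAULT_ID_MAP",
    "load_annotation",
    "resolve_genes",
    "find_neighbors",
]


class AnnotationError(ValueError):
    """Fatal annotation-ingest problem (missing column, empty table)."""


#: Column roles for the UCSC refGene/knownGene export dialect.
DEFAULT_ID_MAP = {
    "columns": {
        "gene_id": "name2",
        "transcript_id": "name",
        "chrom": "chrom",
        "strand": "strand",
        "start": "txStart",
        "end": "txEnd",
        "exon_starts": "exonStarts",
        "exon_ends": "exonEnds",
        "description": "description",
    },
    "alias_columns": ["name"],
}

_REQUIRED_ROLES = ("gene_id", "chrom", "strand", "start", "end")


@dataclass(frozen=True)
class GeneModel:
    """One gene (after isoform collapse, one transcript model).

    ``span_start``/``span_end`` and every exon are genomic bp, 0-based
    half-open.  The TSS is ``span_start`` on the + strand and ``span_end``
    (the exclusive bound) on the - strand, so the gene body is exactly
    ``[0, length)`` in TSS-relative coordinates on both strands.
    """

    gene_id: str
    chrom: str
    strand: str
    span_start: int
    span_end: int
    exons: tuple[tuple[int, int], ...] = ()
    aliases: tuple[str, ...] = ()
    description: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (0 <= self.span_start < self.span_end):
            raise ValueError(
                f"invalid span [{self.span_start}, {self.span_end}) for {self.gene_id}"
            )
        prev_end = None
        for s, e in self.exons:
            if not (self.span_start <= s < e <= self.span_end):
                raise ValueError(f"exon [{s}, {e}) outside span of {self.gene_id}")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"exons of {self.gene_id} unsorted or overlapping")
            prev_end = e

    @property
    def length(self) -> int:
        return self.span_end - self.span_start

    @property
    def tss(self) -> int:
        return self.span_start if self.strand == "+" else self.span_end

    def all_ids(self) -> tuple[str, ...]:
        return (self.gene_id, *self.aliases)


@dataclass
class AnnotationSet:
    """Transcript rows grouped by gene plus collapsed-gene indices.

    ``transcripts`` keeps every parsed row (keyed by canonical gene id) so the
    largest-isoform choice is visible and testable; ``genes`` and the two
    indices expose the collapsed view: each identifier resolves to at most one
    gene, and ``chrom_index`` holds every collapsed gene exactly once.
    """

    transcripts: dict[str, list[GeneModel]]
    reports: list[tuple[int, str]] = field(default_factory=list)
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._collapsed: dict[str, GeneModel] = {}
        for gid, models in self.transcripts.items():
            best = max(models, key=lambda g: g.length)  # max() keeps first on ties
            self._collapsed[gid] = best
        self.id_index: dict[str, GeneModel] = {}
        for gene in self._collapsed.values():
            for ident in gene.all_ids():
                self.id_index.setdefault(ident.lower(), gene)
        self.chrom_index: dict[str, IntervalTree] = {}
        for gene in self._collapsed.values():
            tree = self.chrom_index.setdefault(gene.chrom, IntervalTree())
            tree[gene.span_start:gene.span_end] = gene
        if not self.chrom_sizes:
            self.chrom_sizes = {
                chrom: max(iv.end for iv in tree)
                for chrom, tree in self.chrom_index.items()
            }

    @property
    def genes(self) -> list[GeneModel]:
        return list(self._collapsed.values())

    def get(self, name: str) -> GeneModel | None:
        return self.id_index.get(name.strip().lower())

    def __len__(self) -> int:
        return len(self._collapsed)


def _parse_exon_list(text: str) -> tuple[int, ...]:
    # UCSC exon lists are comma-terminated: "100,300," -> (100, 300)
    return tuple(int(tok) for tok in text.strip().split(",") if tok.strip())


def load_annotation(
    table_path: str | Path,
    id_map_path: str | Path | None = None,
    id_map: dict | None = None,
) -> AnnotationSet:
    """Load a tab-separated annotation table into an :class:`AnnotationSet`.

    Multiple transcript rows per gene are retained; isoform collapse (largest
    span) happens when genes are resolved.  A missing required column is fatal
    and the error names the column; rows with unparsable or inconsistent
    coordinates are skipped and reported as ``(line_number, reason)``.
    """
    if id_map is None:
        if id_map_path is not None:
            id_map = json.loads(Path(id_map_path).read_text())
        else:
            id_map = DEFAULT_ID_MAP
    cols = dict(DEFAULT_ID_MAP["columns"], **id_map.get("columns", {}))
    alias_cols = list(id_map.get("alias_columns", DEFAULT_ID_MAP["alias_columns"]))

    with open(table_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for role in _REQUIRED_ROLES:
            if cols[role] not in header:
                raise AnnotationError(
                    f"annotation table is missing required column "
                    f"{cols[role]!r} (role: {role})"
                )
        have_exons = cols["exon_starts"] in header and cols["exon_ends"] in header
        transcripts: dict[str, list[GeneModel]] = {}
        reports: list[tuple[int, str]] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                gid = (row[cols["gene_id"]] or "").strip()
                if not gid:
                    raise ValueError("empty gene id")
                start = int(row[cols["start"]])
                end = int(row[cols["end"]])
                strand = row[cols["strand"]].strip()
                if have_exons:
                    starts = _parse_exon_list(row[cols["exon_starts"]] or "")
                    ends = _parse_exon_list(row[cols["exon_ends"]] or "")
                    if len(starts) != len(ends):
                        raise ValueError("exonStarts/exonEnds length mismatch")
                    exons = tuple(zip(starts, ends))
                else:
                    exons = ()
                aliases = tuple(
                    v.strip()
                    for c in alias_cols
                    if (v := row.get(c) or "").strip() and v.strip() != gid
                )
                desc = (row.get(cols["description"]) or "").strip()
                model = GeneModel(
                    gene_id=gid,
                    chrom=row[cols["chrom"]].strip(),
                    strand=strand,
                    span_start=start,
                    span_end=end,
                    exons=exons,
                    aliases=aliases,
                    description=desc,
                )
            except (ValueError, KeyError, TypeError) as exc:
                reports.append((lineno, str(exc)))
                continue
            transcripts.setdefault(gid, []).append(model)
    if not transcripts:
        raise AnnotationError(f"no parsable rows in {table_path}")
    return AnnotationSet(transcripts=transcripts, reports=reports)


def resolve_genes(
    names: list[str], ann: AnnotationSet
) -> tuple[list[GeneModel], list[str]]:
    """Resolve user identifiers to one collapsed gene model each.

    Matching is case-insensitive and exact.  Input duplicates (by resolved
    gene, or by normalized name when unresolved) are dropped, keeping
    first-seen order.  Unresolvable names are returned, never raised.
    """
    resolved: list[GeneModel] = []
    unresolved: list[str] = []
    seen_genes: set[str] = set()
    seen_names: set[str] = set()
    for raw in names:
        key = raw.strip().lower()
        if not key or key in seen_names:
            continue
        seen_names.add(key)
        gene = ann.get(raw)
        if gene is None:
            unresolved.append(raw.strip())
        elif gene.gene_id not in seen_genes:
            seen_genes.add(gene.gene_id)
            resolved.append(gene)
    return resolved, unresolved


def gene_window(gene: GeneModel, flank_up: int, flank_down: int) -> tuple[int, int]:
    """Genomic analysis window: span extended strand-aware (flank_up on the
    TSS side), clipped at 0."""
    if gene.strand == "+":
        lo, hi = gene.span_start - flank_up, gene.span_end + flank_down
    else:
        lo, hi = gene.span_start - flank_down, gene.span_end + flank_up
    return max(0, lo), hi


def find_neighbors(
    gene: GeneModel, flank_up: int, flank_down: int, ann: AnnotationSet
) -> list[tuple[GeneModel, str]]:
    """Every other gene whose span overlaps the gene's flanked window.

    Returns ``(neighbor, orientation)`` pairs, orientation ``"same"`` or
    ``"opposite"`` by strand comparison, sorted by genomic start for
    determinism.
    """
    if flank_up < 0 or flank_down < 0:
        raise ValueError("flanks must be >= 0")
    lo, hi = gene_window(gene, flank_up, flank_down)
    tree = ann.chrom_index.get(gene.chrom)
    if tree is None:
        return []
    hits = [
        iv.data
        for iv in tree.overlap(lo, hi)
        if iv.data.gene_id != gene.gene_id
    ]
    hits.sort(key=lambda g: (g.span_start, g.span_end, g.gene_id))
    return [
        (g, "same" if g.strand == gene.strand else "opposite") for g in hits
    ]
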