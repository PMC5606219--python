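# Methods

## Model and assumptions

The unit of analysis is the *gene panel*: one gene, reduced to a single
transcript model, with every genomic feature re-expressed in a TSS-anchored,
strand-corrected coordinate frame. The method assumes peak-level input
(called enrichment intervals with a scalar score), not base-resolution
signal; all statements about a mark are therefore statements about interval
geometry — presence, counts, overlaps and distances — never about read
depth.

Coordinates are 0-based half-open (BED convention) everywhere, including
annotation tables. For a minus-strand gene the TSS anchor is `span_end`, the
*exclusive* bound of the half-open span. This is deliberate: with the
reflection `rel = (span_end − end, span_end − start)` the gene body maps to
exactly `[0, L)` on both strands, and genome reflection (the mirror test)
is an exact involution with no ±1 residue.

**Isoform collapse.** "Largest isoform" means maximal genomic span
(`span_end − span_start`), not summed exon length; ties keep the transcript
seen first in the file. The span is what determines the display window and
every window-relative quantity, which makes it the right notion of "largest"
for this analysis; mature-transcript length would change nothing downstream
except the exon track.

**Window admission.** A peak belongs to a panel iff its relative interval
overlaps the window `[−flank_up, L + flank_down)` by at least one base.
Admitted peaks are stored *unclipped* so their true size and score survive;
filters and profiles intersect them with whatever window they interrogate.
Clipping at admission time was rejected because it silently distorts
size/score semantics.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `flank_up`, `flank_down` | 20 000 bp | analysis window beyond the gene body, strand-relative (upstream of TSS / beyond the transcription end) |
| `min_peak_score`, `min_peak_size`, `max_peak_size` | 0 / 0 / ∞ | quality cutoffs applied before mapping |
| `expr_scale_lo`, `expr_scale_hi` | auto | expression display bounds; when unset, the 5th and 95th percentiles (linear interpolation) of all loaded values |
| profile `bin_size` (TSS mode) | 1 000 bp | occupancy bin width, aligned at 0 |
| profile `n_bins` (gene-body mode) | 100 | equal length-fractions of each body |
| overlap `max_distance` | 0 | gap allowance; 0 = overlapping or abutting |
| SVG opacity floor | 0.3 | peak scores map linearly from [min, max] of the loaded data onto [0.3, 1.0] |

Filter conventions, chosen once and used consistently: presence is
`count ≥ 1`, absence `count = 0`; the gap between half-open intervals is
`max(0, max(starts) − min(ends))`, so abutting intervals are "near" at
distance 0; an expression filter fails when the gene has no value for that
cell type (missing data is never treated as zero, and the gene table shows
it as NaN rather than 0).

## Profiles

The profile statistic is per-bin **gene occupancy**: the fraction of
contributing genes with ≥ 1 interval of the track overlapping the bin. This
is binary per gene per bin, so a gene with ten stacked peaks counts once —
appropriate when the input is peak calls rather than signal. An optional
`score_weighted` flag substitutes the gene's maximal overlapping score
(normalized by the track maximum) for the 0/1 indicator. Gene-body mode
rescales each body `[0, L)` into `n_bins` equal fractions using exact
integer arithmetic (`bin j = [jL/n, (j+1)L/n)` compared as cross products),
so a track tiling every body yields identically 1.0 regardless of lengths.
Gene-body profiles cover the body only; flank context is read from the
TSS-mode profile rather than being appended in mixed units.

## Synthetic data

The generator emulates the input classes the tool ingests: a UCSC-style
transcript table plus ID map, BED/broadPeak/narrowPeak peak files, and
two-column expression tables. Genes are placed non-overlapping with random
strands and 1–10 exons; background peaks are Poisson-placed (default 3 per
100 kb — a density comparable to a genome-wide histone-mark peak set) with
uniform sizes 200–2000 bp and scores 100–1000; expression values are
log-normal. One integer seed drives each generator through a single numpy
`Generator` stream with fixed draw order, so every artifact is
bit-reproducible.

`plant_pattern` makes recovery testable as an *exact* set equality: target
genes receive intervals constructed to satisfy the corresponding filter, and
non-target genes have every peak of the pattern's primary mark removed from
their query window (removal, not resampling, so no rejection loops). Two
choices make the guarantee airtight rather than probabilistic:

* the default inter-gene gap (50 kb) exceeds the default window flank
  (20 kb), so a peak planted for one gene cannot enter another gene's
  window;
* planted peaks are tagged by name and exempt from scrubbing.

What the synthetic data deliberately does **not** model: peak-shape and
width distributions of real callers, chromosome-scale covariation of marks,
correlated replicate structure, copy-number or mappability artifacts, and
any coupling between expression and chromatin state except where a pattern
plants it. Passing tests therefore demonstrate the correctness of the
coordinate transform, filter algebra, aggregation and serialization — not
biological discovery performance on real data.

## Numerical and format choices

* Session JSON is canonical — sorted keys, compact separators, Python's
  shortest round-tripping float representation, trailing newline — so
  save→load→save is byte-identical and sessions diff cleanly.
* `max_peak_size = ∞` serializes as `null`; "not provided" numeric peak
  fields (`.` in BED-family columns) are `None`/`null`, never 0. The BED
  score column is the single exception (absent → 0, per the display
  convention); scores above the nominal 1000 cap are accepted with a
  warning because real peak files exceed it.
* Track intervals are stored sorted by `(rel_start, rel_end, score, name)`,
  making panel content independent of input file order.
* Percentiles use linear interpolation between order statistics; a
  degenerate expression scale (all values equal) is widened by
  `max(0.5, 5 %)` for display.
* Session validation is a structural validator that reports every failing
  JSON path; the schema is documented in `session_schema.json`. A future
  major `format_version` is an explicit unsupported-version error, never a
  silent partial parse.
* SVG is produced with the standard library's XML tree; elements carry
  semantic classes (`gene-panel`, `gene-body`, `peak-<mark>`, `neighbor`,
  `expr-swatch`) so figures are styleable and testable.

## Scale of the shipped analyses

The acceptance script mirrors the case-study geometry at its published size
(330 genes, 4 marks × 2 cell types, 20 kb flanks) and runs the invariance
checks at 100 seeds / ≥ 500 panels; the whole script completes in seconds,
so these sizes are simply the study conditions, not a compromise.

## Known limitations

* Filename auto-mapping assumes `cell_mark.ext`; anything else needs a
  manifest entry (the convention is a package choice — no standard exists).
* Neighbor lookup returns collapsed genes only; alternative isoforms of a
  neighbor are not reported separately.
* `set_flanks` rebuilds panels from the original inputs; it is defined (and
  tested) as exactly equivalent to a fresh build, which costs a re-scan
  rather than an incremental update.
* Expression join is by exact (case-insensitive) identifier/alias match;
  no fuzzy ID reconciliation across annotation releases.
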