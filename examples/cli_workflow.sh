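#!/usr/bin/env bash
# Full shell workflow: simulate a dataset with a planted bivalent pattern,
# map it to TSS-relative panels, filter with the written chain, report.
set -euo pipefail

out=$(mktemp -d)
echo "working in $out"

genecontext simulate --outdir "$out/data" --seed 5 --n-genes 40 \
    --plant-bivalent 6

args=(--annotation "$out/data/annotation.tsv"
      --id-map "$out/data/id_map.json"
      --genes "$out/data/genes.txt"
      --expression "cellA=$out/data/expression/cellA.tsv"
      --expression "cellB=$out/data/expression/cellB.tsv"
      --outdir "$out/run")
for f in "$out"/data/peaks/*.narrowPeak; do args+=(--feature "$f"); done
genecontext map "${args[@]}"

genecontext filter --session "$out/run/session.json" \
    --chain "$out/data/chain.json" --summary "$out/run/summary.txt"

genecontext report --session "$out/run/session.json" \
    --outdir "$out/report" --filtered-only

genecontext session inspect "$out/run/session.json"
ls "$out/report"
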