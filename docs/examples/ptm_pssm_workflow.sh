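#!/bin/sh
# PTM-filtered PSSM training workflow, end to end from the shell:
# generate a synthetic dataset with planted phospho-motif instances and a
# matching modification-site table, keep only PTM-connected matches, train
# a PSSM on them, and measure the target/decoy ratio gain of a score
# threshold on a fresh search.
set -e

PATTERN='(.)(.)([^IRFW])([ST])([ILMVFWY])([ILMVFWY])(.)'
OUT=example_out
mkdir -p "$OUT"

slimscan fixtures --n-proteins 100 --length 300 --seed 5 \
    --plant-pattern KKDSLLE --plant-fraction 0.5 --out-dir "$OUT/fix"

# search with the PTM connection, keeping only phosphorylated matches,
# and export them as a training FASTA
slimscan search --fasta "$OUT/fix/proteome.fasta" --pattern "$PATTERN" \
    --ptm-psp "$OUT/fix/ptm_psp.tsv" --modification phosphorylation \
    --ptm-scope 4 --filter-without-connections \
    --out "$OUT/train_matches.tsv" --out-fasta "$OUT/train_instances.fasta"

slimscan train-pssm --instances "$OUT/train_instances.fasta" \
    --pattern "$PATTERN" --out "$OUT/model.pssm"

slimscan decoy --fasta "$OUT/fix/proteome.fasta" --seed 6 \
    --out "$OUT/decoy.fasta"

slimscan search --fasta "$OUT/fix/proteome.fasta" --pattern "$PATTERN" \
    --pssm "$OUT/model.pssm" --out "$OUT/target_scored.tsv"
slimscan search --fasta "$OUT/decoy.fasta" --pattern "$PATTERN" \
    --pssm "$OUT/model.pssm" --out "$OUT/decoy_scored.tsv"

N_AA=$(grep -v '^>' "$OUT/fix/proteome.fasta" | tr -d '\n' | wc -c)
slimscan enrich --target "$OUT/target_scored.tsv" \
    --decoy "$OUT/decoy_scored.tsv" \
    --n-target-aa "$N_AA" --n-decoy-aa "$N_AA" \
    --thresholds 0,25,50,75 --out "$OUT/enrichment.tsv"

cat "$OUT/enrichment.tsv"
cat "$OUT/enrichment.tsv.curve.tsv"
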