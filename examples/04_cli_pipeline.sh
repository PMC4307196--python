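#!/usr/bin/env bash
# The same pipeline from the shell: simulate a labeled community, build
# a model, classify the reads, and inspect the model file.
set -euo pipefail
workdir=$(mktemp -d)

hyperbin simulate \
    --out-fasta "$workdir/community.fa" \
    --out-lineages "$workdir/community.tsv" \
    --n-phyla 4 --orders-per-phylum 3 --reads-per-taxon 100 \
    --read-length 1000 --separation 5.0 --seed 1

hyperbin build-model "$workdir/community.fa" "$workdir/community.tsv" \
    --out "$workdir/model.h5" --k 4 --s 8 --r 3 \
    --labeling pur --alpha 0.8 --seed 1

hyperbin classify "$workdir/community.fa" "$workdir/model.h5" \
    --out-assignments "$workdir/assignments.tsv" \
    --out-krona "$workdir/krona.txt"

hyperbin inspect-model "$workdir/model.h5"

echo "first assignments:"
head -n 3 "$workdir/assignments.tsv"
rm -rf "$workdir"
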