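#!/usr/bin/env bash
# End-to-end command-line workflow: simulate, detect, benchmark.
# Run from the repository root:  bash examples/05_cli_workflow.sh
set -euo pipefail

workdir=$(mktemp -d)
trap 'rm -rf "$workdir"' EXIT

# 1. simulate a diagnosed/reference pair with a shift after sample 161
hwks simulate --n 512 --k 161 --v 3 --seed 7 --out "$workdir/z.txt" --ref "$workdir/x.txt"

# 2. tree detector (needs the reference) and an exhaustive baseline
hwks detect --input "$workdir/z.txt" --reference "$workdir/x.txt" --method hwks
hwks detect --input "$workdir/z.txt" --method ks

# 3. a small custom benchmark: two positions at N = 64, 20 replicates
hwks bench --positions "64:9,33" --methods hwks,ks --reps 20 --seed 0 \
    --out "$workdir/bench.tsv"
cat "$workdir/bench.tsv"

# 4. the evenly spread test positions used by the multi-position design
hwks table3-positions --n 256
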