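#!/usr/bin/env bash
# End-to-end shell workflow: simulate a small phantom cohort with rendered
# clips, measure one clip from its pixels, and build the study report.
set -euo pipefail

out=$(mktemp -d)

diamotion simulate --seed 7 --out "$out/sim" --n-subjects 2 --n-breaths 1
clip=$(ls "$out"/sim/clips/*.tif | head -1)

diamotion measure --input "$clip" --method all --out "$out/results.csv"
cat "$out/results.csv"

diamotion stats --table "$out/sim/study_table.csv" \
    --ratings "$out/sim/ratings_area.csv" \
    --out "$out/report"
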