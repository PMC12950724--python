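#!/usr/bin/env python
"""Impute and diagnose the cohort with all three instruments.

Mode-imputes the masked categorical baseline fields, applies PG-SGA, ESPEN
and GLIM to every patient, and prints the per-tool prevalence table (the
baseline-characteristics view of nutritional status). In this synthetic
cohort, as in the registry it emulates, ESPEN diagnoses malnutrition far
more often than PG-SGA or GLIM.
"""

import argparse
from pathlib import Path

from nutrilcm.cohort import MASKABLE_COLUMNS, frame_to_records, read_cohort_csv
from nutrilcm.criteria import apply_all, mode_impute
from nutrilcm.pipeline import prevalence_table

parser = argparse.ArgumentParser()
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

df = read_cohort_csv(args.results / "cohort.csv")
df = mode_impute(df, [c for c in MASKABLE_COLUMNS if c in df.columns])
records = frame_to_records(df)
dx = apply_all(records)
dx.to_csv(args.results / "diagnoses.csv", index=False)

print(f"diagnosed {len(dx)} patients")
for tool, row in prevalence_table(dx).items():
    print(f"  {tool}: {row['malnourished_n']}/{row['denominator']} malnourished ({row['percent']}%)")
print(f"wrote {args.results/'diagnoses.csv'}")
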