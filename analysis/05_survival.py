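#!/usr/bin/env python
"""Survival stratified by nutritional status, per instrument.

Kaplan-Meier curves with log-rank tests for the well/malnourished split of
each tool, plus severity-graded analyses for PG-SGA and GLIM (ESPEN
defines no severity grades, so it is analysed only as binary). Cox
proportional-hazards fits give the hazard ratios. Curve CSVs and a JSON
summary go to the results directory.
"""

import argparse
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from nutrilcm.cohort import read_cohort_csv
from nutrilcm.pipeline import _jsonable
from nutrilcm.survival import survival_by_nutrition

parser = argparse.ArgumentParser()
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

df = read_cohort_csv(args.results / "cohort.csv")
dx = pd.read_csv(args.results / "diagnoses.csv")

payload = {}
binary = survival_by_nutrition(df, dx, grouping="binary")
severity = survival_by_nutrition(df, dx, grouping="severity", tools=("PGSGA", "GLIM"))

for label, res in (("binary", binary), ("severity", severity)):
    payload[label] = {}
    print(f"\n{label} grouping:")
    for tool, row in res.items():
        lr = row["log_rank"]
        fit = row["cox"]
        medians = {g: c.median for g, c in row["curves"].items()}
        print(f"  {tool}: log-rank chi2={lr.statistic:.2f} (df={lr.df}, p={lr.p_value:.4g})")
        for rec in fit.to_frame().to_dict(orient="records"):
            print(
                f"    {rec['covariate']}: HR {rec['hr']:.2f} "
                f"({rec['ci_lower']:.2f}-{rec['ci_upper']:.2f}), p={rec['p_value']:.4g}"
            )
        payload[label][tool] = {
            "log_rank": asdict(lr),
            "cox": fit.to_frame().to_dict(orient="records"),
            "median_survival_months": medians,
        }
        for g, curve in row["curves"].items():
            curve.to_frame().to_csv(
                args.results / f"km_{label}_{tool}_{g}.csv", index=False
            )

with open(args.results / "survival.json", "w") as fh:
    json.dump(payload, fh, indent=2, default=_jsonable)
print(f"\nwrote {args.results/'survival.json'} and per-group KM curve CSVs")
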