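#!/usr/bin/env python
"""Validate the estimation machinery by simulation.

Three studies: (1) latent class recovery — 50 cohorts of n=3,182 simulated
at the estimated accuracies and refitted with flat priors, reporting 95%
CrI coverage and posterior-mean bias per parameter; (2) the log-rank
engine's type-I error under equal hazards; (3) Cox recovery of the true
severity hazard ratios. This is the evidence that the pipeline's answers
can be trusted at the study's scale.
"""

import argparse
import json
from pathlib import Path

from nutrilcm.evaluation import cox_hr_recovery, lcm_recovery_study, logrank_type1_error

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--results", type=Path, default=Path("results"))
parser.add_argument("--replicates", type=int, default=50)
args = parser.parse_args()

rec = lcm_recovery_study(n_replicates=args.replicates, seed=args.seed)
print(f"latent class recovery ({rec.n_replicates} replicates, n=3,182):")
for name, cov, bias in zip(rec.names, rec.coverage, rec.bias):
    print(f"  {name}: coverage {cov:.0%}, bias {bias:+.4f}")

t1 = logrank_type1_error(n_replicates=1000, seed=args.seed + 2)
print(f"log-rank type-I error at alpha=0.05: {t1:.3f} (1000 replicates)")

cox = cox_hr_recovery(n_seeds=20, seed=args.seed + 3)
print(
    f"Cox HR recovery over 20 seeds: severe {cox['hr_severe_mean']:.3f} "
    f"(true 1.50), moderate {cox['hr_moderate_mean']:.3f} (true 1.29)"
)

args.results.mkdir(parents=True, exist_ok=True)
with open(args.results / "operating_characteristics.json", "w") as fh:
    json.dump(
        {
            "lcm_recovery": {
                "coverage": dict(zip(rec.names, rec.coverage.tolist())),
                "bias": dict(zip(rec.names, rec.bias.tolist())),
                "n_replicates": rec.n_replicates,
            },
            "logrank_type1_error": t1,
            "cox_hr_recovery": cox,
        },
        fh,
        indent=2,
    )
print(f"wrote {args.results/'operating_characteristics.json'}")
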