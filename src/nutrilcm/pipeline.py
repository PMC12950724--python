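"""Pipeline orchestration: simulate -> impute -> diagnose -> cross-classify
-> latent class fit -> diagnostics -> discrepancy -> survival -> report.

All randomness flows from the seeds in :class:`RunConfig`; a fixed config
yields a byte-identical report. The consolidated :class:`RunReport` mirrors
the shape of a clinical baseline-characteristics paper: cohort summary,
per-tool prevalence, posterior diagnostic accuracy with a convergence
verdict, discrepancy attribution, and survival stratification.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import criteria as criteria_mod
from . import discrepancy as discrepancy_mod
from . import latent_class as lcm
from . import survival as survival_mod
from .cohort import CohortSpec, LatentCohort
from .criteria import TEST_ORDER, ValidationError

__all__ = [
    "RunConfig",
    "run_pipeline",
    "prevalence_table",
    "complete_case_subset",
    "BASELINE_COLUMNS",
]

log = logging.getLogger("nutrilcm")

#: Baseline characteristic fields used for complete-case filtering.
BASELINE_COLUMNS = [
    "age",
    "sex",
    "bmi",
    "wl_3mo_pct",
    "wl_6mo_pct",
    "wl_beyond_6mo_pct",
    "wl_any_time_pct",
    "muscle_reduced_anthro",
    "nrs_positive",
    "reduced_intake",
]


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``input_csv`` / ``simulation`` must be set. ``seeds``
    must have one entry per chain.
    """

    input_csv: Optional[str] = None
    simulation: Optional[CohortSpec] = None
    chains: int = 3
    iterations: int = 20_000
    burn_in: int = 5_000
    seeds: Optional[tuple[int, ...]] = None
    priors: lcm.LCMPriors = field(default_factory=lcm.LCMPriors)
    impute: bool = True
    complete_case: bool = False
    adjust_covariates: tuple[str, ...] = ()
    out_dir: Optional[str] = None
    rhat_threshold: float = 1.1

    def validate(self) -> None:
        if (self.input_csv is None) == (self.simulation is None):
            raise ValidationError("exactly one of input_csv / simulation must be given")
        if self.seeds is None:
            self.seeds = tuple(range(1, self.chains + 1))
        if len(self.seeds) != self.chains:
            raise ValidationError(
                f"need one seed per chain: {self.chains} chains, {len(self.seeds)} seeds"
            )
        if self.chains < 2:
            raise ValidationError(
                "convergence diagnostics need >= 2 chains; refusing chains=1"
            )


def prevalence_table(diagnoses: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Per-tool malnutrition counts and percentages (one decimal, half-up)."""
    n = len(diagnoses)
    out = {}
    for tool, col in zip(TEST_ORDER, ("pgsga_pos", "espen_pos", "glim_pos")):
        c = int(diagnoses[col].sum())
        out[tool] = {
            "malnourished_n": c,
            "denominator": n,
            "percent": discrepancy_mod.round_half_up_pct(c, n),
        }
    return out


def complete_case_subset(cohort_df: pd.DataFrame) -> pd.DataFrame:
    """Drop every record with any missing baseline field."""
    cols = [c for c in BASELINE_COLUMNS if c in cohort_df.columns]
    mask = cohort_df[cols].notna().all(axis=1)
    out = cohort_df[mask].reset_index(drop=True)
    if out.empty:
        log.warning("complete-case subset is empty")
    return out


def cohort_summary(cohort_df: pd.DataFrame) -> dict:
    """Baseline characteristics table: counts and percentages per level."""
    n = len(cohort_df)
    pct = lambda c: discrepancy_mod.round_half_up_pct(c, n)
    age = cohort_df["age"].astype(float)
    summary = {
        "n": n,
        "age_ge_65": {"n": int((age >= 65).sum()), "percent": pct(int((age >= 65).sum()))},
        "male": {
            "n": int((cohort_df["sex"] == "male").sum()),
            "percent": pct(int((cohort_df["sex"] == "male").sum())),
        },
        "nrs_positive": {
            "n": int((cohort_df["nrs_positive"] == True).sum()),  # noqa: E712 (NaN-safe)
            "percent": pct(int((cohort_df["nrs_positive"] == True).sum())),  # noqa: E712
        },
        "median_followup_months": float(np.median(cohort_df["followup_months"].astype(float)))
        if cohort_df["followup_months"].notna().all()
        else None,
    }
    return summary


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise ValidationError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return the consolidated report dict.

    Stage failures abort with the stage name attached. A latent-class fit
    whose R-hat exceeds the threshold is flagged ``"not converged"`` in the
    report; the pipeline still completes (exit code 3 at the CLI).
    """
    config.validate()
    report: dict = {"provenance": {
        "seeds": list(config.seeds),
        "chains": config.chains,
        "iterations": config.iterations,
        "burn_in": config.burn_in,
        "test_order": list(TEST_ORDER),
    }}

    # --- acquire cohort ---
    if config.simulation is not None:
        spec = config.simulation
        cohort = cohort_mod.generate_mechanistic_cohort(spec)
        cohort = cohort_mod.attach_survival(cohort, spec)
        df = cohort_mod.cohort_to_frame(cohort)
        if spec.missing_fraction > 0:
            df = cohort_mod.inject_missingness(df, spec.missing_fraction, spec.seed + 7)
        report["provenance"]["simulation_seed"] = spec.seed
    else:
        df = cohort_mod.read_cohort_csv(config.input_csv)

    if config.complete_case:
        n_before = len(df)
        df = complete_case_subset(df)
        report["complete_case"] = {"n_before": n_before, "n_after": len(df)}
    elif config.impute:
        maskable = [c for c in cohort_mod.MASKABLE_COLUMNS if c in df.columns]
        n_missing = int(df[maskable].isna().sum().sum())
        if n_missing:
            df = criteria_mod.mode_impute(df, maskable)
        report["imputation"] = {"cells_imputed": n_missing}

    records = cohort_mod.frame_to_records(df)
    report["cohort_summary"] = cohort_summary(df)

    # --- diagnose ---
    diagnoses = criteria_mod.apply_all(records)
    report["prevalence"] = prevalence_table(diagnoses)

    # --- cross-classify and fit the latent class model ---
    panels = diagnoses[["pgsga_pos", "espen_pos", "glim_pos"]].to_numpy()
    table = lcm.build_cross_class(panels, k_tests=3)
    report["cross_class_counts"] = {
        format(i, "03b")[::-1]: int(c) for i, c in enumerate(table.counts)
    }
    draws = lcm.gibbs_fit(
        table,
        config.priors,
        chains=config.chains,
        iterations=config.iterations,
        burn_in=config.burn_in,
        seeds=config.seeds,
    )
    draws = lcm.enforce_orientation(draws)
    summary = lcm.summarize(draws)
    diag = lcm.gelman_rubin(draws)
    ok = lcm.converged(diag, config.rhat_threshold)
    report["latent_class"] = {
        "posterior": summary,
        "convergence": diag,
        "converged": ok,
        "verdict": "converged" if ok else "not converged",
        "orientation_flipped_fraction": draws.orientation_flipped_fraction,
    }

    # --- discrepancy attribution ---
    disc = discrepancy_mod.build_report(df, records, diagnoses)
    report["discrepancy"] = {
        "group_sizes": disc.group_sizes,
        "pathway_counts": disc.pathway_counts,
        "pathway_percentages": disc.pathway_pcts,
        "characteristics": disc.characteristics.to_dict(orient="records"),
    }

    # --- survival ---
    surv = survival_mod.survival_by_nutrition(
        df, diagnoses, grouping="binary", adjust_covariates=config.adjust_covariates
    )
    surv_report = {}
    for tool, res in surv.items():
        fit = res["cox"]
        surv_report[tool] = {
            "log_rank": asdict(res["log_rank"]) if res["log_rank"] else None,
            "cox": fit.to_frame().to_dict(orient="records"),
            "median_survival": {
                g: c.median for g, c in res["curves"].items()
            },
        }
    report["survival"] = surv_report

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort_mod.write_cohort_csv(df, out / "cohort.csv")
        diagnoses.to_csv(out / "diagnoses.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        with open(out / "report.txt", "w") as fh:
            fh.write(render_text_report(report))
    return report


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, float) and not np.isfinite(x):
        return str(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def render_text_report(report: dict) -> str:
    """Human-readable summary of a pipeline run."""
    lines = ["nutrilcm pipeline report", "=" * 40, ""]
    cs = report.get("cohort_summary", {})
    lines.append(f"Cohort: n = {cs.get('n')}")
    for key in ("age_ge_65", "male", "nrs_positive"):
        if key in cs:
            lines.append(f"  {key}: {cs[key]['n']} ({cs[key]['percent']}%)")
    lines.append("")
    lines.append("Prevalence of malnutrition by tool:")
    for tool, row in report.get("prevalence", {}).items():
        lines.append(
            f"  {tool}: {row['malnourished_n']}/{row['denominator']} ({row['percent']}%)"
        )
    lc = report.get("latent_class", {})
    if lc:
        lines.append("")
        lines.append(f"Latent class model ({lc.get('verdict')}):")
        for name, s in lc.get("posterior", {}).items():
            lines.append(
                f"  {name}: {s['mean']:.3f} (95% CrI {s['cri_lower']:.3f}-{s['cri_upper']:.3f})"
            )
    disc = report.get("discrepancy", {})
    if disc:
        lines.append("")
        lines.append(f"ESPEN/GLIM concordance groups: {disc['group_sizes']}")
        lines.append("ESPEN-only pathway attribution:")
        for k, v in disc["pathway_counts"].items():
            lines.append(f"  {k}: {v} ({disc['pathway_percentages'][k]}%)")
    sv = report.get("survival", {})
    if sv:
        lines.append("")
        lines.append("Survival by nutrition (binary):")
        for tool, row in sv.items():
            lr = row["log_rank"]
            p = f"{lr['p_value']:.4g}" if lr else "n/a"
            hr = row["cox"][0]
            lines.append(
                f"  {tool}: log-rank p = {p}; HR = {hr['hr']:.2f} "
                f"(95% CI {hr['ci_lower']:.2f}-{hr['ci_upper']:.2f})"
            )
    return "\n".join(lines) + "\n"
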