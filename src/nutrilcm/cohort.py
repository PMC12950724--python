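"""Synthetic colorectal-cancer cohorts with a latent malnutrition state.

The patient-level registry behind this analysis is not public, so every
downstream stage is exercised on simulated cohorts that share its
statistical structure. Two generators are provided:

* :func:`generate_latent_class_cohort` draws test results directly from
  the latent class model (latent Bernoulli status; per-test results
  conditionally independent given status with the specified Se/Sp). This
  gives *exact* conditional independence, which is what the Bayesian
  latent class fit assumes and what its validation needs.
* :func:`generate_mechanistic_cohort` draws realistic covariates (age,
  sex, BMI, windowed weight-loss percentages, FFMI, muscle flag, PG-SGA
  score, risk-screen flag) whose joint distribution makes the three rule
  engines fire at plausible rates — including the BMI 18.5-20 band and
  the "historic weight loss only" profile that drive the ESPEN/GLIM
  discordance. Test results then come from applying the criteria module,
  so conditional independence is only approximate here.

Default sizes and rates emulate the study cohort: n = 3,182 patients,
~58.5% aged >=65, ~59.7% male, latent prevalence 0.25, exponential
survival in months with hazard ratios 1.29 (moderate) and 1.50 (severe)
for malnutrition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .criteria import PatientRecord, Sex, ValidationError

__all__ = [
    "CohortSpec",
    "LatentCohort",
    "generate_latent_class_cohort",
    "generate_mechanistic_cohort",
    "attach_survival",
    "inject_missingness",
    "cohort_to_frame",
    "frame_to_records",
    "write_cohort_csv",
    "read_cohort_csv",
    "COHORT_COLUMNS",
]

#: Frozen cohort CSV schema, one row per patient; missing-value token "".
COHORT_COLUMNS = [
    "id",
    "age",
    "sex",
    "bmi",
    "wl_3mo_pct",
    "wl_6mo_pct",
    "wl_beyond_6mo_pct",
    "wl_any_time_pct",
    "ffmi",
    "muscle_reduced_anthro",
    "pgsga_score",
    "nrs_positive",
    "reduced_intake",
    "has_cancer",
    "followup_months",
    "event",
]

#: Categorical baseline fields eligible for MCAR masking. Survival fields
#: and the PG-SGA score (a test input) are never masked.
MASKABLE_COLUMNS = ["sex", "muscle_reduced_anthro", "reduced_intake", "nrs_positive"]

_SEVERE_SHARE = 0.4  # share of malnourished patients graded severe


@dataclass
class CovariateConfig:
    """Distribution settings for the mechanistic covariate draws.

    Age is normal (mean 67, sd 10, clipped to 25-95), putting ~58% of the
    cohort at >=65. BMI is normal within latent class; weight-loss
    magnitudes are gamma-distributed among the malnourished with severity-
    dependent means. ``muscle_ffmi_agreement`` is the probability that the
    anthropometric muscle flag agrees with the FFMI cutoff.
    """

    age_mean: float = 67.0
    age_sd: float = 10.0
    age_range: tuple[float, float] = (25.0, 95.0)
    male_fraction: float = 0.597
    bmi_mean_well: float = 22.2
    bmi_sd_well: float = 2.5
    bmi_mean_mal: float = 20.2
    bmi_sd_mal: float = 2.3
    bmi_range: tuple[float, float] = (12.0, 45.0)
    #: kg/m2 of current BMI lost per percent of 6-month weight loss
    bmi_wl_slope: float = 0.28
    #: global multiplier on every weight-loss percentage (0 = no loss)
    wl_scale: float = 1.0
    ffmi_mean_male: float = 19.3
    ffmi_mean_female: float = 17.0
    ffmi_sd: float = 1.3
    ffmi_shift_mal: float = -0.5
    ffmi_wl_slope: float = 0.15
    ffmi_available: float = 0.85
    muscle_ffmi_agreement: float = 0.9
    muscle_false_flag: float = 0.015
    nrs_positive_mal: float = 0.95
    nrs_positive_well: float = 0.70
    reduced_intake_mal: float = 0.7
    reduced_intake_well: float = 0.15
    # probability a patient's largest historic loss exceeds the windowed ones
    historic_loss_prob: float = 0.30

    def validate(self) -> None:
        if self.wl_scale < 0:
            raise ValidationError(f"covariate_config.wl_scale must be >= 0, got {self.wl_scale}")
        for name in ("age_range", "bmi_range"):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ValidationError(f"covariate_config.{name} is inverted: ({lo}, {hi})")
        for name in (
            "male_fraction",
            "ffmi_available",
            "muscle_ffmi_agreement",
            "muscle_false_flag",
            "nrs_positive_mal",
            "nrs_positive_well",
            "reduced_intake_mal",
            "reduced_intake_well",
            "historic_loss_prob",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"covariate_config.{name} must be in [0, 1], got {v}")


@dataclass
class CohortSpec:
    """Everything needed to generate one synthetic cohort.

    ``se``/``sp`` parameterise the latent-class generator (test order
    PG-SGA, ESPEN, GLIM); they default to the sensitivities/specificities
    this analysis estimates for the three instruments. Rates are per month.
    """

    n_patients: int = 3182
    prevalence: float = 0.25
    se: tuple[float, ...] = (0.80, 0.84, 0.57)
    sp: tuple[float, ...] = (0.99, 0.43, 0.81)
    hazard_scale: float = float(np.log(2) / 60.0)  # baseline median OS 60 months
    hr_moderate: float = 1.29
    hr_severe: float = 1.50
    censoring_rate: float = float(np.log(2) / 50.0)
    weibull_shape: float = 1.0  # 1 = exponential baseline
    covariate_config: CovariateConfig = field(default_factory=CovariateConfig)
    missing_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValidationError(f"n_patients must be >= 1, got {self.n_patients}")
        if not 0 <= self.prevalence <= 1:
            raise ValidationError(f"prevalence must be in [0, 1], got {self.prevalence}")
        if len(self.se) != len(self.sp):
            raise ValidationError("se and sp must have the same length")
        for name, vec in (("se", self.se), ("sp", self.sp)):
            for k, v in enumerate(vec):
                if not 0 <= v <= 1:
                    raise ValidationError(f"{name}[{k}] must be in [0, 1], got {v}")
        for k, (a, b) in enumerate(zip(self.se, self.sp)):
            if a + b <= 1:
                raise ValidationError(
                    f"se[{k}] + sp[{k}] must exceed 1 (orientation), got {a} + {b}"
                )
        for name in ("hazard_scale", "hr_moderate", "hr_severe", "censoring_rate", "weibull_shape"):
            v = getattr(self, name)
            if name == "censoring_rate":
                if v < 0:
                    raise ValidationError(f"{name} must be >= 0, got {v}")
            elif v <= 0:
                raise ValidationError(f"{name} must be > 0, got {v}")
        if not 0 <= self.missing_fraction < 1:
            raise ValidationError(
                f"missing_fraction must be in [0, 1), got {self.missing_fraction}"
            )
        self.covariate_config.validate()


@dataclass
class LatentCohort:
    """Generated records plus the latent truth used to create them."""

    records: list[PatientRecord]
    true_status: np.ndarray
    true_severity: list[str]
    panels: Optional[np.ndarray] = None  # (n, K) binary, latent-class mode only

    def __post_init__(self) -> None:
        n = len(self.records)
        self.true_status = np.asarray(self.true_status, dtype=int)
        if len(self.true_status) != n or len(self.true_severity) != n:
            raise ValidationError("truth vectors must match the number of records")
        for s, sev in zip(self.true_status, self.true_severity):
            if (s == 0) != (sev == "well"):
                raise ValidationError("severity must be 'well' exactly when status is 0")

    @property
    def n(self) -> int:
        return len(self.records)


def _draw_severity(rng: np.random.Generator, status: np.ndarray) -> list[str]:
    sev = []
    for s in status:
        if s == 0:
            sev.append("well")
        else:
            sev.append("severe" if rng.random() < _SEVERE_SHARE else "moderate")
    return sev


def generate_latent_class_cohort(spec: CohortSpec) -> LatentCohort:
    """Cohort drawn directly from the latent class model.

    Latent status ~ Bernoulli(prevalence); test k is positive with
    probability se_k among the diseased and 1 - sp_k among the healthy,
    independently across tests given status. Covariates are filled with
    neutral placeholder values — only the test panels carry signal here.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, K = spec.n_patients, len(spec.se)
    status = (rng.random(n) < spec.prevalence).astype(int)
    se = np.asarray(spec.se)
    sp = np.asarray(spec.sp)
    p_pos = np.where(status[:, None] == 1, se[None, :], 1 - sp[None, :])
    panels = (rng.random((n, K)) < p_pos).astype(int)
    severity = _draw_severity(rng, status)
    records = [
        PatientRecord(
            id=f"P{i:05d}",
            age=60.0,
            sex=Sex.MALE,
            bmi=23.0,
            pgsga_score=0,
            nrs_positive=True,
        )
        for i in range(n)
    ]
    return LatentCohort(records, status, severity, panels=panels)


def generate_mechanistic_cohort(spec: CohortSpec) -> LatentCohort:
    """Cohort with internally consistent covariates that drive the rules.

    Malnourished patients get lower BMI, larger recent weight losses
    (severity-dependent), lower FFMI and higher PG-SGA scores; a
    configurable fraction of patients carry only *historic* weight loss
    (>10% at some time but little in the GLIM windows), which is what
    makes ESPEN positive where GLIM is not. The anthropometric muscle flag
    agrees with the FFMI cutoff at ``muscle_ffmi_agreement``.
    """
    spec.validate()
    cfg = spec.covariate_config
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    status = (rng.random(n) < spec.prevalence).astype(int)
    severity = _draw_severity(rng, status)

    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), *cfg.age_range)
    male = rng.random(n) < cfg.male_fraction

    # Unintentional weight-loss history, drawn per patient as one of four
    # temporal profiles: "stable" (no meaningful loss), "progressive"
    # (ongoing loss captured by the 6-month window), "recent" (rapid loss
    # concentrated in the last 3 months, with partial earlier regain so the
    # net 6-month figure is smaller), and "historic" (>10% lost at some
    # point in the past, mostly outside both 6-month windows). The recent
    # and historic profiles are what ESPEN's clauses capture and GLIM's
    # windows can miss.
    wl3 = np.zeros(n)
    wl6 = np.zeros(n)
    wl_beyond = np.zeros(n)
    wl_any = np.zeros(n)
    profile_cuts = {
        # cumulative probabilities: stable, progressive, recent, historic
        "well": (0.50, 0.70, 0.82, 1.0),
        "moderate": (0.10, 0.45, 0.75, 1.0),
        "severe": (0.0, 0.70, 0.85, 1.0),
    }
    for i in range(n):
        sev = severity[i]
        cuts = profile_cuts[sev]
        u = rng.random()
        if u < cuts[0]:
            pass  # stable: all zeros
        elif u < cuts[1]:  # progressive
            if sev == "well":
                wl6[i] = rng.gamma(1.8, 1.8)
            elif sev == "moderate":
                wl6[i] = 5.0 + rng.gamma(1.5, 1.5)
            else:
                wl6[i] = 10.0 + rng.gamma(2.0, 2.5)
            wl3[i] = wl6[i] * rng.uniform(0.7, 0.95)
            if rng.random() < 0.3:
                wl_beyond[i] = wl6[i] * rng.uniform(0.8, 1.6)
        elif u < cuts[2]:  # recent rapid loss, net 6-month figure smaller
            if sev == "well":
                wl3[i] = rng.gamma(2.0, 1.6)
            elif sev == "moderate":
                wl3[i] = 5.5 + rng.gamma(1.5, 1.5)
            else:
                wl3[i] = 10.0 + rng.gamma(2.0, 2.0)
            wl6[i] = wl3[i] * rng.uniform(0.35, 0.85)
        else:  # historic loss, windows quiet
            base = 10.0 + rng.gamma(2.0, 2.0) if sev != "well" else 10.0 + rng.gamma(1.5, 1.5)
            wl_any[i] = base
            wl6[i] = rng.gamma(1.5, 1.2)
            wl3[i] = wl6[i] * rng.uniform(0.3, 0.8)
    wl_any = np.maximum.reduce([wl3, wl6, wl_beyond, wl_any])
    wl3 *= cfg.wl_scale
    wl6 *= cfg.wl_scale
    wl_beyond *= cfg.wl_scale
    wl_any *= cfg.wl_scale

    # current BMI and FFMI reflect the weight already lost
    bmi = np.where(
        status == 1,
        rng.normal(cfg.bmi_mean_mal, cfg.bmi_sd_mal, n),
        rng.normal(cfg.bmi_mean_well, cfg.bmi_sd_well, n),
    )
    bmi = np.clip(bmi - cfg.bmi_wl_slope * np.maximum(wl3, wl6), *cfg.bmi_range)

    ffmi_base = np.where(male, cfg.ffmi_mean_male, cfg.ffmi_mean_female)
    ffmi = rng.normal(ffmi_base + np.where(status == 1, cfg.ffmi_shift_mal, 0.0), cfg.ffmi_sd)
    ffmi = ffmi - cfg.ffmi_wl_slope * wl6
    ffmi_cut = np.where(male, 17.0, 15.0)
    low_ffmi = ffmi < ffmi_cut
    # anthropometric flag: detects low FFMI at the agreement rate, with a
    # small false-flag rate among patients whose FFMI is normal
    muscle_flag = np.where(
        low_ffmi,
        rng.random(n) < cfg.muscle_ffmi_agreement,
        rng.random(n) < cfg.muscle_false_flag,
    )
    ffmi_avail = rng.random(n) < cfg.ffmi_available

    # Cancer patients whose phenotype is already compromised (underweight,
    # muscle-depleted, or losing weight) nearly always report a >10% loss
    # at *some* point in their history; give them one where the windowed
    # fields alone would miss it. This mirrors the registry pattern where
    # the broad any-time clause captured essentially every phenotypically
    # affected patient.
    no_clause = (wl_any <= 10) & (wl3 <= 5)
    marker = (bmi < 20.0) | (wl6 > 5) | low_ffmi | muscle_flag
    give = no_clause & marker & (rng.random(n) < cfg.historic_loss_prob + 0.45)
    wl_any = np.where(give, (10.0 + rng.gamma(1.5, 1.8, n)) * cfg.wl_scale, wl_any)

    # PG-SGA total score: near zero among the well, banded by severity otherwise
    score = np.zeros(n, dtype=int)
    for i in range(n):
        if severity[i] == "well":
            score[i] = rng.poisson(0.25)
        elif severity[i] == "moderate":
            score[i] = int(np.clip(2 + rng.poisson(2.5), 2, 8)) if rng.random() < 0.8 else rng.poisson(0.5)
        else:
            score[i] = 9 + rng.poisson(2.0) if rng.random() < 0.85 else int(4 + rng.poisson(2.0))

    nrs = np.where(
        status == 1,
        rng.random(n) < cfg.nrs_positive_mal,
        rng.random(n) < cfg.nrs_positive_well,
    )
    intake = np.where(
        status == 1,
        rng.random(n) < cfg.reduced_intake_mal,
        rng.random(n) < cfg.reduced_intake_well,
    )

    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                id=f"P{i:05d}",
                age=float(round(age[i], 1)),
                sex=Sex.MALE if male[i] else Sex.FEMALE,
                bmi=float(round(bmi[i], 2)),
                wl_3mo_pct=float(round(wl3[i], 2)),
                wl_6mo_pct=float(round(wl6[i], 2)),
                wl_beyond_6mo_pct=float(round(wl_beyond[i], 2)),
                wl_any_time_pct=float(round(wl_any[i], 2)),
                ffmi=float(round(ffmi[i], 2)) if ffmi_avail[i] else None,
                muscle_reduced_anthro=bool(muscle_flag[i]),
                pgsga_score=int(score[i]),
                nrs_positive=bool(nrs[i]),
                reduced_intake=bool(intake[i]),
                has_cancer=True,
            )
        )
    return LatentCohort(records, status, severity)


def attach_survival(cohort: LatentCohort, spec: CohortSpec) -> LatentCohort:
    """Draw follow-up time and event status from a proportional-hazards model.

    Event times are Weibull (exponential when ``weibull_shape`` is 1) with
    rate ``hazard_scale * hr^severity``; censoring times are independent
    exponential with ``censoring_rate``. Each record gets the earlier of
    the two and an event indicator. Times are in months, strictly positive.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1_000_003)
    hr = {"well": 1.0, "moderate": spec.hr_moderate, "severe": spec.hr_severe}
    n = cohort.n
    u = rng.random(n)
    rates = np.array([spec.hazard_scale * hr[s] for s in cohort.true_severity])
    # inverse-CDF Weibull with scale chosen so shape=1 reduces to Exponential(rate)
    event_t = (-np.log(u) / rates) ** (1.0 / spec.weibull_shape)
    if spec.censoring_rate > 0:
        cens_t = rng.exponential(1.0 / spec.censoring_rate, n)
    else:
        cens_t = np.full(n, np.inf)
    t = np.minimum(event_t, cens_t)
    ev = event_t <= cens_t
    t = np.maximum(np.round(t, 3), 0.001)
    for i, r in enumerate(cohort.records):
        r.followup_months = float(t[i])
        r.event = bool(ev[i])
    return cohort


def inject_missingness(
    cohort_df: pd.DataFrame, missing_fraction: float, seed: int
) -> pd.DataFrame:
    """Mask categorical baseline cells completely at random (MCAR).

    Only the columns in ``MASKABLE_COLUMNS`` are eligible; survival time,
    event status and the PG-SGA score are never masked, so no patient can
    lose all three test inputs at once.
    """
    if not 0 <= missing_fraction < 1:
        raise ValidationError(f"missing_fraction must be in [0, 1), got {missing_fraction}")
    out = cohort_df.copy()
    if missing_fraction == 0:
        return out
    rng = np.random.default_rng(seed)
    for col in MASKABLE_COLUMNS:
        if col in out.columns:
            mask = rng.random(len(out)) < missing_fraction
            out[col] = out[col].astype(object)
            out.loc[mask, col] = None
    return out


def cohort_to_frame(cohort: LatentCohort) -> pd.DataFrame:
    """Flatten the records into the frozen cohort CSV schema."""
    rows = []
    for r in cohort.records:
        d = asdict(r)
        d["sex"] = r.sex.value
        rows.append(d)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def truth_frame(cohort: LatentCohort) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in cohort.records],
            "true_status": cohort.true_status,
            "true_severity": cohort.true_severity,
        }
    )


_BOOL_COLS = ["muscle_reduced_anthro", "nrs_positive", "reduced_intake", "has_cancer", "event"]


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    """Parse a cohort frame back into validated records."""
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"cohort table missing columns: {missing_cols}")
    records = []
    for _, row in df.iterrows():
        kw = {}
        for col in COHORT_COLUMNS:
            v = row[col]
            if pd.isna(v):
                v = None
            elif col in _BOOL_COLS:
                v = bool(v) if not isinstance(v, str) else v.lower() in ("true", "1")
            kw[col] = v
        kw["pgsga_score"] = int(kw["pgsga_score"])
        if kw["nrs_positive"] is None or kw["sex"] is None:
            raise ValidationError(
                f"record {kw['id']}: sex and nrs_positive must be present (impute first)"
            )
        kw["reduced_intake"] = bool(kw["reduced_intake"]) if kw["reduced_intake"] is not None else False
        kw["has_cancer"] = bool(kw["has_cancer"]) if kw["has_cancer"] is not None else True
        kw["event"] = bool(kw["event"]) if kw["event"] is not None else False
        kw["followup_months"] = float(kw["followup_months"]) if kw["followup_months"] is not None else 0.0
        records.append(PatientRecord(**kw))
    return records


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write the cohort with fixed float formatting (byte-identical per seed)."""
    df.to_csv(path, index=False, float_format="%.6g", na_rep="")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"cohort CSV missing columns: {missing_cols}")
    return df
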