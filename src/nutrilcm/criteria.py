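"""Rule engines for three malnutrition diagnostics, plus mode imputation.

The three instruments are applied exactly as their consensus definitions
state them for an oncology cohort:

* **PG-SGA** (Patient-Generated Subjective Global Assessment): an additive
  questionnaire + examination score, banded 0-1 well-nourished, 2-3 mildly,
  4-8 moderately and >=9 severely malnourished; a score >=2 flags
  malnutrition.
* **ESPEN** (2015 consensus): for patients with a positive nutrition-risk
  screen, malnutrition via low BMI alone (<18.5 kg/m2), or unintentional
  weight loss (>10% at any time, or >5% within the last 3 months) combined
  with an age-adjusted BMI cutoff (<20 if <70 y, <22 if >=70 y) or a
  sex-adjusted fat-free-mass-index cutoff (<15 women, <17 men).
* **GLIM** (Global Leadership Initiative on Malnutrition): at least one
  phenotypic criterion (weight loss >5% within 6 months or >10% beyond
  6 months; low BMI with Asian age-adjusted cutoffs 18.5/20; reduced muscle
  mass by anthropometry or FFMI) plus at least one etiologic criterion
  (reduced intake/assimilation, or disease burden — the malignancy itself
  in a cancer cohort). Severity is graded from the weight-loss magnitude.

All inequalities are implemented literally as the definitions write them:
diagnostic weight-loss thresholds are strict (``>``), severity thresholds
are inclusive (``>=``), and BMI cutoffs are strict. Boundary behaviour is
pinned by tests at every named threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "Sex",
    "Tool",
    "PatientRecord",
    "Diagnosis",
    "classify_pgsga",
    "diagnose_espen",
    "diagnose_glim",
    "apply_all",
    "mode_impute",
    "TEST_ORDER",
]

#: Fixed test order used everywhere a per-patient panel is built:
#: bit 0 = PG-SGA, bit 1 = ESPEN, bit 2 = GLIM.
TEST_ORDER = ("PGSGA", "ESPEN", "GLIM")

# FFMI low-muscle cutoffs (kg/m2), shared by ESPEN condition 3 and the
# GLIM reduced-muscle-mass phenotypic criterion.
FFMI_CUTOFF_FEMALE = 15.0
FFMI_CUTOFF_MALE = 17.0


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Tool(str, Enum):
    PGSGA = "PGSGA"
    ESPEN = "ESPEN"
    GLIM = "GLIM"


class ValidationError(ValueError):
    """A patient record or argument violates a documented invariant."""


def _is_missing(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and math.isnan(x):
        return True
    return False


@dataclass
class PatientRecord:
    """One subject's covariates, nutrition inputs and follow-up outcome.

    Weight-loss fields are percentages of body weight lost unintentionally,
    over the window the name states; ``wl_any_time_pct`` is the maximum loss
    reported at any time and must dominate the windowed fields. ``ffmi`` and
    ``muscle_reduced_anthro`` are optional: absence makes the clauses that
    need them evaluate false (with a completeness warning), never error.
    """

    id: str
    age: float
    sex: Sex
    bmi: float
    wl_3mo_pct: float = 0.0
    wl_6mo_pct: float = 0.0
    wl_beyond_6mo_pct: float = 0.0
    wl_any_time_pct: float = 0.0
    ffmi: Optional[float] = None
    muscle_reduced_anthro: Optional[bool] = None
    pgsga_score: int = 0
    nrs_positive: bool = False
    reduced_intake: bool = False
    has_cancer: bool = True
    followup_months: float = 0.0
    event: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.sex, str):
            self.sex = Sex(self.sex)
        if self.bmi <= 0:
            raise ValidationError(f"record {self.id}: bmi must be > 0, got {self.bmi}")
        for name in ("wl_3mo_pct", "wl_6mo_pct", "wl_beyond_6mo_pct", "wl_any_time_pct"):
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"record {self.id}: {name} must be >= 0, got {v}")
        if self.wl_any_time_pct < max(self.wl_3mo_pct, self.wl_6mo_pct) - 1e-9:
            raise ValidationError(
                f"record {self.id}: wl_any_time_pct must dominate the windowed losses"
            )
        if self.pgsga_score < 0:
            raise ValidationError(
                f"record {self.id}: pgsga_score must be >= 0, got {self.pgsga_score}"
            )
        if self.followup_months < 0:
            raise ValidationError(f"record {self.id}: followup_months must be >= 0")


@dataclass
class Diagnosis:
    """Outcome of one instrument on one patient.

    ``malnourished`` iff ``category != "well"``; ``triggered_rules`` lists
    the rule identifiers that fired (nonempty whenever malnourished) plus
    any data-completeness warnings, prefixed ``warn:``.
    """

    tool: Tool
    malnourished: bool
    category: str
    triggered_rules: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        fired = [r for r in self.triggered_rules if not r.startswith("warn:")]
        assert self.malnourished == (self.category != "well")
        assert not self.malnourished or fired, "malnourished diagnosis needs a rule"


def classify_pgsga(score: int) -> Diagnosis:
    """Band a PG-SGA total score into the four nutrition categories.

    0-1 well, 2-3 mild, 4-8 moderate, >=9 severe; malnourished iff >=2.
    The coarse survival grouping (well / possibly-or-moderately 2-8 /
    severely >=9) is derivable from ``category``.
    """
    if score < 0:
        raise ValidationError(f"pgsga_score must be >= 0, got {score}")
    if score <= 1:
        return Diagnosis(Tool.PGSGA, False, "well")
    if score <= 3:
        cat = "mild"
    elif score <= 8:
        cat = "moderate"
    else:
        cat = "severe"
    return Diagnosis(Tool.PGSGA, True, cat, [f"score>=2:{cat}"])


def pgsga_survival_group(score: int) -> str:
    """Coarse PG-SGA grouping used for survival stratification."""
    if score <= 1:
        return "well"
    if score <= 8:
        return "possibly_or_moderate"
    return "severe"


def _espen_wl_clause(r: PatientRecord) -> list[str]:
    """The shared ESPEN weight-loss clause: >10% at any time OR >5% in 3 months."""
    parts = []
    if r.wl_any_time_pct > 10:
        parts.append("wl>10-anytime")
    if r.wl_3mo_pct > 5:
        parts.append("wl>5-3mo")
    return parts


def diagnose_espen(r: PatientRecord) -> Diagnosis:
    """ESPEN 2015 consensus diagnosis, gated on a positive risk screen.

    C1: BMI < 18.5. C2: weight-loss clause AND BMI < 20 (<70 y) / < 22
    (>=70 y). C3: weight-loss clause AND FFMI < 15 (women) / < 17 (men).
    Any condition suffices; all that fire are recorded. A missing FFMI makes
    C3 false and records a completeness warning.
    """
    if not r.nrs_positive:
        return Diagnosis(Tool.ESPEN, False, "well")
    rules: list[str] = []
    if r.bmi < 18.5:
        rules.append("C1")
    wl = _espen_wl_clause(r)
    if wl:
        bmi_cut = 20.0 if r.age < 70 else 22.0
        if r.bmi < bmi_cut:
            rules.append("C2")
        if _is_missing(r.ffmi):
            rules.append("warn:ffmi-missing-C3-false")
        else:
            ffmi_cut = FFMI_CUTOFF_FEMALE if r.sex is Sex.FEMALE else FFMI_CUTOFF_MALE
            if r.ffmi < ffmi_cut:
                rules.append("C3")
    fired = [x for x in rules if not x.startswith("warn:")]
    if fired:
        return Diagnosis(Tool.ESPEN, True, "malnourished", rules)
    return Diagnosis(Tool.ESPEN, False, "well", rules)


def diagnose_glim(r: PatientRecord) -> Diagnosis:
    """GLIM consensus diagnosis with severity grading, gated on the screen.

    Phenotypic: P1 weight loss (>5% within 6 months or >10% beyond
    6 months); P2 low BMI (<18.5 if <70 y, <20 if >=70 y — Asian cutoffs);
    P3 reduced muscle mass (anthropometric flag OR FFMI below the sex
    cutoff, whichever is available). Etiologic: E1 reduced intake; E2 the
    malignancy itself. Malnourished iff (P1 or P2 or P3) and (E1 or E2).

    Severity: severe iff weight loss >=10% within 6 months or >=20% beyond
    6 months; otherwise moderate. The >=10% rule takes precedence at the
    band boundary, so the moderate bands read [5,10) within and (10,20)
    beyond. When malnutrition rests on low BMI or muscle mass with no
    qualifying loss, severity defaults to moderate and ``severity-default``
    is recorded.
    """
    if not r.nrs_positive:
        return Diagnosis(Tool.GLIM, False, "well")
    rules: list[str] = []
    if r.wl_6mo_pct > 5 or r.wl_beyond_6mo_pct > 10:
        rules.append("P1")
    bmi_cut = 18.5 if r.age < 70 else 20.0
    if r.bmi < bmi_cut:
        rules.append("P2")
    muscle = False
    if not _is_missing(r.muscle_reduced_anthro) and r.muscle_reduced_anthro:
        muscle = True
    if not muscle and not _is_missing(r.ffmi):
        ffmi_cut = FFMI_CUTOFF_FEMALE if r.sex is Sex.FEMALE else FFMI_CUTOFF_MALE
        muscle = r.ffmi < ffmi_cut
    if _is_missing(r.muscle_reduced_anthro) and _is_missing(r.ffmi):
        rules.append("warn:muscle-data-missing-P3-false")
    elif muscle:
        rules.append("P3")
    if r.reduced_intake:
        rules.append("E1")
    if r.has_cancer:
        rules.append("E2")
    phen = any(x in rules for x in ("P1", "P2", "P3"))
    etio = any(x in rules for x in ("E1", "E2"))
    if not (phen and etio):
        return Diagnosis(Tool.GLIM, False, "well", [x for x in rules if x.startswith("warn:")])
    if r.wl_6mo_pct >= 10 or r.wl_beyond_6mo_pct >= 20:
        cat = "severe"
    else:
        cat = "moderate"
        if "P1" not in rules:
            rules.append("severity-default")
    return Diagnosis(Tool.GLIM, True, cat, rules)


def diagnose_all(r: PatientRecord) -> dict[str, Diagnosis]:
    """All three instruments on one record, keyed by tool name."""
    return {
        "PGSGA": classify_pgsga(r.pgsga_score),
        "ESPEN": diagnose_espen(r),
        "GLIM": diagnose_glim(r),
    }


def apply_all(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Apply the three instruments to a cohort.

    Returns one row per patient with the binary panel in the fixed order
    (PG-SGA, ESPEN, GLIM), the tool-specific categories, and the triggered
    rules semicolon-joined. Per-record failures are re-raised with the
    record id attached.
    """
    rows = []
    for r in records:
        try:
            dx = diagnose_all(r)
        except ValidationError:
            raise
        except Exception as exc:  # pragma: no cover - defensive context
            raise ValidationError(f"record {r.id}: {exc}") from exc
        rows.append(
            {
                "id": r.id,
                "pgsga_pos": int(dx["PGSGA"].malnourished),
                "espen_pos": int(dx["ESPEN"].malnourished),
                "glim_pos": int(dx["GLIM"].malnourished),
                "pgsga_category": dx["PGSGA"].category,
                "espen_category": dx["ESPEN"].category,
                "glim_category": dx["GLIM"].category,
                "pgsga_group": pgsga_survival_group(r.pgsga_score),
                "pgsga_rules": ";".join(dx["PGSGA"].triggered_rules),
                "espen_rules": ";".join(dx["ESPEN"].triggered_rules),
                "glim_rules": ";".join(dx["GLIM"].triggered_rules),
            }
        )
    if not rows:
        raise ValidationError("empty cohort")
    return pd.DataFrame(rows)


def mode_impute(table: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Fill missing cells in the named columns with the column mode.

    Ties between equally frequent values are broken toward the smallest
    value (pandas' sorted mode). A column with no observed value at all
    cannot be imputed and raises, naming the column.
    """
    out = table.copy()
    for col in columns:
        if col not in out.columns:
            raise ValidationError(f"column {col!r} not in table")
        observed = out[col].dropna()
        if observed.empty:
            raise ValidationError(f"column {col!r} is entirely missing; no mode exists")
        mode = observed.mode().iloc[0]  # pandas sorts modes: smallest wins ties
        out[col] = out[col].where(out[col].notna(), mode)
    return out
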