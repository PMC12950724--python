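"""Pathway attribution for ESPEN/GLIM diagnostic discordance.

ESPEN diagnoses malnutrition far more often than GLIM in the same cohort,
because two of its thresholds are more inclusive: the BMI cutoff combined
with weight loss is <20 kg/m2 under age 70 (GLIM uses <18.5), and its
weight-loss clause accepts >10% lost *at any time* while GLIM requires the
loss to fall within 6 months (>5%) or beyond 6 months (>10%). This module
partitions discordantly diagnosed patients by the specific rule pathway
that produced the ESPEN-only diagnosis, and provides the chi-square /
Fisher machinery used to compare groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .criteria import Diagnosis, PatientRecord, ValidationError

__all__ = [
    "classify_concordance",
    "attribute_espen_pathway",
    "chi_square",
    "fisher_exact",
    "build_report",
    "DiscrepancyReport",
    "round_half_up_pct",
]

PATHWAYS = ("C2-BMI-band", "C2-WL-anytime", "C3-FFMI", "C1", "multiple")


def round_half_up_pct(count: int, denom: int, decimals: int = 1) -> float:
    """Percentage rounded half-up to one decimal, as clinical tables print it."""
    if denom == 0:
        return 0.0
    pct = Decimal(count) * 100 / Decimal(denom)
    q = Decimal(10) ** -decimals
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def classify_concordance(espen: Diagnosis, glim: Diagnosis) -> str:
    """Four-way concordance label for one patient's ESPEN and GLIM results."""
    e, g = espen.malnourished, glim.malnourished
    if e and g:
        return "both"
    if e:
        return "espen_only"
    if g:
        return "glim_only"
    return "neither"


def _glim_qualifying_loss(r: PatientRecord) -> bool:
    return r.wl_6mo_pct > 5 or r.wl_beyond_6mo_pct > 10


def attribute_espen_pathway(
    r: PatientRecord, espen: Diagnosis, glim: Diagnosis
) -> str:
    """Primary rule pathway behind an ESPEN-positive diagnosis.

    Priority-ordered so that the labels partition ESPEN-only patients into
    the mutually exclusive subgroups the discrepancy table presents:

    1. ``C2-BMI-band`` — condition 2 fired through BMI in [18.5, 20) with
       age < 70 (the band GLIM's <18.5 cutoff does not reach), with the
       weight-loss clause satisfied via the GLIM-comparable 3-month route,
       so the BMI band is the ESPEN-specific driver;
    2. ``C2-WL-anytime`` — condition 2 fired and its weight-loss clause
       held only through ">10% at any time", with no GLIM-qualifying loss,
       so the broader time frame is the driver;
    3. ``C3-FFMI`` — only condition 3 fired;
    4. ``C1`` — BMI < 18.5;
    5. ``multiple`` — anything else (several pathways jointly required).
    """
    if not espen.malnourished:
        raise ValidationError("pathway attribution requires an ESPEN-positive patient")
    fired = {x for x in espen.triggered_rules if not x.startswith("warn:")}
    if "C2" in fired and r.age < 70 and 18.5 <= r.bmi < 20 and r.wl_3mo_pct > 5:
        return "C2-BMI-band"
    if "C2" in fired and r.wl_any_time_pct > 10 and not (r.wl_3mo_pct > 5) and not _glim_qualifying_loss(r):
        return "C2-WL-anytime"
    if fired == {"C3"}:
        return "C3-FFMI"
    if "C1" in fired and r.bmi < 18.5:
        return "C1"
    return "multiple"


def chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns (statistic, df, p) for an r x c table of nonnegative integer
    counts; zero row or column margins are rejected.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValidationError("chi-square needs an r x c table with r, c >= 2")
    if np.any(t < 0) or not np.all(t == np.round(t)):
        raise ValidationError("counts must be nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValidationError("zero marginal row/column: test undefined")
    stat, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums the probabilities of all tables (with the observed margins) whose
    hypergeometric probability does not exceed the observed table's.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError("Fisher exact test needs a 2x2 table")
    if np.any(t < 0) or not np.all(t == np.round(t)):
        raise ValidationError("counts must be nonnegative integers")
    _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    return float(p)


def expected_counts(table) -> np.ndarray:
    """Expected cell counts under independence (for the Fisher-vs-chi2 rule)."""
    t = np.asarray(table, dtype=float)
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()


@dataclass
class DiscrepancyReport:
    """Pathway-attributed discordance summary in the published table's shape."""

    n_total: int
    group_sizes: dict[str, int]
    pathway_counts: dict[str, int]
    pathway_pcts: dict[str, float]
    characteristics: pd.DataFrame = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "row": f"pathway:{k}",
                "espen_only_n": v,
                "espen_only_pct": self.pathway_pcts[k],
            }
            for k, v in self.pathway_counts.items()
        ]
        return pd.DataFrame(rows)


def build_report(
    cohort: pd.DataFrame,
    records: list[PatientRecord],
    diagnoses: pd.DataFrame,
) -> DiscrepancyReport:
    """Build the full discordance report for a diagnosed cohort.

    Counts the four concordance groups, attributes every ESPEN-only
    patient to a primary pathway, and compares characteristic frequencies
    between the ESPEN-only and both-positive groups with the chi-square
    test, switching to Fisher's exact test mechanically whenever any
    expected cell count falls below five. Percentages are rounded half-up
    to one decimal.
    """
    from .criteria import diagnose_espen, diagnose_glim

    df = diagnoses.set_index("id")
    by_id = {r.id: r for r in records}
    groups: dict[str, list[str]] = {"both": [], "espen_only": [], "glim_only": [], "neither": []}
    for pid in df.index:
        e, g = df.loc[pid, "espen_pos"], df.loc[pid, "glim_pos"]
        key = ("both" if g else "espen_only") if e else ("glim_only" if g else "neither")
        groups[key].append(pid)
    sizes = {k: len(v) for k, v in groups.items()}
    n_total = len(df)

    pathway_counts = {k: 0 for k in PATHWAYS}
    for pid in groups["espen_only"]:
        r = by_id[pid]
        label = attribute_espen_pathway(r, diagnose_espen(r), diagnose_glim(r))
        pathway_counts[label] += 1
    n_eo = sizes["espen_only"]
    pathway_pcts = {k: round_half_up_pct(v, n_eo) for k, v in pathway_counts.items()}

    # characteristic comparisons: ESPEN-only vs both-positive
    chars = {
        "age_lt_70": lambda r: r.age < 70,
        "bmi_lt_18.5": lambda r: r.bmi < 18.5,
        "bmi_18.5_to_20_age_lt_70": lambda r: 18.5 <= r.bmi < 20 and r.age < 70,
        "glim_qualifying_weight_loss": _glim_qualifying_loss,
        "espen_only_weight_loss_anytime": lambda r: r.wl_any_time_pct > 10
        and not (r.wl_3mo_pct > 5)
        and not _glim_qualifying_loss(r),
        "reduced_ffmi": lambda r: r.ffmi is not None
        and r.ffmi < (15.0 if r.sex.value == "female" else 17.0),
        "reduced_muscle_anthro": lambda r: bool(r.muscle_reduced_anthro),
    }
    rows = []
    for name, pred in chars.items():
        counts = {}
        for grp in ("espen_only", "both"):
            members = [by_id[p] for p in groups[grp]]
            counts[grp] = sum(1 for r in members if pred(r))
        row = {
            "characteristic": name,
            "total_n": sum(1 for r in records if pred(r)),
            "total_pct": round_half_up_pct(sum(1 for r in records if pred(r)), n_total),
            "espen_only_n": counts["espen_only"],
            "espen_only_pct": round_half_up_pct(counts["espen_only"], max(n_eo, 1)),
            "both_n": counts["both"],
            "both_pct": round_half_up_pct(counts["both"], max(sizes["both"], 1)),
        }
        tab = np.array(
            [
                [counts["espen_only"], max(n_eo, 0) - counts["espen_only"]],
                [counts["both"], sizes["both"] - counts["both"]],
            ]
        )
        test_name, p = None, None
        if tab.sum() > 0 and not (np.any(tab.sum(0) == 0) or np.any(tab.sum(1) == 0)):
            if np.any(expected_counts(tab) < 5):
                test_name, p = "fisher", fisher_exact(tab)
            else:
                test_name, (_, _, p) = "chi_square", chi_square(tab)
        row["test"] = test_name
        row["p_value"] = p
        rows.append(row)

    return DiscrepancyReport(
        n_total=n_total,
        group_sizes=sizes,
        pathway_counts=pathway_counts,
        pathway_pcts=pathway_pcts,
        characteristics=pd.DataFrame(rows),
    )
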