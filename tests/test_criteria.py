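"""Rule-engine behaviour, pinned at every published threshold."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutrilcm.criteria import (
    ValidationError,
    apply_all,
    classify_pgsga,
    diagnose_espen,
    diagnose_glim,
    mode_impute,
    pgsga_survival_group,
)

from conftest import make_record


class TestPGSGA:
    @pytest.mark.parametrize(
        "score,category,malnourished",
        [
            (0, "well", False),
            (1, "well", False),
            (2, "mild", True),
            (3, "mild", True),
            (4, "moderate", True),
            (8, "moderate", True),
            (9, "severe", True),
            (15, "severe", True),
        ],
    )
    def test_bands(self, score, category, malnourished):
        d = classify_pgsga(score)
        assert d.category == category
        assert d.malnourished is malnourished

    def test_negative_score_rejected(self):
        with pytest.raises(ValidationError):
            classify_pgsga(-1)

    @pytest.mark.parametrize(
        "score,group",
        [(0, "well"), (1, "well"), (2, "possibly_or_moderate"), (8, "possibly_or_moderate"), (9, "severe")],
    )
    def test_survival_grouping(self, score, group):
        assert pgsga_survival_group(score) == group


class TestESPEN:
    def test_c1_low_bmi_alone(self):
        d = diagnose_espen(make_record(bmi=17.9))
        assert d.malnourished and "C1" in d.triggered_rules

    def test_c2_weight_loss_with_age_adjusted_bmi(self):
        d = diagnose_espen(make_record(age=65, bmi=19.0, wl_3mo_pct=6.0, wl_any_time_pct=6.0))
        assert d.malnourished and "C2" in d.triggered_rules

    def test_c3_weight_loss_with_low_ffmi(self):
        d = diagnose_espen(
            make_record(bmi=23.0, wl_any_time_pct=11.0, ffmi=16.5, sex="male")
        )
        assert d.malnourished and d.triggered_rules == ["C3"]

    def test_no_condition_fires(self):
        assert not diagnose_espen(make_record(bmi=24.0)).malnourished

    def test_screen_gate(self):
        r = make_record(bmi=15.0, wl_any_time_pct=20.0, wl_6mo_pct=20.0, nrs_positive=False)
        d = diagnose_espen(r)
        assert not d.malnourished and d.category == "well"

    @pytest.mark.parametrize(
        "age,bmi,expect",
        [
            # under-70 cutoff at 20, strict
            (69.9, 19.99, True),
            (69.9, 20.0, False),
            # 70-and-over cutoff at 22
            (70.0, 21.99, True),
            (70.0, 22.0, False),
        ],
    )
    def test_c2_bmi_boundaries(self, age, bmi, expect):
        d = diagnose_espen(make_record(age=age, bmi=bmi, wl_3mo_pct=5.01, wl_any_time_pct=5.01))
        assert ("C2" in d.triggered_rules) is expect

    @pytest.mark.parametrize(
        "wl3,wl_any,expect",
        [
            (5.0, 5.0, False),  # strict >5
            (5.01, 5.01, True),
            (0.0, 10.0, False),  # strict >10 any time
            (0.0, 10.01, True),
        ],
    )
    def test_weight_loss_clause_boundaries(self, wl3, wl_any, expect):
        d = diagnose_espen(make_record(age=60, bmi=19.0, wl_3mo_pct=wl3, wl_any_time_pct=wl_any))
        assert d.malnourished is expect

    @pytest.mark.parametrize(
        "sex,ffmi,expect",
        [("female", 14.99, True), ("female", 15.0, False), ("male", 16.99, True), ("male", 17.0, False)],
    )
    def test_c3_ffmi_boundaries(self, sex, ffmi, expect):
        d = diagnose_espen(
            make_record(sex=sex, bmi=25.0, wl_any_time_pct=10.01, ffmi=ffmi)
        )
        assert ("C3" in d.triggered_rules) is expect

    def test_c1_bmi_boundary(self):
        assert diagnose_espen(make_record(bmi=18.49)).malnourished
        assert not diagnose_espen(make_record(bmi=18.5)).malnourished

    def test_missing_ffmi_is_warning_not_error(self):
        d = diagnose_espen(make_record(bmi=25.0, wl_any_time_pct=12.0, ffmi=None))
        assert not d.malnourished
        assert any(r.startswith("warn:") for r in d.triggered_rules)


class TestGLIM:
    def test_moderate_via_6mo_loss(self):
        d = diagnose_glim(make_record(wl_6mo_pct=7.0, wl_any_time_pct=7.0))
        assert d.malnourished and d.category == "moderate"

    def test_severe_via_6mo_loss(self):
        d = diagnose_glim(make_record(wl_6mo_pct=12.0, wl_any_time_pct=12.0))
        assert d.category == "severe"

    def test_elderly_low_bmi_moderate(self):
        d = diagnose_glim(make_record(age=75, bmi=19.5))
        assert d.malnourished and d.category == "moderate"
        assert "severity-default" in d.triggered_rules

    def test_screen_gate(self):
        r = make_record(wl_6mo_pct=15.0, wl_any_time_pct=15.0, nrs_positive=False)
        assert not diagnose_glim(r).malnourished

    def test_needs_etiologic(self):
        r = make_record(wl_6mo_pct=8.0, wl_any_time_pct=8.0, has_cancer=False, reduced_intake=False)
        assert not diagnose_glim(r).malnourished
        r2 = make_record(wl_6mo_pct=8.0, wl_any_time_pct=8.0, has_cancer=False, reduced_intake=True)
        assert diagnose_glim(r2).malnourished

    @pytest.mark.parametrize(
        "age,bmi,expect",
        [(69.9, 18.49, True), (69.9, 18.5, False), (70.0, 19.99, True), (70.0, 20.0, False)],
    )
    def test_low_bmi_boundaries(self, age, bmi, expect):
        d = diagnose_glim(make_record(age=age, bmi=bmi))
        assert d.malnourished is expect

    @pytest.mark.parametrize(
        "wl6,beyond,malnourished,category",
        [
            (5.0, 0.0, False, "well"),  # strict >5 within 6 months
            (5.01, 0.0, True, "moderate"),
            (9.99, 0.0, True, "moderate"),
            (10.0, 0.0, True, "severe"),  # >=10 within 6 months is severe
            (0.0, 10.0, False, "well"),  # strict >10 beyond 6 months
            (0.0, 10.01, True, "moderate"),
            (0.0, 19.99, True, "moderate"),
            (0.0, 20.0, True, "severe"),  # >=20 beyond 6 months is severe
        ],
    )
    def test_weight_loss_and_severity_boundaries(self, wl6, beyond, malnourished, category):
        r = make_record(
            wl_6mo_pct=wl6,
            wl_beyond_6mo_pct=beyond,
            wl_any_time_pct=max(wl6, beyond),
        )
        d = diagnose_glim(r)
        assert d.malnourished is malnourished
        assert d.category == category

    def test_muscle_mass_either_route(self):
        via_flag = diagnose_glim(make_record(muscle_reduced_anthro=True, ffmi=None))
        via_ffmi = diagnose_glim(make_record(muscle_reduced_anthro=False, ffmi=16.0, sex="male"))
        assert via_flag.malnourished and "P3" in via_flag.triggered_rules
        assert via_ffmi.malnourished and "P3" in via_ffmi.triggered_rules

    def test_severity_partition(self):
        """Every GLIM-malnourished patient is exactly one of moderate/severe."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            wl6 = float(rng.uniform(0, 15))
            beyond = float(rng.uniform(0, 25))
            r = make_record(
                age=float(rng.uniform(30, 90)),
                bmi=float(rng.uniform(14, 30)),
                wl_6mo_pct=wl6,
                wl_beyond_6mo_pct=beyond,
                wl_any_time_pct=max(wl6, beyond) + float(rng.uniform(0, 5)),
                ffmi=float(rng.uniform(13, 22)),
                muscle_reduced_anthro=bool(rng.random() < 0.3),
            )
            d = diagnose_glim(r)
            assert d.malnourished == (d.category in ("moderate", "severe"))


@settings(deadline=None, max_examples=80)
@given(
    bmi=st.floats(10, 45),
    wl6=st.floats(0, 30),
    age=st.floats(20, 95),
    score=st.integers(0, 20),
)
def test_screen_gate_dominates_all_covariates(bmi, wl6, age, score):
    """A negative risk screen forces ESPEN and GLIM to well-nourished."""
    r = make_record(
        age=age,
        bmi=bmi,
        wl_6mo_pct=wl6,
        wl_any_time_pct=wl6,
        pgsga_score=score,
        nrs_positive=False,
    )
    assert not diagnose_espen(r).malnourished
    assert not diagnose_glim(r).malnourished


@settings(deadline=None, max_examples=50)
@given(st.integers(0, 10**6))
def test_determinism_same_record_same_diagnosis(seed):
    rng = np.random.default_rng(seed)
    wl6 = float(rng.uniform(0, 20))
    r_kw = dict(
        age=float(rng.uniform(25, 95)),
        bmi=float(rng.uniform(13, 35)),
        wl_6mo_pct=wl6,
        wl_any_time_pct=wl6 + float(rng.uniform(0, 10)),
    )
    d1 = diagnose_glim(make_record(**r_kw))
    d2 = diagnose_glim(make_record(**r_kw))
    assert d1 == d2


class TestApplyAll:
    def test_all_negative_record(self):
        df = apply_all([make_record(pgsga_score=0, bmi=24.0)])
        assert df[["pgsga_pos", "espen_pos", "glim_pos"]].iloc[0].tolist() == [0, 0, 0]

    def test_all_positive_record(self):
        r = make_record(pgsga_score=10, bmi=17.0, wl_6mo_pct=12.0, wl_any_time_pct=12.0)
        df = apply_all([r])
        assert df[["pgsga_pos", "espen_pos", "glim_pos"]].iloc[0].tolist() == [1, 1, 1]

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            apply_all([])

    def test_batch_runs_without_error(self, small_cohort, small_diagnoses):
        assert len(small_diagnoses) == small_cohort.n
        # non-degenerate: every tool produces both outcomes
        for col in ("pgsga_pos", "espen_pos", "glim_pos"):
            assert 0 < small_diagnoses[col].mean() < 1


class TestModeImpute:
    def test_fills_with_mode(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 2.0, np.nan]})
        out = mode_impute(df, ["a"])
        assert out["a"].tolist() == [1.0, 1.0, 2.0, 1.0]

    def test_tie_breaks_to_smallest(self):
        df = pd.DataFrame({"a": [2.0, 1.0, 2.0, 1.0, np.nan]})
        assert mode_impute(df, ["a"])["a"].iloc[-1] == 1.0

    def test_observed_cells_untouched(self):
        df = pd.DataFrame({"a": [3.0, np.nan, 5.0], "b": ["x", "y", None]})
        out = mode_impute(df, ["a", "b"])
        assert out.loc[0, "a"] == 3.0 and out.loc[2, "a"] == 5.0
        assert out["b"].tolist() == ["x", "y", "x"]
        assert out["a"].notna().all() and out["b"].notna().all()

    def test_all_missing_column_rejected(self):
        df = pd.DataFrame({"a": [np.nan, np.nan]})
        with pytest.raises(ValidationError, match="'a'"):
            mode_impute(df, ["a"])
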