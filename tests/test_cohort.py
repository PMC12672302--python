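"""Cohort rules: filters, strategy resolution, slopes, labels, splits, features."""

import numpy as np
import pandas as pd
import pytest

from vfcast.cohort import (
    FilterCriteria,
    apply_min_test_filter,
    baseline_vf_features,
    build_feature_matrix,
    compute_md_slope,
    eye_series_table,
    filter_vf_tests,
    label_progressor,
    resolve_test_strategy,
    split_by_patient,
    tukey_outlier_filter,
)
from vfcast.errors import DataError


def _vf_row(**overrides):
    base = {
        "patient_id": "P1",
        "eye": "OD",
        "test_date": 0,
        "md_db": -5.0,
        "psd_db": 2.0,
        "fixation_loss": 0.10,
        "false_neg": 0.20,
        "strategy": "SITA-Standard",
        "pattern": "24-2",
        "stimulus": "III",
        "background": "white",
        "age": 45.0,
        "post_surgery": False,
    }
    base.update(overrides)
    return base


class TestRecordFilters:
    @pytest.mark.parametrize(
        "overrides, retained",
        [
            ({}, True),  # reliable white 24-2 adult, no surgery
            ({"fixation_loss": 0.40}, False),
            ({"false_neg": 0.40}, False),
            ({"fixation_loss": 0.33}, False),  # strict bound: 33% itself fails
            ({"pattern": "10-2"}, False),
            ({"background": "yellow"}, False),
            ({"age": 17.0}, False),
            ({"post_surgery": True}, False),
        ],
    )
    def test_inclusion_rules(self, overrides, retained):
        df = pd.DataFrame([_vf_row(**overrides)])
        kept, _ = filter_vf_tests(df, FilterCriteria())
        assert (len(kept) == 1) is retained

    def test_audit_counts_per_rule(self):
        df = pd.DataFrame(
            [_vf_row(), _vf_row(fixation_loss=0.5), _vf_row(pattern="10-2"), _vf_row(age=10)]
        )
        kept, audit = filter_vf_tests(df, FilterCriteria())
        assert len(kept) == 1
        assert audit["fixation_loss"] == 1
        assert audit["pattern"] == 1
        assert audit["age"] == 1

    def test_idempotence(self, small_cohort):
        vf, _, _ = small_cohort
        once, _ = filter_vf_tests(vf, FilterCriteria())
        twice, audit2 = filter_vf_tests(once, FilterCriteria())
        pd.testing.assert_frame_equal(once, twice)
        assert sum(audit2.values()) == 0

    def test_unparseable_rate_reports_row(self):
        df = pd.DataFrame([_vf_row(), _vf_row(fixation_loss="bad")])
        with pytest.raises(DataError, match="row"):
            filter_vf_tests(df, FilterCriteria())


class TestStrategyResolution:
    def _eye(self, strategies, dates=None):
        dates = dates if dates is not None else list(range(len(strategies)))
        return pd.DataFrame(
            [_vf_row(strategy=s, test_date=d) for s, d in zip(strategies, dates)]
        )

    def test_minority_removed(self):
        df = self._eye(["SITA-Standard"] * 4 + ["SITA-Fast"] * 2)
        out = resolve_test_strategy(df)
        assert len(out) == 4
        assert set(out["strategy"]) == {"SITA-Standard"}

    def test_single_strategy_unchanged(self):
        df = self._eye(["SITA-Fast"] * 3)
        pd.testing.assert_frame_equal(resolve_test_strategy(df), df)

    def test_tie_keeps_strategy_of_earliest_test(self):
        df = self._eye(["SITA-Fast", "SITA-Standard", "SITA-Fast", "SITA-Standard"], [5, 1, 9, 7])
        out = resolve_test_strategy(df)
        assert set(out["strategy"]) == {"SITA-Standard"}  # earliest test is day 1
        assert len(out) == 2


class TestMinTestRule:
    def test_count_thresholds(self):
        rows = []
        for pid, n in zip("ABCD", [1, 2, 3, 4]):
            rows += [_vf_row(patient_id=pid, test_date=300 * i) for i in range(n)]
        out = apply_min_test_filter(pd.DataFrame(rows), 3)
        assert set(out["patient_id"]) == {"C", "D"}  # 2 of 4 eyes survive


class TestSlopeAndLabel:
    def test_exact_line(self):
        assert compute_md_slope([0, 365, 730], [-5, -6, -7]) == pytest.approx(-1.0)

    def test_flat_series(self):
        assert compute_md_slope([0, 365], [-4, -4]) == pytest.approx(0.0)

    def test_normal_equations_oracle(self):
        t = np.array([0.0, 180.0, 365.0])
        y = np.array([-5.0, -5.5, -7.0])
        ty = t / 365.0
        # independent oracle: solve the unnormalized normal equations directly
        A = np.array([[len(ty), ty.sum()], [ty.sum(), (ty**2).sum()]])
        b = np.array([y.sum(), (ty * y).sum()])
        expected = np.linalg.solve(A, b)[1]
        assert compute_md_slope(t, y) == pytest.approx(expected, abs=1e-12)

    def test_undefined_slope_errors(self):
        with pytest.raises(DataError):
            compute_md_slope([100], [-5])
        with pytest.raises(DataError):
            compute_md_slope([100, 100], [-5, -6])

    def test_label_boundary_is_strict(self):
        assert label_progressor(-2.51) == "fast"
        assert label_progressor(0.20) == "slow"
        assert label_progressor(-1.0) == "slow"
        assert label_progressor(-1.0000001) == "fast"
        with pytest.raises(DataError):
            label_progressor(float("nan"))


class TestTukeyFilter:
    def test_single_extreme_value_removed(self):
        s = pd.Series([0.0, 0.0, 0.0, 0.0, 100.0])
        kept, removed = tukey_outlier_filter(s)
        assert list(removed) == [100.0]
        assert len(kept) == 4

    def test_all_equal_none_removed(self):
        s = pd.Series([1.5] * 6)
        kept, removed = tukey_outlier_filter(s)
        assert removed.empty and len(kept) == 6

    def test_symmetric_set_none_removed(self):
        # Q1 = -1.5, Q3 = 1.5, IQR = 3 -> fences [-6, 6] under the
        # linear-interpolation quantile rule
        s = pd.Series([-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0])
        kept, removed = tukey_outlier_filter(s)
        assert removed.empty and len(kept) == 7

    def test_fewer_than_four_is_noop_with_warning(self):
        s = pd.Series([0.0, 50.0, -50.0])
        with pytest.warns(UserWarning):
            kept, removed = tukey_outlier_filter(s)
        assert len(kept) == 3 and removed.empty

    def test_fences_can_come_from_reference_values(self):
        s = pd.Series([0.0, 10.0])
        ref = pd.Series([0.0, 0.0, 0.0, 0.0, 0.1])
        kept, removed = tukey_outlier_filter(s, fences_from=ref)
        assert list(removed) == [10.0]


class TestPatientSplit:
    def test_sizes_80_10_10(self):
        out = split_by_patient([f"P{i}" for i in range(10)], seed=1)
        sizes = out["split"].value_counts()
        assert sizes["train"] == 8 and sizes["validation"] == 1 and sizes["test"] == 1

    def test_deterministic_under_seed(self):
        ids = [f"P{i}" for i in range(57)]
        pd.testing.assert_frame_equal(split_by_patient(ids, seed=9), split_by_patient(ids, seed=9))

    def test_no_leakage_for_multi_eye_patients(self, small_cohort):
        vf, _, _ = small_cohort
        split = split_by_patient(vf["patient_id"], seed=2)
        eyes = vf[["patient_id", "eye"]].drop_duplicates().merge(split, on="patient_id")
        per_patient = eyes.groupby("patient_id")["split"].nunique()
        assert (per_patient == 1).all()

    def test_too_few_patients_errors(self):
        with pytest.raises(DataError):
            split_by_patient(["P1", "P2"], seed=0)


def _feature_inputs():
    ehr = pd.DataFrame(
        {
            "patient_id": ["P1", "P2", "P3", "P4"],
            "va_logmar": [0.1, 0.2, np.nan, 0.4],
            "iop_max": [20.0, 22.0, 24.0, 30.0],
            "cdr": [0.6, 0.7, 0.5, 0.6],
            "cct": [np.nan, 560.0, 557.8, 600.0],
            "sph_eq": [-2.0, np.nan, -3.0, -1.0],
            "age_baseline": [60.0, 55.0, 70.0, 65.0],
            "race": ["Asian", None, "White", "Martian"],
            "sex": ["F", "M", "F", "M"],
            "dx_diabetes": [1, 0, 0, 1],
        }
    )
    base = pd.DataFrame(
        {
            "patient_id": ["P1", "P2", "P3", "P4"],
            "eye": ["OD"] * 4,
            "baseline_md": [-5.0, -6.0, -4.0, -8.0],
            "baseline_psd": [2.0, 3.0, 2.5, 4.0],
            "n_baseline_tests": [2, 1, 3, 1],
            "baseline_slope": [-0.5, np.nan, 0.2, np.nan],
            "baseline_slope_defined": [1, 0, 1, 0],
        }
    )
    return ehr, base


class TestFeatureMatrix:
    def test_numeric_imputation_uses_training_mean(self):
        ehr, base = _feature_inputs()
        train = np.array([True, True, True, False])
        ehr = ehr.copy()
        ehr.loc[3, "race"] = "Asian"  # keep categorical levels inside training
        fm = build_feature_matrix(ehr, base, train)
        # P1's cct missing -> mean of training cct values (560.0, 557.8)
        assert fm.X.loc[0, "cct"] == pytest.approx((560.0 + 557.8) / 2)
        assert fm.imputation["cct"] == pytest.approx(558.9)

    def test_missing_race_becomes_other(self):
        ehr, base = _feature_inputs()
        fm = build_feature_matrix(ehr, base, np.array([True, True, True, False]) | True)
        assert fm.X.loc[1, "race=Other"] == 1.0

    def test_one_hot_rows_sum_to_one(self):
        ehr, base = _feature_inputs()
        fm = build_feature_matrix(ehr, base, np.ones(4, dtype=bool))
        race_cols = [c for c in fm.X.columns if c.startswith("race=")]
        assert len(race_cols) == 4  # Asian, Martian, Other, White
        np.testing.assert_allclose(fm.X[race_cols].sum(axis=1), 1.0)

    def test_undefined_baseline_slope_imputed_zero_with_indicator(self):
        ehr, base = _feature_inputs()
        fm = build_feature_matrix(ehr, base, np.ones(4, dtype=bool))
        assert fm.X.loc[1, "baseline_slope"] == 0.0
        assert fm.X.loc[1, "baseline_slope_defined"] == 0.0
        assert fm.X.loc[0, "baseline_slope_defined"] == 1.0

    def test_level_unseen_in_training_errors_naming_column(self):
        ehr, base = _feature_inputs()
        train = np.array([True, True, True, False])  # Martian only outside training
        with pytest.raises(DataError, match="race"):
            build_feature_matrix(ehr, base, train)

    def test_imputation_ignores_non_training_rows(self):
        ehr, base = _feature_inputs()
        train = np.array([True, True, True, False])
        ehr2 = ehr.copy()
        ehr2.loc[3, ["iop_max", "cct", "sph_eq"]] = [999.0, 999.0, 999.0]
        ehr2.loc[3, "race"] = "Asian"
        ehr_ok = ehr.copy()
        ehr_ok.loc[3, "race"] = "Asian"
        fm1 = build_feature_matrix(ehr_ok, base, train)
        fm2 = build_feature_matrix(ehr2, base, train)
        assert fm1.imputation == fm2.imputation

    def test_no_missing_cells_after_imputation(self, small_cohort):
        vf, ehr, _ = small_cohort
        series = eye_series_table(vf)
        base = baseline_vf_features(series)
        fm = build_feature_matrix(ehr, base, np.ones(len(base), dtype=bool))
        assert not fm.X.isna().any().any()
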