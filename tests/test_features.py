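"""Feature engineering: windows, transforms, Charlson, imputation, scaling."""

import numpy as np
import pandas as pd
import pytest

from crpcsurv.charlson import DEFAULT_CHARLSON_MAP
from crpcsurv.features import (
    FeatureExtractionError, StateError, VariableSpec, apply_imputer,
    apply_standardization, charlson_score, extract_features, fit_imputer,
    impute_penalized_gaussian, log_transform, standardize,
)
from crpcsurv.synthetic import CohortTables

from helpers import make_fm

D0 = pd.Timestamp("2012-06-01")


def d(offset):
    return D0 + pd.Timedelta(days=offset)


def tiny_tables(lab_rows, dx_rows=()):
    return CohortTables(
        demographics=pd.DataFrame({
            "patient_id": ["A"], "birth_date": ["1945-06-01"],
            "race": ["White"], "bmi": [26.0], "insurance": ["Private"],
        }),
        medications=pd.DataFrame(columns=["patient_id", "drug_class", "start_date", "end_date"]),
        labs=pd.DataFrame(lab_rows, columns=["patient_id", "analyte", "value", "date"]),
        diagnoses=pd.DataFrame(list(dx_rows), columns=["patient_id", "code", "date"]),
        vitals_outcome=pd.DataFrame({
            "patient_id": ["A"], "death_date": [pd.NaT],
            "last_followup_date": [d(400)],
        }),
    )


def phen_one(date=D0):
    return pd.DataFrame({"patient_id": ["A"], "is_crpc": [True],
                         "method": ["both"], "crpc_date": [date],
                         "exclusion_reason": ["none"]})


SPECS = [VariableSpec("alp", "lab"), VariableSpec("age", "demographic"),
         VariableSpec("bmi", "demographic"),
         VariableSpec("comorbidity_count", "diagnosis")]


class TestLabWindow:
    def test_closest_value_selected(self):
        t = tiny_tables([("A", "alp", 1.0, d(-10)), ("A", "alp", 9.0, d(-40))])
        fm = extract_features(t, phen_one(), SPECS)
        assert fm.X.loc["A", "alp"] == 1.0

    def test_value_outside_three_months_is_missing(self):
        t = tiny_tables([("A", "alp", 1.0, d(-120))])
        fm = extract_features(t, phen_one(), SPECS)
        assert np.isnan(fm.X.loc["A", "alp"])
        assert fm.missing_mask.loc["A", "alp"]

    def test_window_boundaries_half_open(self):
        # 91 days before/after is inside; 92 days is outside
        inside = extract_features(tiny_tables([("A", "alp", 2.0, d(91))]), phen_one(), SPECS)
        outside = extract_features(tiny_tables([("A", "alp", 2.0, d(92))]), phen_one(), SPECS)
        assert inside.X.loc["A", "alp"] == 2.0
        assert np.isnan(outside.X.loc["A", "alp"])

    def test_tie_breaks_toward_earlier_measurement(self):
        t = tiny_tables([("A", "alp", 1.0, d(-20)), ("A", "alp", 9.0, d(20))])
        fm = extract_features(t, phen_one(), SPECS)
        assert fm.X.loc["A", "alp"] == 1.0

    def test_randomized_tables_match_bruteforce(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(40):
            off = int(rng.integers(-150, 150))
            rows.append(("A", "alp", float(rng.uniform(1, 9)), d(off)))
        t = tiny_tables(rows)
        fm = extract_features(t, phen_one(), SPECS)
        # oracle: exhaustive scan with same-day max dedup
        df = pd.DataFrame(rows, columns=["pid", "an", "v", "date"])
        df = df.groupby("date", as_index=False)["v"].max()
        df["delta"] = (df["date"] - D0).dt.days
        df = df[(df["delta"] >= -91) & (df["delta"] <= 91)]
        if df.empty:
            assert np.isnan(fm.X.loc["A", "alp"])
        else:
            min_abs = df["delta"].abs().min()
            cands = df[df["delta"].abs() == min_abs].sort_values("delta")
            assert fm.X.loc["A", "alp"] == cands["v"].iloc[0]

    def test_crpc_after_followup_rejected(self):
        t = tiny_tables([("A", "alp", 1.0, d(0))])
        with pytest.raises(FeatureExtractionError):
            extract_features(t, phen_one(date=d(500)), SPECS)

    def test_survival_outcome_in_months(self):
        fm = extract_features(tiny_tables([]), phen_one(), SPECS)
        assert fm.time_months.loc["A"] == pytest.approx(400 / 30.4375)
        assert not fm.event.loc["A"]


class TestLogTransform:
    def test_zeros_replaced_with_min_positive(self):
        fm = make_fm(pd.DataFrame({"x": [0.0, 1.0, np.e]}), [1, 2, 3], [1, 1, 1],
                     skewed={"x"})
        out = log_transform(fm)
        assert np.allclose(out.X["x"], [0.0, 0.0, 1.0])

    def test_no_zeros_plain_log(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0.5, 9, size=20)
        fm = make_fm(pd.DataFrame({"x": v}), np.ones(20), np.ones(20), skewed={"x"})
        out = log_transform(fm)
        # replace-then-log oracle
        floor = v[v > 0].min()
        expected = np.log(np.where(v > 0, v, floor))
        assert np.allclose(out.X["x"], expected)

    def test_double_application_guarded(self):
        fm = make_fm(pd.DataFrame({"x": [1.0, 2.0]}), [1, 2], [1, 1], skewed={"x"})
        out = log_transform(fm)
        with pytest.raises(StateError):
            log_transform(out)

    def test_negative_values_rejected(self):
        fm = make_fm(pd.DataFrame({"x": [-1.0, 2.0]}), [1, 2], [1, 1], skewed={"x"})
        with pytest.raises(ValueError):
            log_transform(fm)

    def test_all_zero_skewed_column_rejected(self):
        fm = make_fm(pd.DataFrame({"x": [0.0, 0.0]}), [1, 2], [1, 1], skewed={"x"})
        with pytest.raises(ValueError):
            log_transform(fm)

    def test_non_skewed_columns_untouched(self):
        fm = make_fm(pd.DataFrame({"x": [1.0, 2.0], "y": [5.0, 6.0]}),
                     [1, 2], [1, 1], skewed={"x"})
        out = log_transform(fm)
        assert np.allclose(out.X["y"], [5.0, 6.0])


class TestCharlson:
    IDX = pd.Series([D0], index=["A"])

    def score(self, dx_rows):
        dx = pd.DataFrame(dx_rows, columns=["patient_id", "code", "date"])
        return charlson_score(dx, self.IDX)

    def test_no_qualifying_codes(self):
        assert self.score([("A", "999", d(-100))]).loc["A"] == 0

    def test_two_categories_sum(self):
        s = self.score([("A", "410", d(-100)), ("A", "250.0", d(-200))])
        assert s.loc["A"] == 2

    def test_category_counted_once(self):
        s = self.score([("A", "410", d(-100)), ("A", "410", d(-300))])
        assert s.loc["A"] == 1

    def test_lookback_window(self):
        assert self.score([("A", "410", d(-800))]).loc["A"] == 0  # > 2 years
        assert self.score([("A", "410", d(10))]).loc["A"] == 0   # after index

    def test_random_code_sets_match_set_oracle(self):
        rng = np.random.default_rng(2)
        prefixes = list(DEFAULT_CHARLSON_MAP)
        for _ in range(20):
            chosen = rng.choice(prefixes, size=rng.integers(1, 8))
            rows = [("A", c, d(-int(rng.integers(0, 700)))) for c in chosen]
            expected = sum({DEFAULT_CHARLSON_MAP[c][0]: DEFAULT_CHARLSON_MAP[c][1]
                            for c in chosen}.values())
            assert self.score(rows).loc["A"] == expected


class TestImputation:
    def test_no_missing_returns_unchanged(self):
        X = pd.DataFrame({"a": [1.0, 2, 3], "b": [4.0, 5, 6]})
        fm = make_fm(X, [1, 2, 3], [1, 1, 1])
        out = impute_penalized_gaussian(fm, seed=0)
        pd.testing.assert_frame_equal(out.X, X)

    def test_exact_linear_column_recovered(self):
        rng = np.random.default_rng(4)
        n = 200
        A = rng.standard_normal((n, 3))
        y = A @ np.array([2.0, -1.0, 0.5]) + 3.0
        X = pd.DataFrame(A, columns=["a", "b", "c"])
        X["y"] = y
        holes = rng.uniform(size=n) < 0.2
        X.loc[holes, "y"] = np.nan
        fm = make_fm(X, np.ones(n), np.ones(n))
        out = impute_penalized_gaussian(fm, ridge_lambda_grid=np.array([1e-10]), seed=0)
        assert np.abs(out.X.loc[holes, "y"] - y[holes]).max() < 1e-6

    def test_mcar_imputation_beats_marginal_sd(self):
        rng = np.random.default_rng(9)
        n = 300
        f = rng.standard_normal(n)
        X = pd.DataFrame({
            "a": f + 0.3 * rng.standard_normal(n),
            "b": f + 0.3 * rng.standard_normal(n),
            "y": f + 0.4 * rng.standard_normal(n),
        })
        truth = X["y"].copy()
        holes = rng.uniform(size=n) < 0.25
        X.loc[holes, "y"] = np.nan
        fm = make_fm(X, np.ones(n), np.ones(n))
        out = impute_penalized_gaussian(fm, seed=0)
        rmse = np.sqrt(np.mean((out.X.loc[holes, "y"] - truth[holes]) ** 2))
        assert rmse < truth.std()

    def test_high_missingness_column_dropped(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.standard_normal(50), "b": rng.standard_normal(50)})
        X.loc[: int(0.7 * 50), "b"] = np.nan
        fm = make_fm(X, np.ones(50), np.ones(50))
        out = impute_penalized_gaussian(fm, seed=0, missingness_ceiling=0.6)
        assert out.dropped_for_missingness == ["b"]
        assert "b" not in out.X.columns

    def test_few_complete_rows_fall_back_to_mean(self):
        X = pd.DataFrame({"a": [1.0] * 5, "b": [1.0, 2.0, np.nan, np.nan, np.nan]})
        fm = make_fm(X, np.ones(5), np.ones(5))
        with pytest.warns(UserWarning, match="mean imputation"):
            out = impute_penalized_gaussian(fm, seed=0)
        assert np.allclose(out.X["b"].iloc[2:], 1.5)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((80, 4)), columns=list("abcd"))
        X.loc[rng.uniform(size=80) < 0.2, "d"] = np.nan
        fm = make_fm(X, np.ones(80), np.ones(80))
        o1 = impute_penalized_gaussian(fm, seed=11)
        o2 = impute_penalized_gaussian(fm, seed=11)
        pd.testing.assert_frame_equal(o1.X, o2.X)

    def test_apply_imputer_uses_training_fit_only(self):
        rng = np.random.default_rng(6)
        n = 120
        A = rng.standard_normal((n, 2))
        y = A @ np.array([1.0, -2.0])
        X = pd.DataFrame(A, columns=["a", "b"])
        X["y"] = y
        X.loc[rng.uniform(size=n) < 0.2, "y"] = np.nan
        fm = make_fm(X, np.ones(n), np.ones(n))
        imp = fit_imputer(fm, ridge_lambda_grid=np.array([1e-8]), seed=0)
        # held-out rows, all-missing target: predictions are pure train-model
        Xh = pd.DataFrame(rng.standard_normal((10, 2)), columns=["a", "b"])
        Xh["y"] = np.nan
        fh = make_fm(Xh, np.ones(10), np.ones(10))
        out = apply_imputer(fh, imp)
        expected = Xh[["a", "b"]].to_numpy() @ np.array([1.0, -2.0])
        assert np.abs(out.X["y"] - expected).max() < 1e-4


class TestStandardize:
    def test_unit_scale(self):
        fm = make_fm(pd.DataFrame({"x": [1.0, 2.0, 3.0]}), [1, 2, 3], [1, 1, 1])
        out, params = standardize(fm)
        assert out.X["x"].mean() == pytest.approx(0)
        assert out.X["x"].std(ddof=0) == pytest.approx(1)

    def test_round_trip_on_training_data(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.uniform(0, 5, (30, 2)), columns=["x", "y"])
        fm = make_fm(X, np.ones(30), np.ones(30))
        out, params = standardize(fm)
        again = apply_standardization(fm, params)
        pd.testing.assert_frame_equal(out.X, again.X)

    def test_heldout_uses_training_parameters(self):
        fm_tr = make_fm(pd.DataFrame({"x": [0.0, 2.0, 4.0]}), [1, 2, 3], [1, 1, 1])
        _, params = standardize(fm_tr)  # mean 2, sd ~1.633
        fm_te = make_fm(pd.DataFrame({"x": [10.0, 12.0, 14.0]}), [1, 2, 3], [1, 1, 1])
        out = apply_standardization(fm_te, params)
        sd = np.std([0.0, 2.0, 4.0])
        assert np.allclose(out.X["x"], (np.array([10.0, 12.0, 14.0]) - 2.0) / sd)

    def test_binary_columns_untouched(self):
        fm = make_fm(pd.DataFrame({"b": [0.0, 1.0, 0.0, 1.0]}), np.ones(4), np.ones(4))
        out, params = standardize(fm)
        assert set(out.X["b"]) == {0.0, 1.0}
        assert params.binary_cols == ["b"]

    def test_zero_variance_dropped_with_warning(self):
        fm = make_fm(pd.DataFrame({"x": [2.0, 2.0, 2.0], "y": [1.0, 2.0, 3.0]}),
                     [1, 2, 3], [1, 1, 1])
        with pytest.warns(UserWarning, match="zero-variance"):
            out, params = standardize(fm)
        assert list(out.X.columns) == ["y"]
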