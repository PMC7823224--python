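"""Discrimination metrics, paired tests, stratification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from crpcsurv.evaluation import (
    UndefinedMetricError, crossval_iauc, holdout_compare, integrated_auc,
    km_logrank_hr, median_split, paired_fold_test, time_dependent_auc,
)

from helpers import auc_pair_sum_oracle, make_fm, random_survival_instance


class TestTimeDependentAuc:
    def test_perfect_score_no_censoring(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(1, 50, 40)
        e = np.ones(40, dtype=bool)
        scores = -t  # earlier death = higher score
        for horizon in (10.0, 25.0, 40.0):
            assert time_dependent_auc(scores, t, e, horizon) == pytest.approx(1.0)

    def test_constant_score_half(self):
        rng = np.random.default_rng(1)
        t = rng.uniform(1, 50, 60)
        e = np.ones(60, dtype=bool)
        assert time_dependent_auc(np.zeros(60), t, e, 20.0) == pytest.approx(0.5)

    def test_no_cases_signalled(self):
        t = np.array([10.0, 20.0, 30.0])
        with pytest.raises(UndefinedMetricError):
            time_dependent_auc(np.zeros(3), t, np.zeros(3, bool), 5.0)

    def test_no_controls_signalled(self):
        t = np.array([1.0, 2.0, 3.0])
        with pytest.raises(UndefinedMetricError):
            time_dependent_auc(np.zeros(3), t, np.ones(3, bool), 5.0)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_pair_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(15, 50))
        _, t, e = random_survival_instance(rng, n, censor_scale=1.5)
        scores = rng.normal(size=n)
        horizon = float(np.quantile(t, 0.5))
        try:
            got = time_dependent_auc(scores, t, e, horizon)
        except UndefinedMetricError:
            return
        assert got == pytest.approx(
            auc_pair_sum_oracle(scores, t, e, horizon), abs=1e-10)


class TestIntegratedAuc:
    def test_perfect_discrimination_integrates_to_one(self):
        rng = np.random.default_rng(3)
        t = rng.uniform(1, 60, 200)
        e = np.ones(200, dtype=bool)
        assert integrated_auc(-t, t, e) == pytest.approx(1.0)

    def test_constant_score_half(self):
        rng = np.random.default_rng(4)
        t = rng.uniform(1, 60, 200)
        e = np.ones(200, dtype=bool)
        assert integrated_auc(np.zeros(200), t, e) == pytest.approx(0.5)

    def test_no_events_in_window_signalled(self):
        t = np.array([1.0, 2.0, 50.0, 60.0])
        e = np.array([1, 1, 0, 0], dtype=bool)
        with pytest.raises(UndefinedMetricError):
            integrated_auc(np.zeros(4), t, e, 6, 30)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        _, t, e = random_survival_instance(rng, 150, p=1,
                                           beta=np.array([0.5]))
        s = rng.normal(size=150)
        a = integrated_auc(s, t * 20, e)
        b = integrated_auc(np.exp(2 * s), t * 20, e)
        assert a == pytest.approx(b)

    def test_null_scores_average_near_half(self):
        rng = np.random.default_rng(6)
        vals = []
        for _ in range(20):
            t = rng.exponential(20, 600)
            c = rng.exponential(60, 600)
            time = np.minimum(t, c)
            vals.append(integrated_auc(rng.normal(size=600), time, t <= c))
        assert 0.47 < np.mean(vals) < 0.53


class TestCrossvalIauc:
    def make_signal(self, n=300, seed=0, beta=1.5):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 3))
        b = np.array([beta, 0, 0])
        T = 20 * rng.exponential(np.exp(-(X @ b)), n)
        C = rng.exponential(100, n)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        return make_fm(df, np.minimum(T, C), T <= C)

    def test_strong_signal_gives_high_iauc(self):
        fm = self.make_signal(seed=1)
        res = crossval_iauc(fm, {"alpha": 0.5, "cv_folds": 4}, n_folds=5, seed=2)
        assert 0.65 < res.mean < 0.95

    def test_pure_noise_near_half(self):
        fm = self.make_signal(seed=3, beta=0.0)
        res = crossval_iauc(fm, {"alpha": 0.5, "cv_folds": 4}, n_folds=5, seed=4)
        assert 0.40 < res.mean < 0.60

    def test_deterministic(self):
        fm = self.make_signal(seed=5)
        r1 = crossval_iauc(fm, {"alpha": 0.5, "cv_folds": 4}, n_folds=5, seed=6)
        r2 = crossval_iauc(fm, {"alpha": 0.5, "cv_folds": 4}, n_folds=5, seed=6)
        assert np.array_equal(r1.per_fold_iauc, r2.per_fold_iauc)

    def test_true_predictor_beats_noise_on_same_folds(self):
        rng = np.random.default_rng(7)
        fm = self.make_signal(seed=8)
        eta_true = fm.X["a"].to_numpy() * 1.5
        noise = rng.normal(size=fm.n)
        t = fm.time_months.to_numpy()
        e = fm.event.to_numpy()
        assert integrated_auc(eta_true, t, e) > integrated_auc(noise, t, e)


def wilcoxon_exact_oracle(d):
    """Null distribution of the signed-rank statistic by 2^n enumeration."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    W = ranks[d > 0].sum()
    n = len(d)
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append(ranks[np.array(signs, bool)].sum())
    stats = np.array(stats)
    # two-sided: double the smaller tail, capped at 1
    lo = np.mean(stats <= W)
    hi = np.mean(stats >= W)
    return min(1.0, 2 * min(lo, hi))


class TestPairedFoldTest:
    def test_identical_vectors_give_one(self):
        a = np.array([0.7, 0.72, 0.68])
        assert paired_fold_test(a, a) == 1.0

    def test_all_positive_differences_exact(self):
        a = np.linspace(0.7, 0.8, 10)
        b = a - 0.05
        assert paired_fold_test(a, b) == pytest.approx(2 / 2**10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 12))
        a = rng.normal(0.75, 0.05, n)
        b = a + rng.normal(0, 0.03, n)
        assert paired_fold_test(a, b) == pytest.approx(
            wilcoxon_exact_oracle(a - b), abs=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_fold_test([1, 2], [1, 2, 3])


class TestMedianSplit:
    def test_513_distinct_scores(self):
        rng = np.random.default_rng(9)
        s = pd.Series(rng.permutation(513).astype(float),
                      index=[f"P{i}" for i in range(513)])
        low, high = median_split(s)
        assert (len(low), len(high)) == (257, 256)

    def test_four_distinct(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0])
        low, high = median_split(s)
        assert (len(low), len(high)) == (2, 2)

    def test_ties_at_median_go_low(self):
        s = pd.Series([1.0, 2.0, 2.0, 2.0, 3.0])
        low, high = median_split(s)
        assert len(low) == 4 and len(high) == 1


class TestKmLogrankHr:
    def two_groups(self, seed=0, hr=2.7, n=260):
        rng = np.random.default_rng(seed)
        half = n // 2
        t_lo = rng.exponential(30, half)
        t_hi = rng.exponential(30 / hr, n - half)
        c = rng.exponential(80, n)
        t = np.minimum(np.concatenate([t_lo, t_hi]), c)
        e = np.concatenate([t_lo, t_hi]) <= c
        ids = [f"P{i}" for i in range(n)]
        time = pd.Series(t, index=ids)
        event = pd.Series(e, index=ids)
        return ids[:half], ids[half:], time, event

    def test_detects_planted_hazard_ratio(self):
        low, high, time, event = self.two_groups(seed=1)
        res = km_logrank_hr(low, high, time, event)
        assert res.hr_ci[0] < 2.7 < res.hr_ci[1]
        assert res.logrank_p < 0.01
        assert res.n_low + res.n_high == len(time)

    def test_km_curves_start_at_one_and_decrease(self):
        low, high, time, event = self.two_groups(seed=2)
        res = km_logrank_hr(low, high, time, event)
        for _, grp in res.km_curves.groupby("group"):
            surv = grp.sort_values("time")["survival"].to_numpy()
            assert surv[0] == pytest.approx(1.0)
            assert (np.diff(surv) <= 1e-12).all()

    def test_null_logrank_p_is_calibrated(self):
        rng = np.random.default_rng(3)
        n = 150
        t = rng.exponential(30, n)
        c = rng.exponential(60, n)
        time = pd.Series(np.minimum(t, c), index=[f"P{i}" for i in range(n)])
        event = pd.Series(t <= c, index=time.index)
        count = 0
        for _ in range(100):
            perm = rng.permutation(n)
            low = list(time.index[perm[: n // 2]])
            high = list(time.index[perm[n // 2:]])
            if km_logrank_hr(low, high, time, event).logrank_p < 0.5:
                count += 1
        assert 30 <= count <= 70

    def test_group_without_events_signalled(self):
        ids = [f"P{i}" for i in range(20)]
        time = pd.Series(np.arange(1.0, 21.0), index=ids)
        event = pd.Series([True] * 10 + [False] * 10, index=ids)
        with pytest.raises(UndefinedMetricError):
            km_logrank_hr(ids[:10], ids[10:], time, event)


class TestHoldoutCompare:
    def test_identical_models_no_difference(self):
        rng = np.random.default_rng(4)
        from crpcsurv.coxnet import fit_coxnet
        X = pd.DataFrame(rng.standard_normal((120, 3)), columns=list("abc"))
        b = np.array([1.0, 0, 0])
        T = 20 * rng.exponential(np.exp(-(X.to_numpy() @ b)), 120)
        C = rng.exponential(100, 120)
        fm = make_fm(X, np.minimum(T, C), T <= C)
        model = fit_coxnet(fm, alpha=0.5, lambda_grid=np.array([0.05]), seed=0)
        ia, ib, p = holdout_compare(model, model, fm, n_boot=100, seed=1)
        assert ia == ib
        assert p == 1.0

    def test_bootstrap_deterministic(self):
        rng = np.random.default_rng(5)
        from crpcsurv.coxnet import fit_coxnet
        X = pd.DataFrame(rng.standard_normal((120, 2)), columns=list("ab"))
        b = np.array([1.0, 0])
        T = 20 * rng.exponential(np.exp(-(X.to_numpy() @ b)), 120)
        C = rng.exponential(100, 120)
        fm = make_fm(X, np.minimum(T, C), T <= C)
        m1 = fit_coxnet(fm, alpha=0.5, lambda_grid=np.array([0.05]), seed=0)
        m2 = fit_coxnet(fm, alpha=0.5, lambda_grid=np.array([1.0]), seed=0)
        r1 = holdout_compare(m1, m2, fm, n_boot=100, seed=7)
        r2 = holdout_compare(m1, m2, fm, n_boot=100, seed=7)
        assert r1 == r2
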