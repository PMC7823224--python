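"""Time-dependent discrimination, fold-wise comparison, and risk stratification.

The central metric is the cumulative-case / dynamic-control AUC at horizon t:
cases are patients who died by t, controls are patients still at risk past t,
and case contributions are inverse-probability-of-censoring weighted (IPCW)
with the Kaplan-Meier estimate of the censoring survival function G. Tied
risk scores receive half credit. The integrated AUC (iAUC) averages AUC(t)
over the distinct event times in a window — 6 to 30 months by default — with
weights proportional to the increments of the Kaplan-Meier event-time
distribution, i.e. an integral with respect to where deaths actually happen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .coxnet import FittedCoxModel, fit_coxnet, predict_risk
from .features import FeatureMatrix, standardize


class UndefinedMetricError(ValueError):
    """The requested quantity does not exist for this data (e.g. no cases
    at the evaluation horizon, or a group without events)."""


# ---- censoring weights ----------------------------------------------------

def censoring_survival(time, event):
    """Kaplan-Meier estimate of the censoring survival function G.

    Returns a callable G(t, left=False); ``left=True`` evaluates the
    left-hand limit G(t-).
    """
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, dtype=float), ~np.asarray(event, dtype=bool))
    sf_times = kmf.survival_function_.index.to_numpy(dtype=float)
    sf_vals = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)

    def G(t, left=False):
        t = np.asarray(t, dtype=float)
        side = "left" if left else "right"
        idx = np.searchsorted(sf_times, t, side=side) - 1
        out = np.where(idx < 0, 1.0, sf_vals[np.clip(idx, 0, len(sf_vals) - 1)])
        return out if out.ndim else float(out)

    return G


def time_dependent_auc(scores, time, event, t, G=None) -> float:
    """IPCW cumulative/dynamic AUC at horizon t.

    AUC(t) = sum_i sum_j w_i [1(s_i > s_j) + 1/2 * 1(s_i = s_j)]
             / (sum_i w_i * #controls)

    over cases i (event by t) and controls j (time > t), with case weights
    w_i = 1/G(T_i-). Raises ``UndefinedMetricError`` when either side is
    empty.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    cases = (time <= t) & event
    controls = time > t
    if not cases.any() or not controls.any():
        raise UndefinedMetricError(f"no cases or no controls at t={t}")
    if G is None:
        G = censoring_survival(time, event)
    g = np.asarray(G(time[cases], left=True), dtype=float)
    ok = g > 0
    if not ok.any():
        raise UndefinedMetricError(f"all case censoring weights degenerate at t={t}")
    w = 1.0 / g[ok]
    sc = scores[cases][ok]
    st = scores[controls]
    # rank-based pair sum: for each case, count controls it beats (+ half ties)
    order = np.argsort(st, kind="stable")
    sorted_ctrl = st[order]
    below = np.searchsorted(sorted_ctrl, sc, side="left")
    upto = np.searchsorted(sorted_ctrl, sc, side="right")
    wins = below + 0.5 * (upto - below)
    return float((w * wins).sum() / (w.sum() * len(st)))


def integrated_auc(scores, time, event, t_min: float = 6.0, t_max: float = 30.0) -> float:
    """Event-distribution-weighted average of AUC(t) over the window.

    The grid is the distinct event times in [t_min, t_max]; the weight at
    grid time t_k is the Kaplan-Meier event-distribution increment
    S(t_k-) - S(t_k), renormalized over the window. Grid times where the AUC
    is undefined (no controls remain) are dropped with their weight.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    grid = np.unique(time[event & (time >= t_min) & (time <= t_max)])
    if len(grid) == 0:
        raise UndefinedMetricError(f"no events in [{t_min}, {t_max}]")
    kmf = KaplanMeierFitter().fit(time, event)
    sf_times = kmf.survival_function_.index.to_numpy(dtype=float)
    sf_vals = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)

    def S(t, left=False):
        idx = np.searchsorted(sf_times, t, side="left" if left else "right") - 1
        return 1.0 if idx < 0 else float(sf_vals[idx])

    G = censoring_survival(time, event)
    aucs, weights = [], []
    for t in grid:
        try:
            a = time_dependent_auc(scores, time, event, t, G=G)
        except UndefinedMetricError:
            continue
        aucs.append(a)
        weights.append(S(t, left=True) - S(t))
    if not aucs or sum(weights) <= 0:
        raise UndefinedMetricError("AUC undefined over the whole window")
    w = np.asarray(weights) / np.sum(weights)
    return float(np.sum(w * np.asarray(aucs)))


# ---- cross-validated iAUC --------------------------------------------------

@dataclass
class IAUCResult:
    eval_window: tuple[float, float]
    per_fold_iauc: np.ndarray
    mean: float
    sd: float


def _stratified_folds(event, n_folds, seed):
    from .coxnet import _event_stratified_folds
    return _event_stratified_folds(event, n_folds, seed)


def _fit_on_fold(fm_train: FeatureMatrix, model_config: dict, seed: int) -> FittedCoxModel:
    alpha = model_config.get("alpha", 0.5)
    lam = model_config.get("lambda", "cv")
    if lam == "cv":
        return fit_coxnet(fm_train, alpha=alpha,
                          lambda_grid=model_config.get("lambda_grid"),
                          n_folds=model_config.get("cv_folds", 5), seed=seed)
    return fit_coxnet(fm_train, alpha=alpha, lambda_grid=np.array([float(lam)]),
                      seed=seed)


def crossval_iauc(
    fm: FeatureMatrix,
    model_config: dict | None = None,
    n_folds: int = 10,
    seed: int = 0,
    t_min: float = 6.0,
    t_max: float = 30.0,
    preprocess=None,
) -> IAUCResult:
    """Per-fold integrated AUC with all fitting confined to training folds.

    ``preprocess(fm_train, fm_test) -> (fm_train, fm_test)`` hooks in any
    leakage-prone steps (imputation, transforms) so they are re-estimated on
    each training fold; by default each fold is standardized on its training
    portion (the matrix is assumed already imputed).
    """
    model_config = dict(model_config or {})
    event = fm.event.to_numpy(dtype=bool)
    fold = _stratified_folds(event, n_folds, seed)
    per_fold = []
    for f in range(n_folds):
        tr_ids = fm.patient_ids[fold != f]
        te_ids = fm.patient_ids[fold == f]
        fm_tr = fm.subset_patients(tr_ids)
        fm_te = fm.subset_patients(te_ids)
        if preprocess is not None:
            fm_tr, fm_te = preprocess(fm_tr, fm_te)
        fm_tr_std, params = standardize(fm_tr)
        model = _fit_on_fold(fm_tr_std, model_config, seed)
        model.standardization = params
        eta = predict_risk(model, fm_te).eta
        if not fm_te.event.any():
            raise UndefinedMetricError(f"fold {f} has no events")
        per_fold.append(integrated_auc(
            eta.to_numpy(), fm_te.time_months.to_numpy(),
            fm_te.event.to_numpy(), t_min, t_max,
        ))
    per_fold = np.asarray(per_fold)
    return IAUCResult(eval_window=(t_min, t_max), per_fold_iauc=per_fold,
                      mean=float(per_fold.mean()),
                      sd=float(per_fold.std(ddof=1)))


def paired_fold_test(iauc_a, iauc_b) -> float:
    """Two-sided Wilcoxon signed-rank test on paired fold metrics (the
    dependent-samples Wilcoxon), exact for n <= 25. All-zero differences
    give p = 1 by convention."""
    a = np.asarray(iauc_a, dtype=float)
    b = np.asarray(iauc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    if np.all(d == 0):
        return 1.0
    method = "exact" if len(d) <= 25 else "auto"
    res = stats.wilcoxon(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


# ---- risk stratification ---------------------------------------------------

def median_split(scores: pd.Series):
    """Dichotomize at the median risk score: eta <= median -> low risk.

    With an odd number of distinct scores the low-risk group receives the
    extra patient; all patients tied at the median are low risk.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 patients to split")
    med = float(np.median(scores.to_numpy(dtype=float)))
    low = scores.index[scores <= med]
    high = scores.index[scores > med]
    return list(low), list(high)


@dataclass
class StratificationResult:
    n_low: int
    n_high: int
    hazard_ratio: float
    hr_ci: tuple[float, float]
    logrank_p: float
    km_curves: pd.DataFrame  # columns: group, time, survival, at_risk


def km_logrank_hr(low_ids, high_ids, time: pd.Series, event: pd.Series) -> StratificationResult:
    """Kaplan-Meier curves per risk group, two-sided log-rank test, and the
    high-vs-low hazard ratio from a single-covariate unpenalized Cox fit."""
    if len(low_ids) == 0 or len(high_ids) == 0:
        raise ValueError("both groups must be nonempty")
    frames = []
    for label, ids in (("low", low_ids), ("high", high_ids)):
        t = time.loc[ids].to_numpy(dtype=float)
        e = event.loc[ids].to_numpy(dtype=bool)
        if not e.any():
            raise UndefinedMetricError(f"group {label!r} has no events; HR undefined")
        kmf = KaplanMeierFitter().fit(t, e)
        tab = pd.DataFrame({
            "group": label,
            "time": kmf.survival_function_.index.to_numpy(dtype=float),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
        })
        at_risk = [int((t >= u).sum()) for u in tab["time"]]
        tab["at_risk"] = at_risk
        frames.append(tab)
    km = pd.concat(frames, ignore_index=True)

    t_lo = time.loc[low_ids]; e_lo = event.loc[low_ids]
    t_hi = time.loc[high_ids]; e_hi = event.loc[high_ids]
    lr = logrank_test(t_lo, t_hi, event_observed_A=e_lo, event_observed_B=e_hi)

    df = pd.DataFrame({
        "T": pd.concat([t_lo, t_hi]).to_numpy(dtype=float),
        "E": pd.concat([e_lo, e_hi]).to_numpy(dtype=bool),
        "high": [0] * len(low_ids) + [1] * len(high_ids),
    })
    cph = CoxPHFitter().fit(df, "T", "E")
    hr = float(np.exp(cph.params_["high"]))
    ci = cph.confidence_intervals_
    lo = float(np.exp(ci.loc["high"].iloc[0]))
    hi = float(np.exp(ci.loc["high"].iloc[1]))
    return StratificationResult(
        n_low=len(low_ids), n_high=len(high_ids),
        hazard_ratio=hr, hr_ci=(lo, hi),
        logrank_p=float(lr.p_value), km_curves=km,
    )


# ---- hold-out comparison ---------------------------------------------------

def holdout_compare(
    model_a: FittedCoxModel,
    model_b: FittedCoxModel,
    fm_test: FeatureMatrix,
    t_min: float = 6.0,
    t_max: float = 30.0,
    n_boot: int = 1000,
    seed: int = 0,
):
    """Score two models on one untouched test set and compare their iAUCs
    with a patient-level bootstrap (two-sided percentile p-value).

    Returns (iauc_a, iauc_b, p).
    """
    eta_a = predict_risk(model_a, fm_test).eta.to_numpy()
    eta_b = predict_risk(model_b, fm_test).eta.to_numpy()
    time = fm_test.time_months.to_numpy(dtype=float)
    event = fm_test.event.to_numpy(dtype=bool)
    ia = integrated_auc(eta_a, time, event, t_min, t_max)
    ib = integrated_auc(eta_b, time, event, t_min, t_max)
    rng = np.random.default_rng(seed)
    diffs = []
    n = len(time)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            da = integrated_auc(eta_a[idx], time[idx], event[idx], t_min, t_max)
            db = integrated_auc(eta_b[idx], time[idx], event[idx], t_min, t_max)
        except UndefinedMetricError:
            continue
        diffs.append(da - db)
    diffs = np.asarray(diffs)
    if len(diffs) == 0 or np.all(diffs == 0):
        return ia, ib, 1.0
    p = 2 * min(float(np.mean(diffs <= 0)), float(np.mean(diffs >= 0)))
    return ia, ib, float(min(max(p, 1.0 / len(diffs)), 1.0))
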