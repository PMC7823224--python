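"""Simulation studies validating the pipeline end to end.

Each study regenerates its inputs from a seed, runs the relevant pipeline
components, and returns measured quantities: oracle-agreement checks for the
core estimators, parameter-recovery and null-calibration studies, confidence
-interval coverage for the stratified hazard ratio, and a planted-disparity
recovery study for the bias audit. ``scripts/acceptance.py`` reports these
numbers; the test suite asserts on them.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from ._utils import child_seed
from .audit import disparity_gap
from .coxnet import fit_coxnet
from .evaluation import (
    UndefinedMetricError, crossval_iauc, time_dependent_auc,
)
from .features import (
    extract_features, impute_penalized_gaussian, log_transform, standardize,
)
from .phenotyping import phenotype_cohort
from .reduction import cluster_correlation_pairs, solve_removal_program
from .synthetic import SimulationConfig, generate_cohort, inject_missingness, variable_schema


# ---------------------------------------------------------------------------
# cohort -> fitted model helper

def _cohort_features(cfg: SimulationConfig, mcar_seed: int):
    tables, truth = generate_cohort(cfg)
    if cfg.missing_rate > 0:
        tables = inject_missingness(tables, cfg.missing_rate, mcar_seed)
    phen = phenotype_cohort(tables)
    fm = extract_features(tables, phen, variable_schema(cfg))
    fm = log_transform(fm)
    fm = impute_penalized_gaussian(fm, seed=mcar_seed)
    return tables, truth, fm


# ---------------------------------------------------------------------------
# oracle-agreement checks

def _auc_pair_sum_oracle(scores, time, event, t):
    """Direct O(n^2) IPCW pair sum with an explicit product-limit censoring
    estimator (independent of the production implementation)."""
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)

    def G_left(t0):
        g = 1.0
        for u in sorted(set(time)):
            if u >= t0:
                break
            d = np.sum((time == u) & ~event)
            r = np.sum(time >= u)
            if r > 0:
                g *= 1 - d / r
        return g

    num = wsum = 0.0
    controls = np.where(time > t)[0]
    cases = [i for i in range(len(time)) if event[i] and time[i] <= t]
    if not len(controls) or not cases:
        raise ValueError("undefined")
    for i in cases:
        g = G_left(time[i])
        if g <= 0:
            continue
        w = 1.0 / g
        wsum += w
        for j in controls:
            if scores[i] > scores[j]:
                num += w
            elif scores[i] == scores[j]:
                num += 0.5 * w
    if wsum == 0:
        raise ValueError("undefined")
    return num / (wsum * len(controls))


def auc_oracle_check(seed: int, n_instances: int = 200) -> float:
    """Max |AUC(t) - pair-sum oracle| over random censored instances."""
    rng = np.random.default_rng(child_seed(seed, "auc-oracle"))
    worst = 0.0
    done = 0
    while done < n_instances:
        n = int(rng.integers(10, 51))
        T = rng.exponential(1.0, n)
        C = rng.exponential(1.5, n)
        time = np.minimum(T, C)
        event = T <= C
        scores = np.round(rng.normal(size=n), 1)  # coarse: exercises ties
        t = float(np.quantile(time, rng.uniform(0.2, 0.8)))
        try:
            mine = time_dependent_auc(scores, time, event, t)
            oracle = _auc_pair_sum_oracle(scores, time, event, t)
        except (ValueError, UndefinedMetricError):
            continue
        worst = max(worst, abs(mine - oracle))
        done += 1
    return worst


def _removal_bruteforce(edges, c):
    verts = sorted({v for e in edges for v in e})
    for r in range(len(verts) + 1):
        best = None
        for combo in itertools.combinations(verts, r):
            s = set(combo)
            if all(i in s or j in s for i, j in edges):
                score = sum(c[v] for v in s)
                if best is None or score > best[1]:
                    best = (s, score)
        if best is not None:
            return best[0]
    return set()


def ilp_oracle_check(seed: int, n_instances: int = 100) -> int:
    """Number of random instances (p <= 12) on which the removal ILP matches
    exhaustive enumeration."""
    rng = np.random.default_rng(child_seed(seed, "ilp-oracle"))
    agree = 0
    for _ in range(n_instances):
        p = int(rng.integers(4, 13))
        X = pd.DataFrame(rng.standard_normal((80, p)),
                         columns=[f"v{i:02d}" for i in range(p)])
        part = cluster_correlation_pairs(X)
        labels = np.array(["low"] * len(part.pairs), dtype=object)
        n_high = int(rng.integers(1, min(9, len(part.pairs))))
        labels[rng.choice(len(part.pairs), size=n_high, replace=False)] = "high"
        part.pairs["label"] = labels
        plan = solve_removal_program(part, X)
        corr = np.abs(np.corrcoef(X.to_numpy(), rowvar=False))
        np.fill_diagonal(corr, 0)
        c = {v: corr[k].sum() for k, v in enumerate(X.columns)}
        edges = list(zip(part.high_pairs()["name_i"], part.high_pairs()["name_j"]))
        if set(plan.removed) == _removal_bruteforce(edges, c):
            agree += 1
    return agree


def unpenalized_cox_check(seed: int, n: int = 40, p: int = 3) -> float:
    """Max |beta difference| between the elastic-net fit at lambda=0 and the
    unpenalized Newton-type partial-likelihood solver."""
    from .features import FeatureMatrix, VariableSpec

    rng = np.random.default_rng(child_seed(seed, "newton-oracle"))
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[0], beta[1] = 0.8, -0.5
    T = rng.exponential(np.exp(-(X @ beta)))
    C = rng.exponential(2.0, n)
    time = np.minimum(T, C)
    event = T <= C
    cols = [f"x{i}" for i in range(p)]
    df = pd.DataFrame(X, columns=cols)
    fm = FeatureMatrix(
        X=df, missing_mask=df.isna(),
        specs=[VariableSpec(c, "lab") for c in cols],
        time_months=pd.Series(time), event=pd.Series(event), imputed=True,
    )
    model = fit_coxnet(fm, alpha=0.5, lambda_grid=np.array([0.0]), seed=0)
    ldf = df.copy()
    ldf["T"], ldf["E"] = time, event
    oracle = CoxPHFitter().fit(ldf, "T", "E").params_
    return float(np.abs(model.beta.to_numpy() - oracle.to_numpy()).max())


# ---------------------------------------------------------------------------
# recovery / calibration studies

def support_recovery_study(seed: int, n_seeds: int = 10,
                           n_patients: int = 2000) -> dict:
    """Fraction of replicate cohorts on which the CV-selected elastic net
    recovers every true nonzero effect with the correct sign."""
    successes = 0
    for r in range(n_seeds):
        cfg = SimulationConfig(n_patients=n_patients,
                               seed=child_seed(seed, f"recovery-{r}"),
                               crpc_fraction=0.5)
        _, truth, fm = _cohort_features(cfg, child_seed(seed, f"recovery-m{r}"))
        fm_std, params = standardize(fm)
        model = fit_coxnet(fm_std, alpha=0.5, n_folds=5,
                           seed=child_seed(seed, f"recovery-f{r}"))
        tb = truth.true_beta[truth.true_beta != 0]
        ok = all(
            name in model.beta.index
            and model.beta[name] != 0
            and np.sign(model.beta[name]) == np.sign(val)
            for name, val in tb.items()
        )
        successes += ok
    return {"successes": successes, "n_seeds": n_seeds}


def null_iauc_study(seed: int, n_seeds: int = 10, n_patients: int = 300) -> list[float]:
    """Mean cross-validated iAUC on cohorts whose survival is independent of
    every covariate (true beta = 0)."""
    means = []
    for r in range(n_seeds):
        cfg = SimulationConfig(
            n_patients=n_patients, n_vars=12, n_blocks=0,
            n_unavailable=0, sparse_lab_count=0, true_beta={},
            crpc_fraction=1.0, missing_rate=0.0,
            seed=child_seed(seed, f"null-{r}"),
        )
        _, _, fm = _cohort_features(cfg, child_seed(seed, f"null-m{r}"))
        res = crossval_iauc(fm, {"alpha": 0.5, "cv_folds": 4}, n_folds=10,
                            seed=child_seed(seed, f"null-f{r}"))
        means.append(res.mean)
    return means


def planted_disparity_study(seed: int, n_reps: int = 3,
                            n_patients: int = 4000) -> float:
    """Mean recovered risk-conditional Charlson gap when Black patients carry
    +1 comorbidity at equal underlying risk."""
    gaps = []
    for r in range(n_reps):
        cfg = SimulationConfig(
            n_patients=n_patients, crpc_fraction=1.0, missing_rate=0.0,
            race_shift={"Black": {"comorbidity_count": 1.0}},
            seed=child_seed(seed, f"disparity-{r}"),
        )
        tables, _, fm = _cohort_features(cfg, child_seed(seed, f"disparity-m{r}"))
        fm_std, params = standardize(fm)
        model = fit_coxnet(fm_std, alpha=0.5, n_folds=5,
                           seed=child_seed(seed, f"disparity-f{r}"),
                           standardization=params)
        g = disparity_gap(fm, model, tables.demographics, ("Black", "White"),
                          covariate="charlson", n_boot=0,
                          seed=child_seed(seed, f"disparity-b{r}"))
        gaps.append(g.gap)
    return float(np.mean(gaps))


def hr_coverage_study(seed: int, n_reps: int = 100, n: int = 513,
                      true_hr: float = 2.7) -> int:
    """Number of two-group exponential replicates whose estimated 95% CI
    covers the true hazard ratio."""
    rng = np.random.default_rng(child_seed(seed, "hr-coverage"))
    n_low = (n + 1) // 2
    covered = 0
    for _ in range(n_reps):
        high = np.concatenate([np.zeros(n_low), np.ones(n - n_low)])
        scale = np.where(high == 1, 30.0 / true_hr, 30.0)
        T = rng.exponential(scale)
        C = rng.exponential(80.0, n)
        df = pd.DataFrame({"T": np.minimum(T, C), "E": T <= C, "high": high})
        cph = CoxPHFitter().fit(df, "T", "E")
        lo, hi = np.exp(cph.confidence_intervals_.loc["high"])
        covered += lo < true_hr < hi
    return covered
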