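"""Correlation-based feature reduction.

Three stages, applied to the imputed training matrix:

1. **Pair clustering** — all pairwise absolute Pearson correlations |rho_ij|
   are partitioned into low / medium / high groups by exact one-dimensional
   k-means (k=3) solved with dynamic programming, so there is no
   initialization randomness to seed.
2. **Removal program** — a binary integer program over the vertices of the
   high-pair graph removes variables until no highly correlated pair
   survives intact (a vertex cover). The objective is lexicographic: first
   the fewest removals, then — among minimum covers — remove the most
   redundant variables, scoring each variable by its total absolute
   correlation c_i = sum_j |rho_ij|.
3. **Outcome ranking / recursive elimination** — remaining variables are
   ranked by a censoring-aware analogue of absolute outcome correlation,
   |2*(c-index - 1/2)|; recursive feature elimination then drops the weakest
   coefficient one variable at a time, tracking cross-validated integrated
   AUC at every size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index
from scipy.optimize import LinearConstraint, milp
from scipy.sparse import csr_matrix

from .features import FeatureMatrix

CLUSTER_LABELS = ("low", "medium", "high")


@dataclass
class CorrelationPartition:
    pairs: pd.DataFrame          # columns: i, j, name_i, name_j, abs_rho, label
    cluster_centroids: np.ndarray  # ascending; length <= 3
    variable_names: list[str]

    def high_pairs(self) -> pd.DataFrame:
        return self.pairs[self.pairs["label"] == "high"]


@dataclass
class RemovalPlan:
    removed: list[str]
    retained: list[str]
    objective_value: float       # sum of c_i over removed variables
    total_abs_corr: pd.Series    # c_i per variable


def _kmeans_1d_exact(values: np.ndarray, k: int = 3):
    """Exact weighted 1-D k-means by dynamic programming on sorted unique
    values. Returns (assignment in {0..k_eff-1} per input value, centroids
    ascending). k_eff < k when there are fewer distinct values."""
    values = np.asarray(values, dtype=float)
    uniq, inv, counts = np.unique(values, return_inverse=True, return_counts=True)
    m = len(uniq)
    k_eff = min(k, m)
    w = counts.astype(float)
    wv = w * uniq
    wv2 = w * uniq**2
    W = np.concatenate([[0.0], np.cumsum(w)])
    S1 = np.concatenate([[0.0], np.cumsum(wv)])
    S2 = np.concatenate([[0.0], np.cumsum(wv2)])

    def seg_cost(a, b):
        # within-cluster sum of squares for uniq[a..b] inclusive (vectorized in a)
        ww = W[b + 1] - W[a]
        s1 = S1[b + 1] - S1[a]
        s2 = S2[b + 1] - S2[a]
        return s2 - s1**2 / ww

    idx = np.arange(m)
    D = np.empty((k_eff, m))
    B = np.zeros((k_eff, m), dtype=int)  # first index of the last cluster
    D[0] = seg_cost(np.zeros(m, dtype=int), idx)
    for c in range(1, k_eff):
        for i in range(c, m):
            starts = np.arange(c, i + 1)
            cand = D[c - 1, starts - 1] + seg_cost(starts, np.full(len(starts), i))
            j = int(np.argmin(cand))
            D[c, i] = cand[j]
            B[c, i] = starts[j]
        D[c, :c] = np.inf
    # backtrack breakpoints
    bounds = []
    end = m - 1
    for c in range(k_eff - 1, 0, -1):
        start = B[c, end]
        bounds.append(start)
        end = start - 1
    bounds = sorted(bounds)  # starts of clusters 1..k_eff-1
    labels_uniq = np.zeros(m, dtype=int)
    for b in bounds:
        labels_uniq[b:] += 1
    centroids = np.array([
        wv[labels_uniq == c].sum() / w[labels_uniq == c].sum()
        for c in range(k_eff)
    ])
    return labels_uniq[inv], centroids


def cluster_correlation_pairs(X: pd.DataFrame) -> CorrelationPartition:
    """Label every unordered variable pair low/medium/high by |rho|."""
    if X.shape[1] < 3:
        raise ValueError("need at least 3 variables to cluster pairs")
    names = list(X.columns)
    corr = np.corrcoef(X.to_numpy(dtype=float), rowvar=False)
    if not np.isfinite(corr).all():
        raise ValueError("correlation matrix has non-finite entries (constant column?)")
    iu, ju = np.triu_indices(len(names), k=1)
    rho = np.abs(corr[iu, ju])
    labels_idx, centroids = _kmeans_1d_exact(rho, k=3)
    k_eff = len(centroids)
    if k_eff == 3:
        label_names = CLUSTER_LABELS
    elif k_eff == 2:
        label_names = ("low", "high")
    else:
        # all pair correlations identical: a single degenerate cluster,
        # labelled low so that nothing is removed
        label_names = ("low",)
    pairs = pd.DataFrame({
        "i": iu, "j": ju,
        "name_i": [names[a] for a in iu],
        "name_j": [names[b] for b in ju],
        "abs_rho": rho,
        "label": [label_names[l] for l in labels_idx],
    })
    return CorrelationPartition(pairs=pairs, cluster_centroids=centroids,
                                variable_names=names)


def solve_removal_program(partition: CorrelationPartition,
                          X: pd.DataFrame) -> RemovalPlan:
    """Minimum vertex cover of the high-pair graph, tie-broken toward
    removing the most redundant variables (largest total |rho|).

    Solved exactly as two integer programs (scipy/HiGHS): minimize the
    number of removals, then maximize the summed redundancy of the removed
    set subject to that minimum.
    """
    names = partition.variable_names
    corr = np.abs(np.corrcoef(X[names].to_numpy(dtype=float), rowvar=False))
    np.fill_diagonal(corr, 0.0)
    c = pd.Series(corr.sum(axis=0), index=names)

    high = partition.high_pairs()
    if high.empty:
        return RemovalPlan(removed=[], retained=list(names),
                           objective_value=0.0, total_abs_corr=c)
    verts = sorted(set(high["i"]) | set(high["j"]))
    vmap = {v: k for k, v in enumerate(verts)}
    nv = len(verts)
    rows, cols = [], []
    for r, (i, j) in enumerate(zip(high["i"], high["j"])):
        rows += [r, r]
        cols += [vmap[i], vmap[j]]
    A = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(len(high), nv))
    cover = LinearConstraint(A, lb=1, ub=np.inf)
    integrality = np.ones(nv)
    bounds = (0, 1)

    res1 = milp(c=np.ones(nv), constraints=[cover], integrality=integrality,
                bounds=scipy_bounds(bounds, nv))
    if not res1.success:
        raise RuntimeError(f"removal ILP (stage 1) failed: {res1.message}")
    m_star = int(round(res1.fun))

    cvals = np.array([c.iloc[v] for v in verts])
    size = LinearConstraint(np.ones((1, nv)), lb=m_star, ub=m_star)
    res2 = milp(c=-cvals, constraints=[cover, size], integrality=integrality,
                bounds=scipy_bounds(bounds, nv))
    if not res2.success:
        raise RuntimeError(f"removal ILP (stage 2) failed: {res2.message}")
    x = np.round(res2.x).astype(int)
    removed_idx = {verts[k] for k in range(nv) if x[k] == 1}
    removed = [names[v] for v in sorted(removed_idx)]
    retained = [nm for v, nm in enumerate(names) if v not in removed_idx]
    return RemovalPlan(removed=removed, retained=retained,
                       objective_value=float(cvals[x == 1].sum()),
                       total_abs_corr=c)


def scipy_bounds(bounds, n):
    from scipy.optimize import Bounds
    return Bounds(lb=np.full(n, bounds[0]), ub=np.full(n, bounds[1]))


def rank_by_outcome(fm: FeatureMatrix) -> pd.DataFrame:
    """Rank variables by censoring-aware absolute outcome association.

    Score = |2*(c - 1/2)| where c is Harrell's concordance between the single
    variable and survival time. A variable perfectly ordering the event times
    scores 1; independent noise scores near 0. Ties in score are broken by
    variable name so the ranking is reproducible.
    """
    event = fm.event.to_numpy(dtype=bool)
    if not event.any():
        raise ValueError("all observations censored; outcome ranking undefined")
    time = fm.time_months.to_numpy(dtype=float)
    scores = {}
    for name in fm.X.columns:
        cidx = concordance_index(time, fm.X[name].to_numpy(dtype=float), event)
        scores[name] = abs(2 * (cidx - 0.5))
    out = pd.DataFrame({"variable": list(scores), "outcome_correlation": list(scores.values())})
    out = out.sort_values(["outcome_correlation", "variable"],
                          ascending=[False, True], kind="stable").reset_index(drop=True)
    for s in fm.specs:
        if s.name in scores:
            s.outcome_correlation = scores[s.name]
    return out


def recursive_feature_elimination(
    fm: FeatureMatrix,
    model_config: dict | None = None,
    min_k: int = 5,
    n_folds: int = 10,
    seed: int = 0,
    t_min: float = 6.0,
    t_max: float = 30.0,
):
    """Backward elimination on elastic-net Cox coefficients.

    At each size: fit on all current variables (lambda by CV), record the
    mean ``n_folds``-fold cross-validated integrated AUC, then drop the
    variable with the smallest |coefficient| — variables shrunk exactly to
    zero go first, ties broken by the outcome ranking (weakest first).
    Returns (best_subset, table) where the table has one row per size from p
    down to ``min_k`` and best_subset maximizes mean iAUC (ties toward fewer
    variables).
    """
    from .evaluation import crossval_iauc  # deferred: avoids a module cycle

    model_config = dict(model_config or {})
    if min_k > fm.X.shape[1]:
        raise ValueError("min_k exceeds the number of variables")
    ranking = rank_by_outcome(fm)
    rank_pos = {v: i for i, v in enumerate(ranking["variable"])}

    current = list(fm.X.columns)
    rows = []
    subsets = {}
    while len(current) >= min_k:
        sub = fm.subset_variables(current)
        res = crossval_iauc(sub, model_config=model_config, n_folds=n_folds,
                            seed=seed, t_min=t_min, t_max=t_max)
        rows.append({"k": len(current), "mean_iauc": res.mean, "sd_iauc": res.sd})
        subsets[len(current)] = list(current)
        if len(current) == min_k:
            break
        from .coxnet import fit_coxnet
        model = fit_coxnet(sub, alpha=model_config.get("alpha", 0.5),
                           lambda_grid=model_config.get("lambda_grid"),
                           n_folds=model_config.get("cv_folds", 5), seed=seed)
        absb = model.beta.abs()
        # drop order: zero coefficients first, then smallest |beta|;
        # ties broken by the outcome ranking (least associated drops first)
        drop = sorted(current,
                      key=lambda v: (absb[v] > 0, absb[v], -rank_pos[v]))[0]
        current.remove(drop)
    table = pd.DataFrame(rows)
    best_row = table.sort_values(["mean_iauc", "k"], ascending=[False, True],
                                 kind="stable").iloc[0]
    return subsets[int(best_row["k"])], table
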