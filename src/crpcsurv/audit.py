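"""Race-conditional audit of model risk scores.

The question: do patients of different races need different levels of
comorbidity burden (or PSA) to receive the same predicted risk? The model is
trained *without* race; patients are binned by pooled risk-score percentiles
and the mean of the audited covariate is compared across races within each
bin. Curves separated at equal risk indicate the score encodes the covariate
differently across groups.

Binning is by pooled-population risk deciles (rank-based, hence invariant to
monotone transforms of the score). Bins in which any race cell falls below
``min_n`` patients are merged with their neighbor toward the median bin, for
all races at once, so every race shares the same final bin edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coxnet import FittedCoxModel, predict_risk
from .features import FeatureMatrix

AUDIT_COVARIATES = {"charlson": "comorbidity_count", "psa": "psa"}


@dataclass
class AuditCurve:
    covariate_name: str
    race_group: str
    bins: list[tuple[float, float]]  # percentile intervals
    mean_covariate: np.ndarray
    n: np.ndarray


@dataclass
class DisparityGap:
    race_pair: tuple[str, str]
    covariate_name: str
    gap: float
    ci: tuple[float, float]


def _risk_bins(eta: np.ndarray, n_bins: int) -> np.ndarray:
    """Pooled percentile bin index per patient (rank-based)."""
    ranks = pd.Series(eta).rank(method="average").to_numpy()
    q = (ranks - 0.5) / len(eta)
    return np.minimum((q * n_bins).astype(int), n_bins - 1)


def _merge_small_bins(bin_idx, races, min_n, n_bins):
    """Merge percentile bins toward the center until every (bin, race) cell
    with any member race present has n >= min_n. Merging is global: all
    races share the merged edges."""
    groups = [[b] for b in range(n_bins)]
    race_names = np.unique(races)

    def cell_ok(group):
        members = np.isin(bin_idx, group)
        for r in race_names:
            nr = int((members & (races == r)).sum())
            if 0 < nr < min_n:
                return False
        return True

    changed = True
    while changed and len(groups) > 1:
        changed = False
        center = (len(groups) - 1) / 2
        # visit outermost offending group first
        order = sorted(range(len(groups)), key=lambda g: -abs(g - center))
        for g in order:
            if not cell_ok(groups[g]):
                into = g + 1 if g < center else g - 1
                a, b = sorted((g, into))
                groups[a] = groups[a] + groups[b]
                del groups[b]
                changed = True
                break
    return groups


def audit_risk_scores(
    fm: FeatureMatrix,
    model: FittedCoxModel,
    demographics: pd.DataFrame,
    covariate: str = "charlson",
    n_bins: int = 10,
    min_n: int = 10,
) -> list[AuditCurve]:
    """Mean covariate per risk-percentile bin, one curve per race."""
    if covariate not in AUDIT_COVARIATES:
        raise ValueError(f"covariate must be one of {sorted(AUDIT_COVARIATES)}")
    col = AUDIT_COVARIATES[covariate]
    if col not in fm.X.columns:
        raise ValueError(f"feature matrix lacks audited column {col!r}")
    if any("race" in v.lower() for v in model.variable_names):
        raise ValueError("model was trained with race; the audit requires a race-blind model")
    if "race" not in demographics.columns:
        raise ValueError("demographics table lacks a race column")

    eta = predict_risk(model, fm).eta
    demo = demographics.set_index("patient_id")
    races = demo.loc[fm.X.index, "race"].to_numpy()
    values = fm.X[col].to_numpy(dtype=float)

    bin_idx = _risk_bins(eta.to_numpy(), n_bins)
    groups = _merge_small_bins(bin_idx, races, min_n, n_bins)

    curves = []
    for race in sorted(np.unique(races)):
        sel = races == race
        means, ns, intervals = [], [], []
        for grp in groups:
            members = sel & np.isin(bin_idx, grp)
            lo = 100.0 * min(grp) / n_bins
            hi = 100.0 * (max(grp) + 1) / n_bins
            intervals.append((lo, hi))
            ns.append(int(members.sum()))
            means.append(float(values[members].mean()) if members.any() else np.nan)
        curves.append(AuditCurve(
            covariate_name=covariate, race_group=race,
            bins=intervals, mean_covariate=np.asarray(means),
            n=np.asarray(ns),
        ))
    return curves


def pooled_curve(fm, model, demographics, covariate="charlson",
                 n_bins=10, min_n=10) -> AuditCurve:
    """Race-ignored curve over the same bins (for consistency checks)."""
    demo = demographics.copy()
    demo = demo.assign(race="all")
    return audit_risk_scores(fm, model, demo, covariate, n_bins, min_n)[0]


def curves_to_frame(curves: list[AuditCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for (lo, hi), m, n in zip(c.bins, c.mean_covariate, c.n):
            rows.append({"covariate": c.covariate_name, "race": c.race_group,
                         "bin_lo": lo, "bin_hi": hi, "mean": m, "n": n})
    return pd.DataFrame(rows)


def disparity_gap(
    fm: FeatureMatrix,
    model: FittedCoxModel,
    demographics: pd.DataFrame,
    race_pair: tuple[str, str],
    covariate: str = "charlson",
    n_bins: int = 10,
    min_n: int = 10,
    n_boot: int = 1000,
    seed: int = 0,
) -> DisparityGap:
    """Mean vertical curve separation between two races over shared bins,
    with a patient-level bootstrap 95% interval."""
    ra, rb = race_pair

    demo = demographics.set_index("patient_id")
    races_all = demo.loc[fm.X.index, "race"].to_numpy()
    eta_all = predict_risk(model, fm).eta.to_numpy()
    col = AUDIT_COVARIATES[covariate]
    vals_all = fm.X[col].to_numpy(dtype=float)

    def compute_gap(eta, races, values):
        bin_idx = _risk_bins(eta, n_bins)
        groups = _merge_small_bins(bin_idx, races, min_n, n_bins)
        gaps = []
        for grp in groups:
            members = np.isin(bin_idx, grp)
            a = members & (races == ra)
            b = members & (races == rb)
            if a.any() and b.any():
                gaps.append(values[a].mean() - values[b].mean())
        if len(gaps) < 3:
            raise ValueError(
                f"races {ra!r} and {rb!r} share fewer than 3 bins"
            )
        return float(np.mean(gaps))

    gap = compute_gap(eta_all, races_all, vals_all)
    rng = np.random.default_rng(seed)
    boots = []
    n = len(eta_all)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            boots.append(compute_gap(eta_all[idx], races_all[idx], vals_all[idx]))
        except ValueError:
            continue
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = gap
    return DisparityGap(race_pair=(ra, rb), covariate_name=covariate,
                        gap=gap, ci=(float(lo), float(hi)))
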