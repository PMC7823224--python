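"""Build the patients x variables matrix around each CRPC index date.

Variables are captured relative to the castration-resistance index date:
demographics at the index date, diagnosis/procedure/drug indicators inside a
[-6, +3] month code window, and for each laboratory analyte the value measured
closest to the index date within +/-3 months. The survival outcome is months
from the index date to death, right-censored at the last known follow-up.

All window membership uses half-open day intervals [start, end).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import DAYS_PER_MONTH, months_to_days
from .charlson import DEFAULT_CHARLSON_MAP, classify_code

log = logging.getLogger(__name__)


class FeatureExtractionError(ValueError):
    pass


class StateError(RuntimeError):
    """Raised when an operation is applied in an invalid pipeline state."""


@dataclass
class VariableSpec:
    name: str
    source: str  # demographic | lab | diagnosis | procedure | drug
    skewed: bool = False
    available: bool = True
    outcome_correlation: float | None = None
    code: str | None = None  # for indicator variables: the code / drug class


@dataclass
class Windows:
    """Capture windows around the CRPC index date, in months."""

    code_pre_months: float = 6.0
    code_post_months: float = 3.0
    lab_months: float = 3.0

    @property
    def code_pre_days(self) -> int:
        return months_to_days(self.code_pre_months)

    @property
    def code_post_days(self) -> int:
        return months_to_days(self.code_post_months)

    @property
    def lab_days(self) -> int:
        return months_to_days(self.lab_months)


@dataclass
class FeatureMatrix:
    X: pd.DataFrame                # index: patient_id, columns: variable names
    missing_mask: pd.DataFrame     # True where the raw value was missing
    specs: list[VariableSpec]
    time_months: pd.Series
    event: pd.Series               # True = death observed
    log_transformed: bool = False
    imputed: bool = False
    dropped_for_missingness: list[str] = field(default_factory=list)

    @property
    def patient_ids(self) -> np.ndarray:
        return self.X.index.to_numpy()

    @property
    def n(self) -> int:
        return len(self.X)

    def spec_for(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            X=self.X.copy(),
            missing_mask=self.missing_mask.copy(),
            specs=[replace(s) for s in self.specs],
            time_months=self.time_months.copy(),
            event=self.event.copy(),
            log_transformed=self.log_transformed,
            imputed=self.imputed,
            dropped_for_missingness=list(self.dropped_for_missingness),
        )

    def subset_patients(self, ids) -> "FeatureMatrix":
        ids = list(ids)
        return FeatureMatrix(
            X=self.X.loc[ids].copy(),
            missing_mask=self.missing_mask.loc[ids].copy(),
            specs=[replace(s) for s in self.specs],
            time_months=self.time_months.loc[ids].copy(),
            event=self.event.loc[ids].copy(),
            log_transformed=self.log_transformed,
            imputed=self.imputed,
            dropped_for_missingness=list(self.dropped_for_missingness),
        )

    def subset_variables(self, names) -> "FeatureMatrix":
        names = list(names)
        return FeatureMatrix(
            X=self.X[names].copy(),
            missing_mask=self.missing_mask[names].copy(),
            specs=[replace(s) for s in self.specs if s.name in set(names)],
            time_months=self.time_months.copy(),
            event=self.event.copy(),
            log_transformed=self.log_transformed,
            imputed=self.imputed,
            dropped_for_missingness=list(self.dropped_for_missingness),
        )


def _dedup_same_day_max(labs: pd.DataFrame) -> pd.DataFrame:
    """Keep the maximum value per (patient, analyte, day) — deterministic and
    independent of input row order."""
    return (
        labs.groupby(["patient_id", "analyte", "date"], as_index=False)["value"].max()
    )


def closest_lab_value(
    labs: pd.DataFrame, patient_id, analyte: str, index_date, lab_days: int
):
    """Lab value with date minimizing |date - index_date|, subject to the
    half-open window [index_date - lab_days, index_date + lab_days + 1d).

    Ties in |delta| are broken toward the earlier (pre-index) measurement.
    Returns NaN when no measurement qualifies.
    """
    sub = labs[(labs["patient_id"] == patient_id) & (labs["analyte"] == analyte)]
    if sub.empty:
        return np.nan
    delta = (pd.to_datetime(sub["date"]) - pd.Timestamp(index_date)).dt.days
    ok = (delta >= -lab_days) & (delta < lab_days + 1)
    if not ok.any():
        return np.nan
    sub = sub.loc[ok]
    d = delta[ok]
    key = pd.DataFrame({"absd": d.abs(), "d": d, "v": sub["value"].to_numpy()})
    key = key.sort_values(["absd", "d"], kind="stable")
    return float(key["v"].iloc[0])


def charlson_score(
    diagnoses: pd.DataFrame,
    index_dates: pd.Series,
    weight_map: dict[str, tuple[str, int]] | None = None,
    lookback_days: int = 730,
) -> pd.Series:
    """Charlson Comorbidity Index per patient over a 2-year lookback.

    Sums category weights over *distinct* Charlson categories having at least
    one code dated in the half-open window [index - lookback, index + 1d);
    unknown codes are ignored.
    """
    weight_map = weight_map or DEFAULT_CHARLSON_MAP
    scores = pd.Series(0, index=index_dates.index, dtype=int)
    if diagnoses.empty:
        return scores
    dx = diagnoses[diagnoses["patient_id"].isin(index_dates.index)]
    dx = dx.copy()
    dx["date"] = pd.to_datetime(dx["date"])
    for pid, grp in dx.groupby("patient_id"):
        idx_date = pd.Timestamp(index_dates.loc[pid])
        delta = (grp["date"] - idx_date).dt.days
        in_win = (delta >= -lookback_days) & (delta < 1)
        cats: dict[str, int] = {}
        for code in grp.loc[in_win, "code"]:
            hit = classify_code(code, weight_map)
            if hit is not None:
                cats[hit[0]] = hit[1]
        scores.loc[pid] = sum(cats.values())
    return scores


def extract_features(
    tables,
    phenotypes: pd.DataFrame,
    specs: list[VariableSpec],
    windows: Windows | None = None,
    weight_map: dict[str, tuple[str, int]] | None = None,
) -> FeatureMatrix:
    """Assemble the feature matrix for every phenotyped CRPC patient.

    ``phenotypes`` must carry columns (patient_id, is_crpc, crpc_date); only
    flagged patients enter the matrix. Variables marked unavailable are
    skipped entirely (they contribute to the variable ledger, not the matrix).
    """
    windows = windows or Windows()
    flagged = phenotypes[phenotypes["is_crpc"].astype(bool)].copy()
    if flagged.empty:
        raise FeatureExtractionError("no CRPC-flagged patients to extract")
    flagged["crpc_date"] = pd.to_datetime(flagged["crpc_date"])
    flagged = flagged.sort_values("patient_id", kind="stable")
    pids = flagged["patient_id"].to_numpy()
    index_dates = pd.Series(
        flagged["crpc_date"].to_numpy(), index=pids, name="crpc_date"
    )

    demo = tables.demographics.set_index("patient_id").loc[pids]
    vit = tables.vitals_outcome.set_index("patient_id").loc[pids]

    # survival outcome: months from index to death, censored at last follow-up
    death = pd.to_datetime(vit["death_date"])
    fu = pd.to_datetime(vit["last_followup_date"])
    end = death.fillna(fu)
    tdays = (end.to_numpy() - index_dates.to_numpy()).astype("timedelta64[D]").astype(float)
    bad = tdays <= 0
    if bad.any():
        raise FeatureExtractionError(
            f"{int(bad.sum())} patients have CRPC date on/after last follow-up "
            f"(e.g. {pids[bad][:5].tolist()})"
        )
    time_months = pd.Series(tdays / DAYS_PER_MONTH, index=pids)
    event = pd.Series(death.notna().to_numpy(), index=pids)

    labs = _dedup_same_day_max(tables.labs)
    labs["date"] = pd.to_datetime(labs["date"])
    labs = labs[labs["patient_id"].isin(set(pids))]
    lab_by_analyte = dict(tuple(labs.groupby("analyte"))) if len(labs) else {}
    pid_pos = {p: i for i, p in enumerate(pids)}
    index_arr = index_dates.to_numpy()

    def closest_in_window(analyte: str) -> np.ndarray:
        """Per-patient value closest to the index date within the lab
        window; ties in |delta| break toward the earlier measurement."""
        vals = np.full(len(pids), np.nan)
        g = lab_by_analyte.get(analyte)
        if g is None:
            return vals
        rows = g["patient_id"].map(pid_pos).to_numpy()
        delta = (g["date"].to_numpy() - index_arr[rows]).astype("timedelta64[D]").astype(int)
        ok = (delta >= -windows.lab_days) & (delta < windows.lab_days + 1)
        if not ok.any():
            return vals
        sub = pd.DataFrame({
            "row": rows[ok], "absd": np.abs(delta[ok]), "d": delta[ok],
            "v": g["value"].to_numpy()[ok],
        }).sort_values(["row", "absd", "d"], kind="stable")
        best = sub.drop_duplicates("row", keep="first")
        vals[best["row"].to_numpy()] = best["v"].to_numpy()
        return vals

    cols: dict[str, np.ndarray] = {}
    for s in specs:
        if not s.available:
            continue
        if s.name == "age":
            birth = pd.to_datetime(demo["birth_date"]).to_numpy()
            age = (index_dates.to_numpy() - birth).astype("timedelta64[D]").astype(float) / 365.25
            cols["age"] = age
        elif s.name == "bmi":
            cols["bmi"] = demo["bmi"].astype(float).to_numpy()
        elif s.source == "diagnosis" and s.code is None:
            # Charlson comorbidity score with 2-year lookback
            cols[s.name] = charlson_score(
                tables.diagnoses, index_dates, weight_map
            ).to_numpy().astype(float)
        elif s.source == "lab":
            analyte = "PSA" if s.name == "psa" else s.name
            cols[s.name] = closest_in_window(analyte)
        elif s.source in ("diagnosis", "procedure", "drug"):
            # binary indicator: any qualifying record inside the code window
            if s.source == "drug":
                src = tables.medications.rename(columns={"start_date": "date"})
                match = src["drug_class"] == s.code
            else:
                src = tables.diagnoses
                match = src["code"].astype(str).str.startswith(str(s.code))
            src = src.loc[match & src["patient_id"].isin(pids)].copy()
            src["date"] = pd.to_datetime(src["date"])
            flag = np.zeros(len(pids))
            for i, pid in enumerate(pids):
                g = src[src["patient_id"] == pid]
                if g.empty:
                    continue
                delta = (g["date"] - index_dates.loc[pid]).dt.days
                if ((delta >= -windows.code_pre_days) & (delta < windows.code_post_days)).any():
                    flag[i] = 1.0
            cols[s.name] = flag
        else:
            raise FeatureExtractionError(f"cannot extract variable {s.name!r} ({s.source})")

    ordered = [s.name for s in specs if s.available and s.name in cols]
    X = pd.DataFrame({c: cols[c] for c in ordered}, index=pids)
    mask = X.isna()
    out_specs = [replace(s) for s in specs]
    return FeatureMatrix(
        X=X, missing_mask=mask, specs=out_specs,
        time_months=time_months, event=event,
    )


def log_transform(fm: FeatureMatrix) -> FeatureMatrix:
    """Natural-log the skewed variables, replacing zeros by the column's
    smallest observed positive value first.

    Guarded against double application: log-transforming twice silently
    changes the model scale, so a second call raises ``StateError``.
    """
    if fm.log_transformed:
        raise StateError("feature matrix is already log-transformed")
    out = fm.copy()
    for s in out.specs:
        if not s.skewed or s.name not in out.X.columns:
            continue
        col = out.X[s.name]
        observed = col.dropna()
        if (observed < 0).any():
            raise ValueError(f"skewed column {s.name!r} has negative values")
        pos = observed[observed > 0]
        if len(observed) and pos.empty:
            raise ValueError(f"skewed column {s.name!r} has no positive value")
        if not pos.empty:
            floor = pos.min()
            col = col.where((col > 0) | col.isna(), floor)
        out.X[s.name] = np.log(col)
    out.log_transformed = True
    return out


def default_ridge_grid() -> np.ndarray:
    return np.logspace(-4, 4, 25)


def _ridge_solve(Xc: np.ndarray, yc: np.ndarray, lam: float) -> np.ndarray:
    """Ridge coefficients on centered data via the normal equations."""
    q = Xc.shape[1]
    return np.linalg.solve(Xc.T @ Xc + lam * np.eye(q), Xc.T @ yc)


def _ridge_cv(Xo: np.ndarray, yo: np.ndarray, grid: np.ndarray, seed: int,
              n_folds: int = 5) -> tuple[float, np.ndarray, float, np.ndarray]:
    """Select the ridge penalty by k-fold CV (squared error), then refit on
    all rows. Intercept is unpenalized (fit by centering). Returns
    (lambda, coef, intercept_y_mean, x_means)."""
    rng = np.random.default_rng(seed)
    n = len(yo)
    fold = rng.permutation(n) % n_folds
    errs = np.zeros(len(grid))
    for f in range(n_folds):
        tr, va = fold != f, fold == f
        xm, ym = Xo[tr].mean(axis=0), yo[tr].mean()
        Xc, yc = Xo[tr] - xm, yo[tr] - ym
        XtX = Xc.T @ Xc
        Xty = Xc.T @ yc
        evals, V = np.linalg.eigh(XtX)
        z = V.T @ Xty
        for g, lam in enumerate(grid):
            coef = V @ (z / (evals + lam))
            pred = (Xo[va] - xm) @ coef + ym
            errs[g] += np.sum((yo[va] - pred) ** 2)
    lam = float(grid[int(np.argmin(errs))])
    xm, ym = Xo.mean(axis=0), yo.mean()
    coef = _ridge_solve(Xo - xm, yo - ym, lam)
    return lam, coef, float(ym), xm


@dataclass
class ImputationModel:
    """Fitted penalized-Gaussian imputer: per-column ridge regressions on the
    fully observed predictor columns, reusable on held-out data."""

    predictor_cols: list[str]
    # column -> ("ridge", coef, y_mean, x_means, lambda) or ("mean", value)
    col_models: dict
    train_means: pd.Series
    dropped: list[str]


def fit_imputer(
    fm: FeatureMatrix,
    ridge_lambda_grid: np.ndarray | None = None,
    seed: int = 0,
    missingness_ceiling: float = 0.6,
    min_complete_rows: int = 10,
) -> ImputationModel:
    """Fit ridge (L2-penalized Gaussian) regressions for every incomplete
    column on the fully observed columns.

    Columns whose missing fraction exceeds ``missingness_ceiling`` are marked
    dropped (mirroring exclusion of inconsistently captured variables).
    Penalties are selected per column by 5-fold CV over the grid. Columns
    with fewer than ``min_complete_rows`` observed rows, or when no fully
    observed predictors exist, fall back to mean imputation with a warning.
    """
    grid = np.asarray(ridge_lambda_grid if ridge_lambda_grid is not None else default_ridge_grid())
    miss_frac = fm.missing_mask.mean(axis=0)
    dropped = [c for c in fm.X.columns if miss_frac[c] > missingness_ceiling]
    if dropped:
        log.info("imputer: excluding %d variables above %.0f%% missingness: %s",
                 len(dropped), 100 * missingness_ceiling, dropped)
    keep = [c for c in fm.X.columns if c not in dropped]
    complete_cols = [c for c in keep if not fm.missing_mask[c].any()]
    col_models: dict = {}
    for col in keep:
        if not fm.missing_mask[col].any():
            continue
        y = fm.X[col]
        obs = (~fm.missing_mask[col]).to_numpy()
        n_obs = int(obs.sum())
        if not complete_cols or n_obs < min_complete_rows:
            warnings.warn(
                f"column {col!r}: falling back to mean imputation "
                f"({n_obs} observed rows, {len(complete_cols)} complete predictors)"
            )
            col_models[col] = ("mean", float(y[obs].mean()) if n_obs else 0.0)
            continue
        Xo = fm.X.loc[obs, complete_cols].to_numpy(dtype=float)
        lam, coef, ym, xm = _ridge_cv(Xo, y[obs].to_numpy(dtype=float), grid, seed)
        col_models[col] = ("ridge", coef, ym, xm, lam)
    means = fm.X[keep].mean()
    return ImputationModel(predictor_cols=complete_cols, col_models=col_models,
                           train_means=means, dropped=dropped)


def apply_imputer(fm: FeatureMatrix, imp: ImputationModel) -> FeatureMatrix:
    """Impute a matrix with a previously fitted imputer (training parameters
    only; nothing is re-estimated here)."""
    out = fm.copy()
    drop = [c for c in imp.dropped if c in out.X.columns]
    if drop:
        out.X = out.X.drop(columns=drop)
        out.missing_mask = out.missing_mask.drop(columns=drop)
        out.dropped_for_missingness = list(out.dropped_for_missingness) + drop
    # predictors must be complete before use: fill any stray holes with
    # training means
    for c in imp.predictor_cols:
        holes = out.missing_mask[c]
        if holes.any():
            out.X.loc[holes, c] = imp.train_means[c]
    P = out.X[imp.predictor_cols].to_numpy(dtype=float)
    for col in out.X.columns:
        holes = out.missing_mask[col].to_numpy()
        if not holes.any():
            continue
        model = imp.col_models.get(col)
        if model is None:
            out.X.loc[holes, col] = imp.train_means.get(col, 0.0)
        elif model[0] == "mean":
            out.X.loc[holes, col] = model[1]
        else:
            _, coef, ym, xm, _ = model
            out.X.loc[holes, col] = (P[holes] - xm) @ coef + ym
    out.imputed = True
    return out


def impute_penalized_gaussian(
    fm: FeatureMatrix,
    ridge_lambda_grid: np.ndarray | None = None,
    seed: int = 0,
    missingness_ceiling: float = 0.6,
    min_complete_rows: int = 10,
) -> FeatureMatrix:
    """Fit-and-apply convenience wrapper around :func:`fit_imputer` /
    :func:`apply_imputer` on a single matrix."""
    imp = fit_imputer(fm, ridge_lambda_grid, seed, missingness_ceiling,
                      min_complete_rows)
    return apply_imputer(fm, imp)


@dataclass
class Standardization:
    means: pd.Series
    sds: pd.Series
    binary_cols: list[str]
    dropped_zero_variance: list[str]


def _is_binary(col: pd.Series) -> bool:
    vals = set(np.unique(col.dropna().to_numpy()))
    return vals <= {0.0, 1.0}


def standardize(fm: FeatureMatrix) -> tuple[FeatureMatrix, Standardization]:
    """Center/scale continuous columns to unit SD; leave 0/1 columns alone.

    Zero-variance columns are dropped with a warning. The returned parameters
    reproduce the transform on held-out data (never re-estimated there).
    """
    out = fm.copy()
    binary = [c for c in out.X.columns if _is_binary(out.X[c])]
    cont = [c for c in out.X.columns if c not in binary]
    sds = out.X[cont].std(ddof=0)
    dead = [c for c in cont if sds[c] == 0 or not np.isfinite(sds[c])]
    if dead:
        warnings.warn(f"dropping zero-variance columns: {dead}")
        out.X = out.X.drop(columns=dead)
        out.missing_mask = out.missing_mask.drop(columns=dead)
        cont = [c for c in cont if c not in dead]
    means = out.X[cont].mean()
    sds = out.X[cont].std(ddof=0)
    out.X[cont] = (out.X[cont] - means) / sds
    params = Standardization(means=means, sds=sds, binary_cols=binary,
                             dropped_zero_variance=dead)
    return out, params


def apply_standardization(fm: FeatureMatrix, params: Standardization) -> FeatureMatrix:
    """Apply *training* standardization parameters to held-out data."""
    out = fm.copy()
    drop = [c for c in params.dropped_zero_variance if c in out.X.columns]
    if drop:
        out.X = out.X.drop(columns=drop)
        out.missing_mask = out.missing_mask.drop(columns=drop)
    cont = list(params.means.index)
    out.X[cont] = (out.X[cont] - params.means) / params.sds
    return out
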