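"""End-to-end experiment: generate -> phenotype -> features -> reduce -> fit
-> evaluate -> audit, from one configuration, with every intermediate
artifact persisted and a variable-count ledger carried through.

The ledger tracks how the variable universe shrinks at each stage:
initial -> (minus never-captured variables) -> (minus variables excluded for
missingness) = modelled -> (minus the correlation-removal set) = retained ->
RFE-selected size. Internal consistency of these counts is asserted on every
run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._utils import child_seed
from .audit import curves_to_frame, audit_risk_scores, disparity_gap
from .coxnet import fit_coxnet, predict_risk, train_test_split_90_10
from .evaluation import (
    crossval_iauc, holdout_compare, km_logrank_hr, median_split,
    paired_fold_test,
)
from .features import (
    Windows, apply_imputer, extract_features, fit_imputer, log_transform,
    standardize,
)
from .phenotyping import format_prevalence, phenotype_cohort
from .reduction import (
    cluster_correlation_pairs, rank_by_outcome, recursive_feature_elimination,
    solve_removal_program,
)
from .synthetic import (
    RCT_LIKE_RACE_PROBS, SimulationConfig, default_true_beta, generate_cohort,
    inject_missingness, variable_schema, write_cohort, write_ground_truth,
)

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Failure inside a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage




@dataclass
class ExperimentConfig:
    simulation: SimulationConfig
    out_dir: str = "experiment_out"
    gap_days: int = 90
    windows: Windows = field(default_factory=Windows)
    missingness_ceiling: float = 0.6
    alpha: float = 0.5
    n_folds: int = 10
    t_min: float = 6.0
    t_max: float = 30.0
    test_frac: float = 0.1
    run_rfe: bool = True
    rfe_min_k: int = 5
    top_k_list: tuple[int, ...] = (10, 15, 25)
    run_holdout_comparison: bool = True
    audit_covariates: tuple[str, ...] = ("charlson", "psa")
    audit_race_pairs: tuple[tuple[str, str], ...] = (("Black", "White"), ("Hispanic", "White"))
    audit_bins: int = 10
    audit_min_n: int = 10
    n_boot: int = 200
    seed: int = 13

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = SimulationConfig(**raw.pop("simulation"))
        if "windows" in raw:
            raw["windows"] = Windows(**raw["windows"])
        for key in ("top_k_list",):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "audit_race_pairs" in raw:
            raw["audit_race_pairs"] = tuple(tuple(p) for p in raw["audit_race_pairs"])
        return cls(simulation=sim, **raw)


def transfer_simulation_config(sim: SimulationConfig) -> SimulationConfig:
    """A trial-like source population for the transfer-model comparison:
    predominantly White, fewer comorbidities, higher PSA at diagnosis, and a
    partly different effect structure (domain shift plus effect shift)."""
    from .synthetic import sparse_lab_names, variable_schema

    beta = default_true_beta(sim).copy()
    effects = beta[beta != 0]
    specs = variable_schema(sim)
    unusable = set(sparse_lab_names(sim)) | {s.name for s in specs if not s.available}
    block_end = 4 + sim.n_blocks * sim.block_size
    candidates = [s.name for s in specs[block_end:]
                  if s.name not in unusable and not s.skewed
                  and beta[s.name] == 0.0]
    # move the entire effect structure onto different covariates: the
    # trial-trained model then carries no transportable signal, mirroring a
    # transfer model whose predictive features are not the ones that matter
    # in the target population
    beta[:] = 0.0
    for val, name in zip(effects.to_numpy(), reversed(candidates)):
        beta[name] = float(val)
    return SimulationConfig(
        n_patients=sim.n_patients,
        n_vars=sim.n_vars,
        n_blocks=sim.n_blocks,
        block_size=sim.block_size,
        within_block_rho=sim.within_block_rho,
        true_beta={k: float(v) for k, v in beta.items() if v != 0},
        baseline_hazard_scale=sim.baseline_hazard_scale,
        weibull_shape=sim.weibull_shape,
        censoring_rate_target=sim.censoring_rate_target,
        race_probs=dict(RCT_LIKE_RACE_PROBS),
        race_shift={},
        missing_rate=0.0,
        crpc_fraction=sim.crpc_fraction,
        psa_mean=4.4, psa_sd=1.6,
        comorbidity_mean=1.6, comorbidity_sd=1.8,
        enforce_detectability=True,
        n_unavailable=sim.n_unavailable,
        sparse_lab_count=0,
        seed=child_seed(sim.seed, "transfer-cohort"),
    )


def _prepare_features(tables, phenotypes, config: ExperimentConfig, sim: SimulationConfig):
    specs = variable_schema(sim)
    fm = extract_features(tables, phenotypes, specs, config.windows)
    fm = log_transform(fm)
    return specs, fm


def _cv_with_imputation(fm_raw, variables, config, seed):
    """Cross-validated iAUC with imputation refit inside each training fold."""
    def preprocess(fm_tr, fm_te):
        imp = fit_imputer(fm_tr, seed=seed,
                          missingness_ceiling=config.missingness_ceiling)
        return apply_imputer(fm_tr, imp), apply_imputer(fm_te, imp)

    sub = fm_raw.subset_variables([v for v in variables if v in fm_raw.X.columns])
    return crossval_iauc(
        sub, model_config={"alpha": config.alpha, "cv_folds": 5},
        n_folds=config.n_folds, seed=seed,
        t_min=config.t_min, t_max=config.t_max, preprocess=preprocess,
    )


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute all stages; any failure is re-raised as ``StageError`` with
    the failing stage's name attached."""
    stage = {"name": "setup"}
    try:
        return _run_experiment(config, stage)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage["name"], exc) from exc


def _run_experiment(config: ExperimentConfig, stage: dict) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    seed = config.seed

    # ---- stage: generate -------------------------------------------------
    stage["name"] = "generate"
    log.info("stage=generate seed=%s n=%s", sim.seed, sim.n_patients)
    tables, truth = generate_cohort(sim)
    tables = inject_missingness(tables, sim.missing_rate, child_seed(seed, "mcar"))
    write_cohort(tables, out / "cohort", sim)
    write_ground_truth(truth, out / "ground_truth.json")

    # ---- stage: phenotype ------------------------------------------------
    stage["name"] = "phenotype"
    phenotypes = phenotype_cohort(tables, gap_days=config.gap_days)
    phenotypes.to_csv(out / "phenotypes.csv", index=False, lineterminator="\n")
    n_flagged = int(phenotypes["is_crpc"].sum())
    prevalence = format_prevalence(n_flagged, len(phenotypes))
    log.info("stage=phenotype flagged=%d/%d (%s)", n_flagged, len(phenotypes), prevalence)

    # ---- stage: features -------------------------------------------------
    stage["name"] = "features"
    specs, fm_raw = _prepare_features(tables, phenotypes, config, sim)
    n_initial = len(specs)
    n_unavailable = sum(not s.available for s in specs)
    n_extracted = fm_raw.X.shape[1]

    imp_full = fit_imputer(fm_raw, seed=child_seed(seed, "impute"),
                           missingness_ceiling=config.missingness_ceiling)
    fm = apply_imputer(fm_raw, imp_full)
    n_missing_excluded = len(imp_full.dropped)
    n_modelled = fm.X.shape[1]
    assert n_extracted == n_initial - n_unavailable
    assert n_modelled == n_extracted - n_missing_excluded
    fm.X.to_csv(out / "feature_matrix.csv", lineterminator="\n")
    pd.DataFrame({"patient_id": fm.patient_ids,
                  "time_months": fm.time_months.to_numpy(),
                  "event": fm.event.to_numpy().astype(int)}).to_csv(
        out / "outcome.csv", index=False, lineterminator="\n")
    (out / "variable_specs.json").write_text(json.dumps(
        [asdict(s) for s in specs], indent=2, sort_keys=True))

    # ---- stage: split ----------------------------------------------------
    stage["name"] = "split"
    fm_train, fm_test = train_test_split_90_10(fm, child_seed(seed, "split"),
                                               config.test_frac)
    fm_raw_train = fm_raw.subset_patients(fm_train.patient_ids)
    fm_raw_train = fm_raw_train.subset_variables(
        [c for c in fm_raw_train.X.columns if c in fm.X.columns])

    # ---- stage: reduction ------------------------------------------------
    stage["name"] = "reduction"
    partition = cluster_correlation_pairs(fm_train.X)
    plan = solve_removal_program(partition, fm_train.X)
    n_removed = len(plan.removed)
    n_retained = len(plan.retained)
    assert n_retained == n_modelled - n_removed
    ranking = rank_by_outcome(fm_train.subset_variables(plan.retained))
    plan_payload = {
        "removed": plan.removed, "retained": plan.retained,
        "objective_value": plan.objective_value,
        "cluster_centroids": [float(c) for c in partition.cluster_centroids],
    }
    (out / "reduction_plan.json").write_text(json.dumps(plan_payload, indent=2, sort_keys=True))

    # ---- stage: models + cross-validated iAUC ----------------------------
    stage["name"] = "crossval"
    variants: dict[str, list[str]] = {
        "all_modelled": list(fm.X.columns),
        "independent": list(plan.retained),
    }
    ranked_vars = list(ranking["variable"])
    for k in config.top_k_list:
        if k <= len(ranked_vars):
            variants[f"top_{k}"] = ranked_vars[:k]

    rfe_table = None
    if config.run_rfe:
        rfe_seed = child_seed(seed, "rfe")
        best_subset, rfe_table = recursive_feature_elimination(
            fm_train.subset_variables(plan.retained),
            model_config={"alpha": config.alpha, "cv_folds": 5},
            min_k=config.rfe_min_k, n_folds=config.n_folds, seed=rfe_seed,
            t_min=config.t_min, t_max=config.t_max,
        )
        variants[f"rfe_{len(best_subset)}"] = best_subset
        rfe_table.to_csv(out / "rfe_table.csv", index=False, lineterminator="\n")

    iauc_rows = []
    fold_iauc: dict[str, np.ndarray] = {}
    for name, vars_ in variants.items():
        res = _cv_with_imputation(fm_raw_train, vars_, config, child_seed(seed, f"cv-{name}"))
        fold_iauc[name] = res.per_fold_iauc
        iauc_rows.append({"model": name, "n_variables": len(vars_),
                          "iauc_mean": res.mean, "iauc_sd": res.sd})
        log.info("stage=crossval model=%s k=%d iauc=%.3f (%.3f)",
                 name, len(vars_), res.mean, res.sd)
    iauc_table = pd.DataFrame(iauc_rows)
    iauc_table.to_csv(out / "iauc_table.csv", index=False, lineterminator="\n")

    best_name = iauc_table.sort_values(
        ["iauc_mean", "n_variables"], ascending=[False, True], kind="stable"
    )["model"].iloc[0]
    best_vars = variants[best_name]
    p_best_vs_full = paired_fold_test(fold_iauc[best_name], fold_iauc["all_modelled"])

    # ---- stage: final model on the training split ------------------------
    stage["name"] = "final_fit"
    fm_train_best, std_params = standardize(fm_train.subset_variables(best_vars))
    best_model = fit_coxnet(fm_train_best, alpha=config.alpha,
                            n_folds=config.n_folds,
                            seed=child_seed(seed, "final-fit"),
                            standardization=std_params)
    best_model.to_json(out / "model.json")

    # ---- stage: risk stratification (all phenotyped patients) ------------
    stage["name"] = "stratify"
    scores = predict_risk(best_model, fm.subset_variables(best_vars)).eta
    low_ids, high_ids = median_split(scores)
    strat = km_logrank_hr(low_ids, high_ids, fm.time_months, fm.event)
    strat.km_curves.to_csv(out / "km_curves.csv", index=False, lineterminator="\n")

    # ---- stage: hold-out comparison vs transfer model --------------------
    stage["name"] = "holdout"
    holdout = None
    if config.run_holdout_comparison:
        tsim = transfer_simulation_config(sim)
        t_tables, _ = generate_cohort(tsim)
        t_phen = phenotype_cohort(t_tables, gap_days=config.gap_days)
        _, t_raw = _prepare_features(t_tables, t_phen, config, tsim)
        t_vars = [v for v in best_vars if v in t_raw.X.columns]
        t_imp = fit_imputer(t_raw, seed=child_seed(seed, "t-impute"),
                            missingness_ceiling=config.missingness_ceiling)
        t_fm = apply_imputer(t_raw, t_imp)
        t_fm_std, t_std = standardize(t_fm.subset_variables(t_vars))
        transfer_model = fit_coxnet(t_fm_std, alpha=config.alpha,
                                    n_folds=config.n_folds,
                                    seed=child_seed(seed, "t-fit"),
                                    standardization=t_std)
        local = best_model if set(t_vars) == set(best_vars) else None
        if local is None:
            fm_tr_sub, std_sub = standardize(fm_train.subset_variables(t_vars))
            local = fit_coxnet(fm_tr_sub, alpha=config.alpha,
                               n_folds=config.n_folds,
                               seed=child_seed(seed, "final-fit-sub"),
                               standardization=std_sub)
        ia, ib, p = holdout_compare(
            local, transfer_model, fm_test.subset_variables(t_vars),
            config.t_min, config.t_max, n_boot=config.n_boot,
            seed=child_seed(seed, "holdout-boot"))
        holdout = {"iauc_local": ia, "iauc_transfer": ib, "p_value": p}
        log.info("stage=holdout local=%.3f transfer=%.3f p=%.4f", ia, ib, p)

    # ---- stage: bias audit -----------------------------------------------
    stage["name"] = "audit"
    audit_frames = []
    gaps = []
    present_races = set(tables.demographics["race"])
    for cov in config.audit_covariates:
        from .audit import AUDIT_COVARIATES
        if AUDIT_COVARIATES[cov] not in best_vars:
            continue
        curves = audit_risk_scores(
            fm.subset_variables(best_vars), best_model, tables.demographics,
            covariate=cov, n_bins=config.audit_bins, min_n=config.audit_min_n)
        audit_frames.append(curves_to_frame(curves))
        for pair in config.audit_race_pairs:
            if not set(pair) <= present_races:
                continue
            try:
                g = disparity_gap(
                    fm.subset_variables(best_vars), best_model,
                    tables.demographics, pair, covariate=cov,
                    n_bins=config.audit_bins, min_n=config.audit_min_n,
                    n_boot=config.n_boot, seed=child_seed(seed, f"gap-{cov}"))
            except ValueError:
                continue
            gaps.append({"covariate": cov, "race_a": pair[0], "race_b": pair[1],
                         "gap": g.gap, "ci_low": g.ci[0], "ci_high": g.ci[1]})
    if audit_frames:
        pd.concat(audit_frames, ignore_index=True).to_csv(
            out / "audit_curves.csv", index=False, lineterminator="\n")

    # ---- summary ---------------------------------------------------------
    stage["name"] = "summary"
    ledger = {
        "initial": n_initial,
        "unavailable": n_unavailable,
        "extracted": n_extracted,
        "missingness_excluded": n_missing_excluded,
        "modelled": n_modelled,
        "removed_by_reduction": n_removed,
        "retained": n_retained,
        "rfe_selected": (len(best_subset) if config.run_rfe else None),
    }
    summary = {
        "seed": seed,
        "n_patients": int(sim.n_patients),
        "n_flagged": n_flagged,
        "prevalence": prevalence,
        "variable_ledger": ledger,
        "iauc_table": iauc_rows,
        "best_model": best_name,
        "best_vs_all_modelled_p": p_best_vs_full,
        "stratification": {
            "n_low": strat.n_low, "n_high": strat.n_high,
            "hazard_ratio": strat.hazard_ratio,
            "hr_ci": list(strat.hr_ci), "logrank_p": strat.logrank_p,
        },
        "holdout": holdout,
        "audit_gaps": gaps,
        "n_train": fm_train.n, "n_test": fm_test.n,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
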