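"""Seed-reproducible synthetic EHR-style cohort for metastatic CRPC modelling.

The generator emits the five longitudinal tables the downstream pipeline
consumes (demographics, medication dispenses, labs, diagnoses, death/censor)
plus the ground truth needed for recovery tests: the sparse coefficient
vector, each transitioning patient's true castration-resistance date, and the
per-patient linear predictor.

Data-generating model
---------------------
* ~100 latent covariates are standard Gaussian with an equicorrelated block
  structure (pairwise within-block correlation ``within_block_rho``); they are
  mapped to analyte scales (log-normal for the skewed analytes) when written
  into the lab table.
* Survival from the castration-resistance date follows a Weibull model with
  hazard proportional to exp(eta), eta = Z beta on the *latent standardized*
  covariates. Shape 1 (exponential) by default so closed-form checks exist.
* Censoring is administrative (uniform study entry, fixed study end) plus
  exponential dropout; the dropout rate is calibrated by bisection so the
  realized censored fraction hits the configured target.
* log-PSA follows a piecewise-linear mean: declining while hormone therapy
  works, rising after the true castration-resistance date, plus Gaussian
  noise. Measurement dates sit on a jittered 3-month grid inside the
  hormone-therapy episode.
* Race is drawn from ``race_probs``; ``race_shift`` adds offsets to designated
  *observed* covariates (comorbidity count on the count scale, PSA on the log
  scale) without touching eta — i.e. it plants a disparity at equal risk,
  which is exactly what the bias audit is built to detect.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import DAYS_PER_MONTH
from .charlson import WEIGHT_ONE_PREFIXES
from .features import VariableSpec

RACES = ("White", "Asian", "Black", "Hispanic", "Other")

#: EHR-cohort race mix (fractions of the real-world clinic population).
DEFAULT_RACE_PROBS = {
    "White": 0.657, "Asian": 0.172, "Black": 0.047, "Hispanic": 0.082, "Other": 0.042,
}
#: Trial-like race mix (predominantly White), for transfer-learning scenarios.
RCT_LIKE_RACE_PROBS = {
    "White": 0.869, "Asian": 0.026, "Black": 0.046, "Hispanic": 0.009, "Other": 0.050,
}
INSURANCE_PROBS = {"Medicare": 0.690, "Private": 0.158, "Medicaid": 0.051, "Unknown": 0.101}

STUDY_START = pd.Timestamp("2008-01-01")
STUDY_END = pd.Timestamp("2019-12-31")

HORMONE = "hormone"
SECOND_LINE_CLASSES = ("chemo", "secondary_hormone", "immunomodulatory")


@dataclass
class SimulationConfig:
    n_patients: int
    n_vars: int = 101
    n_blocks: int = 24
    block_size: int = 2
    within_block_rho: float = 0.9
    true_beta: dict[str, float] | None = None  # None -> default sparse vector
    baseline_hazard_scale: float = 24.0        # months; Weibull scale b
    weibull_shape: float = 1.0
    censoring_rate_target: float = 0.30
    race_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RACE_PROBS))
    race_shift: dict[str, dict[str, float]] = field(default_factory=dict)
    missing_rate: float = 0.10                 # consumed by inject_missingness
    crpc_fraction: float = 0.5
    frac_no_hormone: float = 0.05              # of non-transitioning patients
    frac_few_psa: float = 0.05
    second_line_fraction: float = 0.6          # of transitioning patients
    psa_noise_sd: float = 0.15                 # log-PSA measurement noise
    psa_mean: float = 2.7                      # log-PSA at diagnosis, cohort mean
    psa_sd: float = 1.6
    comorbidity_mean: float = 2.5
    comorbidity_sd: float = 2.0
    enforce_detectability: bool = True
    n_unavailable: int = 10
    sparse_lab_count: int = 7
    sparse_lab_capture_rate: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not np.isclose(sum(self.race_probs.values()), 1.0, atol=1e-12):
            raise ValueError("race_probs must sum to 1")
        for name in self.race_probs:
            if name not in RACES:
                raise ValueError(f"unknown race {name!r}")
        for r in ("censoring_rate_target", "missing_rate", "crpc_fraction",
                  "frac_no_hormone", "frac_few_psa", "second_line_fraction",
                  "sparse_lab_capture_rate"):
            v = getattr(self, r)
            if not (0 <= v <= 1) or (r in ("missing_rate",) and v >= 1):
                raise ValueError(f"{r} out of range: {v}")
        if not (0 <= self.within_block_rho < 1):
            raise ValueError("within_block_rho must be in [0, 1)")
        if self.n_blocks * self.block_size > self.n_vars - 4:
            raise ValueError("correlation blocks do not fit in the variable schema")
        if 4 + self.n_blocks * self.block_size > self.n_vars - self.n_unavailable - self.sparse_lab_count:
            raise ValueError("unavailable/sparse labs overlap the correlated blocks")
        shiftable = {s.name for s in variable_schema_names(self.n_vars)}
        for race, shifts in self.race_shift.items():
            if race not in RACES:
                raise ValueError(f"race_shift: unknown race {race!r}")
            for cov in shifts:
                if cov not in shiftable:
                    raise ValueError(f"race_shift: unknown covariate {cov!r}")


def variable_schema_names(n_vars: int) -> list[VariableSpec]:
    """Bare name/source layout: psa, comorbidity_count, age, bmi, lab_004.."""
    specs = [
        VariableSpec("psa", "lab", skewed=True),
        VariableSpec("comorbidity_count", "diagnosis"),
        VariableSpec("age", "demographic"),
        VariableSpec("bmi", "demographic"),
    ]
    for i in range(4, n_vars):
        specs.append(VariableSpec(f"lab_{i:03d}", "lab"))
    return specs


def variable_schema(config: SimulationConfig) -> list[VariableSpec]:
    """Full schema with skewed/available flags for this configuration.

    Layout (defaults in parentheses): indices 0-3 are the named variables;
    correlated blocks occupy the first lab indices (4..51); the 11 lab members
    of the 12-variable log-transform set follow (52..62); the last
    ``n_unavailable`` variables (91..100) are never captured and the
    ``sparse_lab_count`` before them (84..90) are captured so rarely they
    exceed any reasonable missingness ceiling.
    """
    specs = variable_schema_names(config.n_vars)
    block_end = 4 + config.n_blocks * config.block_size
    n_skew_labs = min(11, max(0, config.n_vars - config.n_unavailable
                              - config.sparse_lab_count - block_end))
    for i in range(block_end, block_end + n_skew_labs):
        specs[i].skewed = True
    for i in range(config.n_vars - config.n_unavailable, config.n_vars):
        specs[i].available = False
    return specs


def sparse_lab_names(config: SimulationConfig) -> list[str]:
    lo = config.n_vars - config.n_unavailable - config.sparse_lab_count
    hi = config.n_vars - config.n_unavailable
    return [f"lab_{i:03d}" for i in range(lo, hi)]


def default_true_beta(config: SimulationConfig) -> pd.Series:
    """Sparse truth: effects on PSA, comorbidity burden and two singleton labs."""
    specs = variable_schema(config)
    beta = pd.Series(0.0, index=[s.name for s in specs])
    if config.true_beta is not None:
        for name, val in config.true_beta.items():
            if name not in beta.index:
                raise ValueError(f"true_beta: unknown variable {name!r}")
            beta[name] = float(val)
        return beta
    beta["psa"] = 0.5
    beta["comorbidity_count"] = 0.3
    block_end = 4 + config.n_blocks * config.block_size
    singles = [s.name for s in specs[block_end:]
               if s.available and not s.skewed and s.name not in sparse_lab_names(config)]
    if len(singles) >= 2:
        beta[singles[0]] = 0.4
        beta[singles[1]] = -0.4
    return beta


@dataclass
class CohortTables:
    demographics: pd.DataFrame
    medications: pd.DataFrame
    labs: pd.DataFrame
    diagnoses: pd.DataFrame
    vitals_outcome: pd.DataFrame

    def copy(self) -> "CohortTables":
        return CohortTables(*(getattr(self, f).copy() for f in
                              ("demographics", "medications", "labs",
                               "diagnoses", "vitals_outcome")))

    def validate(self) -> None:
        meds = self.medications
        if len(meds) and (pd.to_datetime(meds["start_date"]) > pd.to_datetime(meds["end_date"])).any():
            raise ValueError("medication with start_date after end_date")
        known = set(self.demographics["patient_id"])
        for name in ("medications", "labs", "diagnoses", "vitals_outcome"):
            tab = getattr(self, name)
            if len(tab) and not set(tab["patient_id"]) <= known:
                raise ValueError(f"{name} references unknown patient_id")
        if len(self.labs) and (self.labs["value"] < 0).any():
            raise ValueError("negative lab value")


@dataclass
class GroundTruth:
    true_beta: pd.Series
    patients: pd.DataFrame  # patient_id, is_crpc, true_crpc_date, eta, time_months, event


def _block_correlated_gaussian(rng, n, config: SimulationConfig) -> np.ndarray:
    """n x n_vars standard-normal matrix; equicorrelated blocks among lab
    indices [4, 4 + n_blocks*block_size); everything else independent."""
    p = config.n_vars
    Z = rng.standard_normal((n, p))
    rho = config.within_block_rho
    if rho > 0:
        factors = rng.standard_normal((n, config.n_blocks))
        for b in range(config.n_blocks):
            lo = 4 + b * config.block_size
            hi = lo + config.block_size
            Z[:, lo:hi] = (np.sqrt(rho) * factors[:, [b]]
                           + np.sqrt(1 - rho) * Z[:, lo:hi])
    return Z


def _calibrate_dropout(T, admin, u, target) -> float:
    """Bisection on the exponential dropout rate so that the realized censored
    fraction (with these exact draws) hits the target."""
    def frac(rate):
        drop = -np.log(u) / rate if rate > 0 else np.full_like(T, np.inf)
        return float(np.mean(np.minimum(admin, drop) < T))

    if target <= 0:
        return 0.0
    lo, hi = 1e-9, 100.0
    if frac(lo) >= target:
        if frac(lo) > target + 0.05:
            warnings.warn(
                "administrative censoring alone exceeds censoring_rate_target; "
                "dropout calibration floored at ~0"
            )
        return lo
    if frac(hi) <= target:
        return hi
    for _ in range(60):
        mid = np.sqrt(lo * hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return np.sqrt(lo * hi)


def _has_rising_triple(v: np.ndarray) -> bool:
    if len(v) < 3:
        return False
    d = np.diff(v)
    return bool(np.any((d[:-1] > 0) & (d[1:] > 0)))


def generate_cohort(config: SimulationConfig) -> tuple[CohortTables, GroundTruth]:
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    specs = variable_schema(config)
    names = [s.name for s in specs]
    beta = default_true_beta(config)
    sparse = set(sparse_lab_names(config))
    pids = np.array([f"P{i:06d}" for i in range(n)])

    race_names = list(config.race_probs)
    races = rng.choice(race_names, size=n, p=[config.race_probs[r] for r in race_names])
    insurance = rng.choice(list(INSURANCE_PROBS), size=n, p=list(INSURANCE_PROBS.values()))

    Z = _block_correlated_gaussian(rng, n, config)
    eta = Z @ beta.to_numpy()

    def shift_for(cov: str) -> np.ndarray:
        out = np.zeros(n)
        for race, shifts in config.race_shift.items():
            if cov in shifts:
                out[races == race] += shifts[cov]
        return out

    # ---- patient roles -------------------------------------------------
    n_crpc = int(round(config.crpc_fraction * n))
    perm = rng.permutation(n)
    is_crpc = np.zeros(n, dtype=bool)
    is_crpc[perm[:n_crpc]] = True
    rest = perm[n_crpc:]
    n_nh = int(round(config.frac_no_hormone * len(rest)))
    n_fp = int(round(config.frac_few_psa * len(rest)))
    no_hormone = np.zeros(n, dtype=bool)
    few_psa = np.zeros(n, dtype=bool)
    no_hormone[rest[:n_nh]] = True
    few_psa[rest[n_nh:n_nh + n_fp]] = True

    # ---- timeline ------------------------------------------------------
    entry_off = rng.integers(0, 4 * 365, size=n)
    entry = STUDY_START + pd.to_timedelta(entry_off, unit="D")
    crpc_off_months = rng.uniform(6, 18, size=n)
    crpc_date = entry + pd.to_timedelta(
        np.round(crpc_off_months * DAYS_PER_MONTH).astype(int), unit="D"
    )
    noncrpc_len_months = rng.uniform(12, 36, size=n)

    # ---- survival draws (clock starts at the detectable index date) ----
    E = rng.exponential(1.0, size=n)
    k = config.weibull_shape
    T = config.baseline_hazard_scale * (E / np.exp(eta)) ** (1.0 / k)
    T = np.maximum(T, 0.1)
    u_drop = rng.uniform(size=n)
    idx_c = np.where(is_crpc)[0]

    # ---- observed covariates -------------------------------------------
    age = np.clip(70 + 8 * Z[:, names.index("age")], 40, 95)
    bmi = np.round(np.clip(27 + 4 * Z[:, names.index("bmi")], 15, 55), 1)
    como_latent = (config.comorbidity_mean
                   + config.comorbidity_sd * Z[:, names.index("comorbidity_count")]
                   + shift_for("comorbidity_count"))
    comorbidity = np.clip(np.round(como_latent), 0, 10).astype(int)
    log_psa_at_dx = (config.psa_mean + config.psa_sd * Z[:, names.index("psa")]
                     + shift_for("psa"))

    # ---- hormone episodes, PSA trajectories, second-line dispenses ------
    # This loop also determines each transitioning patient's *detectable*
    # index date — the earlier of the second-line start and the third value
    # of the earliest rising PSA triple — which anchors the survival clock
    # and the capture windows, exactly as downstream phenotyping will see it.
    med_rows = []
    psa_rows = []
    second_line = np.zeros(n, dtype=bool)
    idx_sl = idx_c[rng.permutation(len(idx_c))[:int(round(config.second_line_fraction * len(idx_c)))]]
    second_line[idx_sl] = True
    sl_class = rng.choice(SECOND_LINE_CLASSES, size=n)
    sl_off = rng.integers(0, 61, size=n)
    index_date = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")

    STEP, JITTER = 91, 10
    for i in range(n):
        if no_hormone[i]:
            # PSA measured but never during a therapy episode
            for m, o in enumerate((0, 90, 180)):
                d = entry[i] + pd.Timedelta(days=o)
                psa_rows.append((pids[i], "PSA", round(float(np.exp(
                    log_psa_at_dx[i] - 0.02 * m + rng.normal(0, config.psa_noise_sd))), 4),
                    d.date()))
            continue
        ep_start = entry[i]
        if is_crpc[i]:
            ep_end = crpc_date[i] + pd.Timedelta(days=365)
        else:
            ep_end = entry[i] + pd.Timedelta(days=int(round(noncrpc_len_months[i] * DAYS_PER_MONTH)))
        # dispenses: 70-day fills every 84 days (gaps of 14 days, merged
        # downstream); the last fill is stretched to cover the episode end
        s = ep_start
        while s < ep_end:
            if s + pd.Timedelta(days=84) >= ep_end:
                e = ep_end
            else:
                e = s + pd.Timedelta(days=70)
            med_rows.append((pids[i], HORMONE, s.date(), e.date()))
            s = s + pd.Timedelta(days=84)
        sl_start = None
        if second_line[i]:
            sl_start = crpc_date[i] + pd.Timedelta(days=int(sl_off[i]))
            med_rows.append((pids[i], sl_class[i], sl_start.date(),
                             (sl_start + pd.Timedelta(days=90)).date()))

        # PSA measurement grid
        span = (ep_end - ep_start).days
        base = np.arange(0, span + 1, STEP)
        jit = rng.integers(-JITTER, JITTER + 1, size=len(base))
        offs = np.clip(base + jit, 0, span)
        offs[0] = 0
        if few_psa[i]:
            offs = offs[:2]
        dates = ep_start + pd.to_timedelta(offs, unit="D")
        t_months = offs / DAYS_PER_MONTH
        if is_crpc[i]:
            t_crpc = (crpc_date[i] - ep_start).days / DAYS_PER_MONTH
            s_pre = rng.uniform(0.05, 0.15)
            s_post = rng.uniform(0.10, 0.25)
            mean = np.where(t_months <= t_crpc,
                            log_psa_at_dx[i] + s_pre * (t_crpc - t_months),
                            log_psa_at_dx[i] + s_post * (t_months - t_crpc))
            post = t_months > t_crpc
        else:
            s_pre = rng.uniform(0.05, 0.15)
            end_m = span / DAYS_PER_MONTH
            mean = log_psa_at_dx[i] + s_pre * (end_m - t_months)
            post = np.zeros(len(t_months), dtype=bool)

        vals = mean + rng.normal(0, config.psa_noise_sd, size=len(mean))
        if config.enforce_detectability:
            if is_crpc[i]:
                for _ in range(20):
                    if _has_rising_triple(vals[post]):
                        break
                    vals[post] = mean[post] + rng.normal(0, config.psa_noise_sd, size=int(post.sum()))
                else:
                    vals[post] = np.sort(vals[post])
            elif not few_psa[i]:
                for _ in range(20):
                    if not _has_rising_triple(vals):
                        break
                    vals = mean + rng.normal(0, config.psa_noise_sd, size=len(mean))
                else:
                    vals = np.sort(vals)[::-1]
        for d, v in zip(dates, vals):
            psa_rows.append((pids[i], "PSA", round(float(np.exp(v)), 4), d.date()))

        if is_crpc[i]:
            d = np.diff(vals)
            hits = np.where((d[:-1] > 0) & (d[1:] > 0))[0]
            psa_idx = dates[hits[0] + 2] if len(hits) else crpc_date[i] + pd.Timedelta(days=90)
            cands = [psa_idx] if sl_start is None else [psa_idx, sl_start]
            index_date[i] = min(cands)

    anchor = pd.DatetimeIndex(index_date.where(pd.Series(is_crpc),
                                               entry + pd.to_timedelta(183, unit="D")))

    # ---- censoring calibrated against the realized index dates ---------
    admin = np.where(is_crpc,
                     (STUDY_END - anchor).days.to_numpy(), 365.0) / DAYS_PER_MONTH
    rate = _calibrate_dropout(T[idx_c], admin[idx_c], u_drop[idx_c],
                              config.censoring_rate_target)
    drop = -np.log(u_drop) / rate if rate > 0 else np.full(n, np.inf)
    C = np.minimum(admin, drop)
    time_months = np.minimum(T, C)
    event = T <= C

    demographics = pd.DataFrame({
        "patient_id": pids,
        "birth_date": (anchor - pd.to_timedelta(np.round(age * 365.25).astype(int), unit="D")).date,
        "race": races,
        "bmi": bmi,
        "insurance": insurance,
    })

    # ---- diagnoses ------------------------------------------------------
    dx_rows = []
    for i in range(n):
        dx_rows.append((pids[i], "185", entry[i].date()))
        cnt = comorbidity[i]
        if cnt > 0:
            codes = rng.choice(WEIGHT_ONE_PREFIXES, size=cnt, replace=False)
            offs = rng.integers(30, 700, size=cnt)
            for c, o in zip(codes, offs):
                dx_rows.append((pids[i], c, (anchor[i] - pd.Timedelta(days=int(o))).date()))
    diagnoses = pd.DataFrame(dx_rows, columns=["patient_id", "code", "date"])

    # ---- non-PSA labs ---------------------------------------------------
    lab_rows = []
    lab_vars = [(j, s) for j, s in enumerate(specs)
                if s.source == "lab" and s.available and s.name != "psa"]
    for j, s in lab_vars:
        z = Z[:, j]
        if s.skewed:
            vals = np.exp(1.0 + 0.8 * z)
        else:
            vals = np.maximum(100 + 15 * z, 0.01)
        offs = rng.integers(-45, 46, size=n)
        captured = np.ones(n, dtype=bool)
        if s.name in sparse:
            captured = rng.uniform(size=n) < config.sparse_lab_capture_rate
        dates = anchor + pd.to_timedelta(offs, unit="D")
        for i in np.where(captured)[0]:
            lab_rows.append((pids[i], s.name, round(float(vals[i]), 4), dates[i].date()))

    medications = pd.DataFrame(med_rows, columns=["patient_id", "drug_class",
                                                  "start_date", "end_date"])
    labs = pd.DataFrame(psa_rows + lab_rows,
                        columns=["patient_id", "analyte", "value", "date"])
    labs = labs.sort_values(["patient_id", "analyte", "date"], kind="stable").reset_index(drop=True)

    # ---- outcome table ---------------------------------------------------
    death = np.where(is_crpc & event, 1, 0)
    death_date = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
    fu_date = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
    t_days = np.maximum(np.round(time_months * DAYS_PER_MONTH).astype(int), 3)
    for i in range(n):
        if is_crpc[i]:
            end = anchor[i] + pd.Timedelta(days=int(t_days[i]))
            fu_date[i] = end
            if death[i]:
                death_date[i] = end
        else:
            ep_end = entry[i] + pd.Timedelta(days=int(round(noncrpc_len_months[i] * DAYS_PER_MONTH)))
            fu_date[i] = ep_end + pd.Timedelta(days=int(rng.integers(0, 366)))
    vitals_outcome = pd.DataFrame({
        "patient_id": pids,
        "death_date": death_date.dt.date,
        "last_followup_date": fu_date.dt.date,
    })

    tables = CohortTables(demographics, medications, labs, diagnoses, vitals_outcome)
    truth = GroundTruth(
        true_beta=beta,
        patients=pd.DataFrame({
            "patient_id": pids,
            "is_crpc": is_crpc,
            "true_crpc_date": pd.Series(crpc_date).where(pd.Series(is_crpc), pd.NaT).dt.date,
            "index_date": index_date.dt.date,
            "eta": eta,
            "time_months": np.where(is_crpc, time_months, np.nan),
            "event": np.where(is_crpc, event, False),
        }),
    )
    return tables, truth


def inject_missingness(tables: CohortTables, missing_rate: float, seed: int) -> CohortTables:
    """Delete each non-PSA lab row independently with probability
    ``missing_rate`` (missing completely at random). PSA and medication rows
    are never touched. Returns a new table set; the input is unmodified."""
    if not (0 <= missing_rate < 1):
        raise ValueError(f"missing_rate out of [0, 1): {missing_rate}")
    out = tables.copy()
    if missing_rate == 0:
        return out
    rng = np.random.default_rng(seed)
    labs = out.labs
    eligible = (labs["analyte"] != "PSA").to_numpy()
    u = rng.uniform(size=len(labs))
    drop = eligible & (u < missing_rate)
    out.labs = labs.loc[~drop].reset_index(drop=True)
    return out


# ---- persistence ---------------------------------------------------------

TABLE_FILES = {
    "demographics": "demographics.csv",
    "medications": "medications.csv",
    "labs": "labs.csv",
    "diagnoses": "diagnoses.csv",
    "vitals_outcome": "vitals_outcome.csv",
}


def write_cohort(tables: CohortTables, out_dir, config: SimulationConfig | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for attr, fname in TABLE_FILES.items():
        getattr(tables, attr).to_csv(out / fname, index=False, lineterminator="\n")
    manifest = {"schema_version": 1}
    if config is not None:
        manifest["seed"] = config.seed
        manifest["config"] = asdict(config)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))


def read_cohort(in_dir) -> CohortTables:
    p = Path(in_dir)
    frames = {attr: pd.read_csv(p / fname) for attr, fname in TABLE_FILES.items()}
    return CohortTables(**frames)


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "true_beta": {k: float(v) for k, v in truth.true_beta.items()},
        "patients": truth.patients.astype(str).to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
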