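import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from crpcsurv.features import (  # noqa: E402
    extract_features, impute_penalized_gaussian, log_transform, standardize,
)
from crpcsurv.phenotyping import phenotype_cohort  # noqa: E402
from crpcsurv.synthetic import (  # noqa: E402
    SimulationConfig, generate_cohort, inject_missingness, variable_schema,
)


@pytest.fixture(scope="session")
def small_cohort():
    """One medium synthetic cohort shared across tests (read-only)."""
    cfg = SimulationConfig(n_patients=300, seed=7, crpc_fraction=0.5)
    tables, truth = generate_cohort(cfg)
    tables = inject_missingness(tables, cfg.missing_rate, seed=71)
    phen = phenotype_cohort(tables)
    return cfg, tables, truth, phen


@pytest.fixture(scope="session")
def small_features(small_cohort):
    """(raw, imputed, standardized+params) feature matrices for the shared cohort."""
    cfg, tables, truth, phen = small_cohort
    fm_raw = log_transform(extract_features(tables, phen, variable_schema(cfg)))
    fm_imp = impute_penalized_gaussian(fm_raw, seed=5)
    fm_std, params = standardize(fm_imp)
    return fm_raw, fm_imp, fm_std, params
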