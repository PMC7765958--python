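import numpy as np
import pandas as pd
import pytest

from mirmaster.simulate import (
    SimulationConfig,
    generate_study,
    generate_target_databases,
)


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study (seed 0) with its target databases."""
    cfg = SimulationConfig()
    study = generate_study(cfg)
    dbset = generate_target_databases(study.truth, cfg)
    return cfg, study, dbset


@pytest.fixture(scope="session")
def small_study():
    """A reduced study for fast pipeline-level tests."""
    cfg = SimulationConfig(
        n_genes=200, n_mirnas=30, n_planted_regulations=15, targets_per_regulator=5,
        n_null_de_mirnas=4, seed=7,
    )
    study = generate_study(cfg)
    dbset = generate_target_databases(study.truth, cfg)
    return cfg, study, dbset


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_matrix(values, features=None, samples=None) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=features, columns=samples)
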