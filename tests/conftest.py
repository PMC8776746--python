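import numpy as np
import pandas as pd
import pytest

from stresspan.environment import STRESS_COLUMNS, standardize_environment
from stresspan.synthetic import SimulationConfig, simulate_dataset, simulate_design


@pytest.fixture(scope="session")
def small_config():
    """A dataset small enough for fast unit tests but with full structure."""
    return SimulationConfig(n_genes=300, n_snp_loci=300, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def study_design():
    """Field-scale design (20 sites x 3 samples x 6 strains) + stress profiles."""
    cfg = SimulationConfig(seed=42)
    rng = np.random.default_rng(42)
    design, raw = simulate_design(cfg, rng)
    stress = standardize_environment(raw)
    return design, stress


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def stress_design_matrix(study_design):
    design, stress = study_design
    merged = design.merge(stress, on="sample_id")
    X = np.column_stack(
        [np.ones(len(merged))] + [merged[s].to_numpy() for s in STRESS_COLUMNS]
    )
    site = pd.factorize(merged["site_id"])[0]
    samp = pd.factorize(merged["sample_id"])[0]
    return X, site, samp
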