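import numpy as np
import pytest

from tallgc import SimulationConfig, simulate_cohort

PLANTED_FOLD2 = tuple((f"SIG{i}", 2.0) for i in range(5))


@pytest.fixture(scope="session")
def planted_cohort():
    """n=50 training-style cohort, 100 genes, 5 planted at fold 2."""
    cfg = SimulationConfig(n_genes=100, planted_genes=PLANTED_FOLD2, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """n=50 cohort with no outcome signal (all folds 1)."""
    cfg = SimulationConfig(n_genes=100, planted_genes=(), seed=43)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
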