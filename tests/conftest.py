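import numpy as np
import pytest

from ecmflock.experiments import pattern_diversity_sweep
from ecmflock.params import SimulationParams


@pytest.fixture(scope="session")
def confluent_sweep():
    """Combined noise / guidance / feedback sweep at confluence (800 cells),
    5 seeded replicates per condition; shared by the directional and PCA
    checks.  Returns (table, pca_summary)."""
    return pattern_diversity_sweep(reps=5, base_seed=0)


@pytest.fixture(scope="session")
def subconfluent_sweep():
    """The same sweep at sub-confluence (50 cells), 10 replicates."""
    return pattern_diversity_sweep(SimulationParams(n_cells=50), reps=10, base_seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
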