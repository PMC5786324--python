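import numpy as np
import pytest

from dpgp import DPConfig, SimulationSpec, TimeGrid, run_sampler, simulate_dataset


@pytest.fixture
def grid8():
    return TimeGrid(np.arange(8.0))


@pytest.fixture(scope="session")
def three_cluster_ds():
    """Three well-separated GP clusters of 50 genes each (tight member noise)."""
    spec = SimulationSpec(n_clusters=3, sizes=50, length_scale=1.0,
                          signal_variance=1.0, marginal_variance=0.05)
    return simulate_dataset(spec, seed=1)


@pytest.fixture(scope="session")
def three_cluster_trace(three_cluster_ds):
    cfg = DPConfig(max_iterations=300, seed=7)
    return run_sampler(three_cluster_ds.matrix, cfg), cfg
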