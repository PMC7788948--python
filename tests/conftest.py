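import numpy as np
import pytest

from scc import ExpressionMatrix, SimulationConfig, simulate


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(7)
    values = rng.poisson(2.0, size=(30, 12)).astype(float)
    return ExpressionMatrix(values)


@pytest.fixture
def two_cluster_matrix() -> ExpressionMatrix:
    """40 cells in two well-separated planted types, 60 genes."""
    rng = np.random.default_rng(11)
    g, c = 60, 40
    means = np.full((g, c), 2.0)
    means[:30, :20] = 20.0  # type A markers
    means[30:, 20:] = 20.0  # type B markers
    return ExpressionMatrix(rng.poisson(means).astype(float))


@pytest.fixture(scope="session")
def sim_small():
    """A small simulated dataset reused across tests (fast, deterministic)."""
    return simulate(SimulationConfig(n_genes=300, n_cells=45, n_types=3, seed=5))
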