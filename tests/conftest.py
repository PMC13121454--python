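import numpy as np
import pytest

from sctwas import CellCountMatrix, SimulationConfig
from sctwas.simulate import simulate_expression_counts, simulate_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cells(rng):
    """20 cells x 5 genes over 4 individuals and 2 cell types."""
    counts = rng.poisson(5.0, size=(20, 5))
    return CellCountMatrix(
        counts=counts,
        gene_ids=np.array([f"g{j}" for j in range(5)]),
        cell_individual=rng.choice(["I0", "I1", "I2", "I3"], size=20),
        cell_type=rng.choice(["T", "B"], size=20),
        cell_depth=counts.sum(axis=1),
    )


@pytest.fixture(scope="session")
def signal_cohort():
    """One simulated cohort with strong genetic signal (abundant cell type)."""
    gb = simulate_genotypes(300, 20, rho=0.5, seed=42)
    cfg = SimulationConfig(n_individuals=300, n_snps=20,
                           cells_per_individual=209,
                           effect_low=2e-6, effect_high=1e-5,
                           n_replicates=1, seed=42)
    rng = np.random.default_rng(43)
    return simulate_expression_counts(gb, cfg, seed=rng)
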