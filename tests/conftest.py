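import numpy as np
import pytest

from harvestgs.config import SimulationConfig
from harvestgs.simulate import simulate_genotypes, simulate_phenotypes


@pytest.fixture(scope="session")
def small_population():
    """A compact two-harvest population reused across test modules."""
    cfg = SimulationConfig(
        n_parents=12,
        n_progeny=150,
        n_markers=250,
        n_qtl_sim=120,
        n_harvests=2,
        h2_per_harvest=(0.35, 0.35),
        genetic_corr=((1.0, 0.7), (0.7, 1.0)),
        n_blocks=3,
        block_sd=15.0,
        harvest_means=(100.0, 180.0),
        missing_rate=0.02,
        seed=42,
    )
    sim = simulate_genotypes(cfg)
    pheno, truth = simulate_phenotypes(sim, cfg)
    return cfg, sim, pheno, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
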