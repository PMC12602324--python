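import numpy as np
import pytest

from gxewas.simulate import SimulationConfig, item_domain_mapping, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """Two tiny cohorts with planted effects, shared by integration tests."""
    cfg = SimulationConfig(
        n_cohorts=2, n_subjects=(260, 220), stress_means=(0.36, 0.51),
        n_batches=(4, 3), n_snps=24, n_cpgs=20, ld_block_size=4,
        missing_rate_items=0.05,
        effect_registry_sizes={"g": 2, "e": 2, "gxe": 2, "mediated": 1},
        seed=11,
    )
    cohorts, registry = simulate_study(cfg)
    return cfg, cohorts, registry


@pytest.fixture(scope="session")
def small_mapping(small_study):
    cfg, _, _ = small_study
    return item_domain_mapping(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_design(rng, n=40, n_snps=5, n_cpgs=4, n_cov=3, missing_rate=0.1):
    """A small random ScanDesign-shaped tuple for oracle comparisons."""
    M = rng.random((n, n_cpgs))
    E = rng.standard_normal(n)
    maf = rng.uniform(0.2, 0.5, n_snps)
    G = (rng.random((n, n_snps)) < maf).astype(float) + (rng.random((n, n_snps)) < maf)
    G = (G >= 1).astype(float)  # dominant coded
    if missing_rate:
        G[rng.random((n, n_snps)) < missing_rate] = np.nan
    C = rng.standard_normal((n, n_cov))
    return M, E, G, C
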