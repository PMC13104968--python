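import numpy as np
import pytest

from paleoimmune.config import ScanConfig, SimConfig
from paleoimmune.scan import run_scan
from paleoimmune.sim import (
    make_ld_reference,
    sample_cohort,
    simulate_genes,
    simulate_trajectories,
)


@pytest.fixture(scope="session")
def small_config():
    """Compact structured cohort: fast enough for per-test reuse."""
    return SimConfig(seed=11, n_blocks=30, variants_per_block=40,
                     n_individuals=400, generations=200)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    traj = simulate_trajectories(small_config)
    return sample_cohort(traj, small_config)


@pytest.fixture(scope="session")
def small_selection(small_cohort):
    cohort, _ = small_cohort
    return run_scan(cohort, ScanConfig())


@pytest.fixture(scope="session")
def small_ld(small_config):
    return make_ld_reference(small_config)


@pytest.fixture(scope="session")
def gene_map(small_cohort):
    cohort, _ = small_cohort
    return simulate_genes(cohort.variants, n_genes=30)


@pytest.fixture(scope="session")
def ldsc_reference():
    """Larger LD reference for the summary-statistic estimators."""
    cfg = SimConfig(seed=1, n_blocks=400, variants_per_block=50)
    return cfg, make_ld_reference(cfg)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
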