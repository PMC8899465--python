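import numpy as np
import pytest

from lfdat import ScenarioConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_dataset():
    """A modest alternative-model dataset: 120 subjects, 10 common SNPs."""
    cfg = ScenarioConfig(n=120, L=10, region_class="common", c=7.0, theta="case1", seed=11)
    geno, pheno, effect, beta_grid = simulate_dataset(cfg)
    return cfg, geno, pheno, effect, beta_grid


@pytest.fixture
def null_dataset():
    cfg = ScenarioConfig(n=80, L=8, region_class="common", seed=5)
    geno, pheno, _, _ = simulate_dataset(cfg, null=True)
    return cfg, geno, pheno
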