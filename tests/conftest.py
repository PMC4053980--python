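import numpy as np
import pytest

from cistriad import SimConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Mid-size synthetic cohort shared by read-only tests."""
    config = SimConfig(
        seed=7,
        n_genes=60,
        n_cpgs=300,
        n_snps=800,
        n_mqtl=20,
        n_eqtl=10,
        n_methexpr=15,
        n_ae_regions=10,
        chrom_length_bp=8_000_000,
    )
    return simulate_cohort(config)
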