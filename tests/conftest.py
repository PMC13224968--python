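import numpy as np
import pytest

from aftnet import SimConfig, SNPSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Compact simulated cohort (well-conditioned single-indicator SNPs)."""
    panel = (
        SNPSpec("G1_rs1", 0.3, -0.3),
        SNPSpec("G2_rs2", 0.2, 0.25),
        SNPSpec("G3_rs3", 0.4, 0.0),
    )
    cohort, truth = simulate_cohort(
        SimConfig(n_subjects=250, snp_panel=panel, snp_encoding="alt_carrier",
                  seed=11)
    )
    return cohort, truth


@pytest.fixture(scope="session")
def default_cohort():
    """Full-structure cohort: 55 features, paired carrier indicators."""
    return simulate_cohort(SimConfig(n_subjects=400, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
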