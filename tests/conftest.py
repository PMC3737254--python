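import numpy as np
import pytest

from adiposeg.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def paper_config():
    """Study-condition configuration: group sizes, allele frequencies and
    mixture parameters of the two-group design."""
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def paper_cohort(paper_config):
    return simulate_cohort(paper_config)


@pytest.fixture(scope="session")
def unit_latent_config():
    """Configuration whose latent traits are exactly standard normal, so the
    measurement model's implied correlation matrix is loadings @ loadings.T
    + diag(uniquenesses)."""
    return SimulationConfig(
        n_fh_minus=50_000,
        n_fh_plus=50_000,
        q_fh_minus=0.0,
        q_fh_plus=0.0,
        d2=0.0,
        s=1.0,
        frame_gender_effect=0.0,
        frame_sd=1.0,
        adiposity_age_slope=0.0,
        seed=5,
    )


def mixture_sample(rng, n, m1=-0.5487, d2=0.93, s=0.30, alpha=0.59):
    """Direct draw from the equal-variance two-mode normal mixture."""
    upper = rng.random(n) < alpha
    return m1 + d2 * upper + rng.normal(0.0, s, n)
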