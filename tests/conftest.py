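import numpy as np
import pytest

import myodens as md


@pytest.fixture(scope="session")
def reference_cohort():
    """Synthetic reference cohort at the published generating parameters."""
    return md.generate_cohort(md.CohortSpec(n=5000, seed=42))


@pytest.fixture(scope="session")
def lms_sample():
    """BCCG sample with a linearly declining median, constant lambda/sigma."""
    rng = np.random.default_rng(11)
    n = 2000
    ages = rng.uniform(18.0, 80.0, n)
    z = rng.standard_normal(n)
    lam, sigma = 1.0, 0.06
    mu = 26.0 - 0.08 * ages
    y = mu * (1.0 + lam * sigma * z) ** (1.0 / lam)
    return ages, y, {"lambda": lam, "sigma": sigma, "mu_intercept": 26.0,
                     "mu_slope": -0.08}


@pytest.fixture(scope="session")
def fitted_model(lms_sample):
    ages, y, _ = lms_sample
    return md.fit_lms(ages, y, sex="F", outcome="musd_leg")


@pytest.fixture(scope="session")
def noisy_phantom():
    """Noisy phantom with 20% intramuscular fat for end-to-end accuracy checks."""
    spec = md.PhantomSpec(shape=(260, 260, 16), fat_fraction=0.2,
                          noise_sd=15.0, seed=7)
    volume, truth = md.generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, fat-free phantom: every compartment is a pure HU constant."""
    spec = md.PhantomSpec(shape=(260, 260, 8), fat_fraction=0.0,
                          noise_sd=0.0, seed=1)
    volume, truth = md.generate_phantom(spec)
    return spec, volume, truth
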