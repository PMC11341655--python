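import logging

import pytest
from hypothesis import HealthCheck, settings

import bmscreen as b

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# duplicate-concentration averaging of multi-plate positive controls is
# expected in larger simulations; keep test logs quiet
logging.getLogger("bmscreen.dose_response").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_screen():
    """One simulated 20-compound screen at 5% noise, fitted once and shared."""
    cfg = b.SimConfig(n_compounds=20, noise_cv_percent=5.0, seed=11)
    wells, truths = b.simulate_screen(cfg)
    fits = b.fit_screen(wells)
    library = b.simulate_library(cfg.n_compounds)
    return cfg, wells, truths, fits, library


@pytest.fixture(scope="session")
def zero_noise_screen():
    """A noiseless 8-compound screen: signals sit exactly on the 4PL truth."""
    cfg = b.SimConfig(n_compounds=8, noise_cv_percent=0.0, seed=3)
    wells, truths = b.simulate_screen(cfg)
    return cfg, wells, truths
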