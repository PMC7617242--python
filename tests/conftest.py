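import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cotrial.growth_model import fit_growth_model
from cotrial.synthetic_data import GrowthSimConfig, simulate_trial

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noise_free_trial():
    """Deterministic two-arm trial lying exactly on the fixed-effect lines."""
    cfg = GrowthSimConfig(
        sd_u0=0.0, sd_u1=0.0, sd_eps=0.0,
        beta0=float(np.log(100.0)), beta1=0.05,
        arm_intercept_shift={"treated": 0.0},
        arm_slope_shift={"treated": -0.02},
        seed=11,
    )
    return simulate_trial(cfg)


@pytest.fixture(scope="session")
def noisy_fit():
    """REML fit of a realistic noisy trial (shared across tests for speed)."""
    cfg = GrowthSimConfig(arm_slope_shift={"treated": -0.03}, seed=23)
    return fit_growth_model(simulate_trial(cfg))
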