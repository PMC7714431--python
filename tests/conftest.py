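import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rapscan import BackgroundModel, bias_test, make_rap_set

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def calibration_runs():
    """200 bias tests with observed sequences drawn from the null itself.

    Shared between the null-calibration check (z should rarely leave
    (-3, 3)) and the p-value uniformity check.
    """
    bg = BackgroundModel.human_genome()
    results = []
    for k in range(200):
        observed = make_rap_set(n=30, length=150, ctd_fraction=0.0, bg=bg, seed=10_000 + k)
        results.append(bias_test(observed, bg=bg, n_sets=500, seed=20_000 + k))
    return results
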