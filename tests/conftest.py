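import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from curvegaze import (
    BendGeometry,
    DetectParams,
    SimConfig,
    StrategyParams,
    detect_cohort,
    simulate_cohort,
    simulate_trial,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


NOISELESS = dict(noise_sd=0.0, vibration_sd=0.0, dropout_prob=0.0)


@pytest.fixture(scope="session")
def bend():
    # inner edge 44.5 m + 7 m lane → the driven path circle is 48 m
    return BendGeometry(inner_edge_radius=44.5, lane_width=7.0)


@pytest.fixture(scope="session")
def clean_waypoint_trial(bend):
    """Noiseless waypoint-tracking trial on the default 48 m bend."""
    params = StrategyParams(strategy="waypoint", **NOISELESS)
    return simulate_trial(bend, params, 11.67, seed=7, path_radius=48.0)


@pytest.fixture(scope="session")
def clean_tp_trial(bend):
    """Noiseless tangent-point-fixation trial."""
    params = StrategyParams(strategy="tp", **NOISELESS)
    return simulate_trial(bend, params, 11.67, seed=7, path_radius=48.0)


@pytest.fixture(scope="session")
def default_cohort():
    """The default 7-subject, 8-trials-per-condition cohort."""
    return simulate_cohort(SimConfig())


@pytest.fixture(scope="session")
def default_cohort_segments(default_cohort):
    """Detected segments + trial summaries for the default cohort."""
    return detect_cohort(default_cohort, DetectParams())


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
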