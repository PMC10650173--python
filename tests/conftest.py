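import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mechanoflim import ProbeGeometry, detect_contact_point
from mechanoflim.synthetic_data import (
    PLRGroundTruth,
    RampProtocol,
    simulate_plr_force_curve,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def probe():
    return ProbeGeometry()


@pytest.fixture(scope="session")
def ramp():
    return RampProtocol()


@pytest.fixture(scope="session")
def elastic_curve(probe, ramp):
    """Noiseless elastic (alpha=0, eta=0) bulk-sample curve."""
    return simulate_plr_force_curve(
        PLRGroundTruth(E0_Pa=1000.0), probe, ramp, bec=False
    )


@pytest.fixture(scope="session")
def elastic_history(elastic_curve):
    return detect_contact_point(elastic_curve)


@pytest.fixture(scope="session")
def plr_curve(probe, ramp):
    """Noiseless viscoelastic curve at band-centre parameters."""
    return simulate_plr_force_curve(
        PLRGroundTruth(E0_Pa=1000.0, alpha=0.2, eta_Pa_s=1.0), probe, ramp
    )


@pytest.fixture(scope="session")
def plr_history(plr_curve):
    return detect_contact_point(plr_curve)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231106)
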