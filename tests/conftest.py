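import numpy as np
import pytest

from caphys.geometry import Centerline, StenosisSpec, make_vessel
from caphys.synthetic import CohortConfig, generate_case_fixture, generate_cohort


@pytest.fixture(scope="session")
def helix() -> Centerline:
    """A synthetic helical centerline with varying radius (non-planar, so a
    full 3-D round-trip is actually exercised)."""
    t = np.linspace(0.0, 4.0 * np.pi, 181)
    pts = np.column_stack([8.0 * np.cos(t), 8.0 * np.sin(t), 3.0 * t])
    radius = 1.5 + 0.4 * np.sin(t / 2.0)
    return Centerline(points=pts, radius=radius)


@pytest.fixture(scope="session")
def straight_tube() -> Centerline:
    return make_vessel(75.0, 1.5, None, 0.0, 151)


@pytest.fixture(scope="session")
def stenosed_vessel() -> Centerline:
    return make_vessel(
        75.0, 1.5, StenosisSpec(center_s=40.0, length=10.0, severity=0.5), 0.0, 301
    )


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortConfig(), seed=12345)


@pytest.fixture(scope="session")
def clean_case():
    """Noise-free physiology fixture with a 50% stenosis."""
    return generate_case_fixture(
        stenosis_severity=0.5, map_mmHg=100.0, v_diastole_target=100.0, noise_sd=0.0, seed=7
    )
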