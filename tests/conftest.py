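import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rootkinetics import GrowthZoneSpec

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_spec():
    """The reference growth zone: V=300 µm/h, P=2 cells/h, l_mature=150 µm."""
    return GrowthZoneSpec(
        meristem_length=500.0,
        initial_cell_length=10.0,
        meristem_strain_rate=0.04,
        elongation_zone_length=400.0,
        elongation_strain_integral=280.0,
    )


@pytest.fixture(scope="session")
def rect_spec():
    """Same parameters with the rectangular strain bump (closed forms)."""
    return GrowthZoneSpec(
        meristem_length=500.0,
        initial_cell_length=10.0,
        meristem_strain_rate=0.04,
        elongation_zone_length=400.0,
        elongation_strain_integral=280.0,
        bump_shape="rectangular",
    )


@pytest.fixture(scope="session")
def steep_spec():
    """A growth zone whose strain bump exceeds P, so per-cell length ratios
    reach 2 and the doubling rule is well-posed even without noise."""
    return GrowthZoneSpec(
        meristem_length=300.0,
        initial_cell_length=15.0,
        meristem_strain_rate=0.05,
        elongation_zone_length=300.0,
        elongation_strain_integral=350.0,
        bump_shape="rectangular",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
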