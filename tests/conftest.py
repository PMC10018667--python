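import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dosescreen.grids import DoseGrid, GridGeometry, RegionMask, Role, Site
from dosescreen.synthetic import SyntheticSpec, make_case

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_geometry() -> GridGeometry:
    return GridGeometry(origin=(0.0, 0.0, 0.0), spacing=(2.0, 2.0, 2.0), shape=(8, 8, 8))


@pytest.fixture
def uniform_field(small_geometry):
    """A flat 10 Gy field with an all-true analysis mask."""
    ref = DoseGrid(small_geometry, np.full(small_geometry.shape, 10.0), label="TPS")
    mask = RegionMask(small_geometry, np.ones(small_geometry.shape, bool), Role.EXTERNAL)
    return ref, mask


@pytest.fixture
def small_lung_spec() -> SyntheticSpec:
    """A cheap lung-like case: coarse grid, small body, single target."""
    return SyntheticSpec(
        site=Site.LUNG_SBRT, seed=42, spacing_mm=2.0, body_radius_mm=24.0,
        target_radius_mm=(6.0,), ptv_margin_mm=5.0, penumbra_sigma_mm=3.0,
    )


@pytest.fixture
def small_mlsrs_spec() -> SyntheticSpec:
    return SyntheticSpec(
        site=Site.MLSRS, seed=7, spacing_mm=1.5, body_radius_mm=30.0, n_targets=3,
        target_radius_mm=(4.0, 5.0, 3.0), prescription_gy=(20.0, 18.0, 22.0),
    )


@pytest.fixture
def small_lung_case(small_lung_spec):
    return make_case(small_lung_spec)


@pytest.fixture
def small_mlsrs_case(small_mlsrs_spec):
    return make_case(small_mlsrs_spec)
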