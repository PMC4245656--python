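import pytest

from crirs.exposure import DustForm, ExposureProfile, PhysicalForm
from crirs.hazard import HazardClass, HazardIndicator, HazardProfile
from crirs.synthetic import InventorySpec, generate_inventory

C = HazardClass
T = HazardIndicator


@pytest.fixture
def mixed_hazard_profile():
    """Hand-checkable profile: 4+0+6+9+0+0+16+12+7 = 54 points."""
    return HazardProfile(
        {
            T.T1: C.C2,
            T.T2: C.NOT_CLASSIFIED,
            T.T3: C.C1,
            T.T4: C.C1,
            T.T5: C.NOT_CLASSIFIED,
            T.T6: C.NOT_CLASSIFIED,
            T.T7: C.C1B,
            T.T8: C.C2,
            T.T9: C.C2,
        }
    )


@pytest.fixture
def mixed_exposure_profile():
    """Hand-checkable profile: 24+8+4+8+16 = 60 points."""
    return ExposureProfile(
        handling_volume_tpy=500.0,
        worker_count=120,
        workplace_count=20,
        form=PhysicalForm("liquid_gas", boiling_point_C=80.0),
        measured_exposure=2.0,
    )


@pytest.fixture
def top_hazard_profile():
    return HazardProfile(
        {
            T.T1: C.C1,
            T.T2: C.C1,
            T.T3: C.C1,
            T.T4: C.C1,
            T.T5: C.C1,
            T.T6: C.C1A,
            T.T7: C.C1A,
            T.T8: C.C1A,
            T.T9: C.C1,
        }
    )


@pytest.fixture
def top_exposure_profile():
    return ExposureProfile(
        handling_volume_tpy=5000.0,
        worker_count=400,
        workplace_count=400,
        form=PhysicalForm("liquid_gas", boiling_point_C=30.0),
        measured_exposure=600.0,
    )


@pytest.fixture(scope="session")
def inventory62():
    """Seeded 62-chemical synthetic inventory with independent indicators."""
    return generate_inventory(InventorySpec(n_chemicals=62, seed=20))


@pytest.fixture(scope="session")
def inventory200():
    return generate_inventory(InventorySpec(n_chemicals=200, seed=7))
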