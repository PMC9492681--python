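import numpy as np
import pytest

from budscale import CultureConditions, MediumProperties, VesselGeometry


@pytest.fixture(scope="session")
def medium() -> MediumProperties:
    """Water-like medium at 30 degC (the package defaults)."""
    return MediumProperties()


@pytest.fixture(scope="session")
def ref_condition() -> CultureConditions:
    """Reference bench condition: 250 mL flask (d = 8.5 cm), 80 mL, 250 rpm."""
    return CultureConditions.from_practical(0.085, 80.0, 250.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def vessel_500() -> VesselGeometry:
    """Nominal 500 mL flask geometry (assumed d = 10.5 cm)."""
    return VesselGeometry(0.105)
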