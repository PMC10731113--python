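import numpy as np
import pytest

from bonequal import MaterialConstants, SpecimenGeometry


@pytest.fixture
def geom() -> SpecimenGeometry:
    """Standard beam: 2 x 3 x 12 mm, 10 mm span, notch at half height."""
    return SpecimenGeometry(B=2.0, W=3.0, L=12.0, S=10.0, a0=1.5)


@pytest.fixture
def mat() -> MaterialConstants:
    """Cortical-bone constants: E = 19.5 GPa, nu = 0.3."""
    return MaterialConstants(E=19.5, nu=0.3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
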