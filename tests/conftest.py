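import numpy as np
import pytest

from mycomech.neohooke import NeoHookeParams
from mycomech.reduction import SpecimenGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def foam_params():
    """A foam-scale parameter pair typical of fitted composites."""
    return NeoHookeParams(c=0.05, d=0.05)


@pytest.fixture
def standard_geometry():
    """The nominal lab specimen: 70 mm diameter, 65 mm tall, flat top."""
    return SpecimenGeometry(diameter=70.0, height=65.0)
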