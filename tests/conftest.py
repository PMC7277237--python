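import numpy as np
import pytest

from molaraxis.annotations_io import BinaryMask, ToothInstance, ToothLabel
from molaraxis.phantom import MolarShapeParams, make_phantom


def mask_from_array(rows) -> BinaryMask:
    """Build a BinaryMask from a list of 0/1 rows."""
    return BinaryMask(np.asarray(rows, dtype=bool))


def block_mask(height, width, r0, r1, c0, c1) -> BinaryMask:
    """Mask with a solid rectangle [r0, r1) x [c0, c1) set."""
    px = np.zeros((height, width), dtype=bool)
    px[r0:r1, c0:c1] = True
    return BinaryMask(px)


@pytest.fixture
def default_params() -> MolarShapeParams:
    return MolarShapeParams()


@pytest.fixture
def upright_phantom(default_params):
    """Noise-free symmetric phantom at 0 degrees on a 240x240 canvas."""
    return make_phantom(default_params, 0.0, canvas=(240, 240))


def instance_from_mask(mask: BinaryMask, fdi: int = 38) -> ToothInstance:
    return ToothInstance(label=ToothLabel.from_fdi(fdi), mask=mask)
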