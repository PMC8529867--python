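import numpy as np
import pytest

from deltarad.imaging import ImageSlice, make_lesion_record
from deltarad.phantoms import TexturePhantomSpec, generate_lesion_image


@pytest.fixture
def phantom_spec():
    return TexturePhantomSpec(seed=42)


@pytest.fixture
def lesion_record(phantom_spec):
    image, mask = generate_lesion_image(phantom_spec, patient_id="P0")
    return make_lesion_record(image, mask, "L0")


@pytest.fixture
def flat_image():
    """A 32x32 homogeneous slice at 40 HU, 1 mm pixels."""
    return ImageSlice(np.full((32, 32), 40, dtype=np.int32), (1.0, 1.0))
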