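import numpy as np
import pytest

from lpcos.synthetic import SyntheticConfig, generate_fundus


@pytest.fixture(scope="session")
def synth_triplet():
    """One default synthetic fundus image with gt/small_gt/fov masks."""
    return generate_fundus(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def clean_bar_image():
    """Noise-free frame with one horizontal dark bar of width 2 px."""
    img = np.full((128, 128), 0.8)
    img[63:65, :] -= 0.4
    return img


@pytest.fixture(scope="session")
def thick_thin_masks():
    """Disjoint thick (20 px) and thin (2 px) horizontal bars, 128x128."""
    gt = np.zeros((128, 128), bool)
    gt[20:40, 10:118] = True  # thick bar, width 20
    gt[90:92, 10:118] = True  # thin bar, width 2
    fov = np.ones((128, 128), bool)
    return gt, fov
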