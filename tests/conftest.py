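import numpy as np
import pytest

from dermocad import synthetic


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def smooth_lesion():
    """One clean lesion image with its ground-truth mask (no hairs)."""
    spec = synthetic.SynthLesionSpec(seed=7)
    img, mask, label = synthetic.generate_lesion_image(spec)
    return img, mask, label


@pytest.fixture(scope="session")
def hairy_lesion(smooth_lesion):
    """The clean lesion with a hair overlay and its hair ground truth."""
    img, _, _ = smooth_lesion
    hspec = synthetic.HairOverlaySpec(n_hairs=8, thickness_px=(1, 3), seed=11)
    hairy, hair_mask = synthetic.add_hairs(img, hspec)
    return hairy, hair_mask
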