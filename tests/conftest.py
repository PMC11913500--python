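import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20231016)


@pytest.fixture(scope="session")
def small_phantom():
    """One 48x48 lesion phantom (image, label)."""
    from dermrestore import LesionPhantomParams, generate_lesion_phantom

    return generate_lesion_phantom(
        LesionPhantomParams(image_size=(48, 48), class_id=3, seed=7)
    )


@pytest.fixture(scope="session")
def hairy_pair(small_phantom):
    """A (clean, hairy, truth-mask) pair on the 48x48 phantom."""
    from dermrestore import HairParams, draw_procedural_hairs

    clean, _ = small_phantom
    return draw_procedural_hairs(clean, HairParams(n_hairs=12, seed=11))
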