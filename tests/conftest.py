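import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phantom_pair():
    """Two desk-scale phantoms with their preprocessed images."""
    from uteroseg.phantom import PhantomConfig, generate_phantom
    from uteroseg.preprocess import preprocess_image

    cfg = PhantomConfig(image_size=128, seed=11)
    out = []
    for i in range(2):
        img, inst = generate_phantom(cfg, i)
        pimg, _, _ = preprocess_image(img)
        out.append((pimg, inst))
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
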