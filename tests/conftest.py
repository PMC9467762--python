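import numpy as np
import pytest

from otoseg import PhantomSpec, make_phantom, suite


@pytest.fixture(scope="session")
def flat_spec() -> PhantomSpec:
    """Texture-free two-constant-region phantom (degenerate intensity bands)."""
    return PhantomSpec(membrane_band=(190, 190), background_band=(40, 40),
                       cone_of_light=None, texture_sd=0.0)


@pytest.fixture(scope="session")
def flat_phantom(flat_spec):
    return make_phantom(flat_spec)


@pytest.fixture(scope="session")
def im1_phantom():
    """IM1: texture-free, smooth gradient shading, no cone."""
    return make_phantom(suite()["IM1"])


def random_label_maps(seed: int, count: int, max_side: int = 8, max_labels: int = 4):
    """Deterministic stream of random small label-map pairs."""
    rng = np.random.default_rng(seed)
    for _ in range(count):
        h = int(rng.integers(2, max_side + 1))
        w = int(rng.integers(2, max_side + 1))
        k1 = int(rng.integers(1, max_labels + 1))
        k2 = int(rng.integers(1, max_labels + 1))
        yield (rng.integers(0, k1, (h, w)), rng.integers(0, k2, (h, w)))
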