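import numpy as np
import pytest

from sinusid import SynthParams, generate_shape, perturb_shape
from sinusid.silhouette import from_mask


@pytest.fixture(scope="session")
def default_params() -> SynthParams:
    return SynthParams(seed=1)


@pytest.fixture(scope="session")
def silhouette(default_params):
    """One default scalloped silhouette."""
    return generate_shape(default_params, 0)


@pytest.fixture(scope="session")
def silhouette_pair(default_params):
    """A matched AM/PM pair of the same case."""
    am = generate_shape(default_params, 0)
    pm = perturb_shape(am, default_params, pair_seed=0)
    return am, pm


@pytest.fixture(scope="session")
def disc_silhouette():
    """Rotationally symmetric disc, radius 35 px."""
    y, x = np.mgrid[0:100, 0:200]
    return from_mask((x - 100) ** 2 + (y - 50) ** 2 <= 35 ** 2)
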