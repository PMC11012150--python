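import numpy as np
import pytest

from bifor.synthetic import SceneSpec

#: Desk-scale scene used by unit tests; acceptance tests run the full-size default.
SMALL_SPEC = SceneSpec(
    shape=(96, 96),
    voxel_size=(0.06, 0.06),
    nucleus_axes=(28.0, 36.0),
    locus_center=(48.0, 58.0),
    locus_sigma=(2.0, 2.0),
    dapi_amplitude=300.0,
    locus_amplitude_green_bg=100.0,
)


@pytest.fixture
def small_spec() -> SceneSpec:
    return SMALL_SPEC


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240613)
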