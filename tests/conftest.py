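import numpy as np
import pytest

from mslat.phantom import Lesion, PhantomSpec, make_baseline_phantom

# lesion centres chosen inside the WM shell of the default geometry
LESION_A = (32.0, 14.0, 28.0)   # radius 4
LESION_B = (48.0, 32.0, 28.0)   # radius 3


@pytest.fixture(scope="session")
def lesioned_spec() -> PhantomSpec:
    return PhantomSpec(
        lesions=(Lesion(LESION_A, 4.0), Lesion(LESION_B, 3.0))
    )


@pytest.fixture(scope="session")
def lesioned_baseline(lesioned_spec):
    return make_baseline_phantom(lesioned_spec, seed=11)


@pytest.fixture(scope="session")
def clean_spec() -> PhantomSpec:
    """Noise-free, artefact-free phantom for exactness checks."""
    return PhantomSpec(noise_sd=0.0, slice_gain_sd=0.0, bias_amplitude=0.0)


@pytest.fixture(scope="session")
def clean_baseline(clean_spec):
    return make_baseline_phantom(clean_spec, seed=1)


@pytest.fixture(scope="session")
def default_baseline():
    return make_baseline_phantom(PhantomSpec(), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
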