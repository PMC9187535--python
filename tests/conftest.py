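import numpy as np
import pytest

from ctriage import NormativeAtlas, PhantomSpec, make_normal_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom plus its tissue label map."""
    return make_normal_phantom(PhantomSpec(noise_sd_hu=0.0))


@pytest.fixture(scope="session")
def noisy_phantom():
    return make_normal_phantom(PhantomSpec(noise_sd_hu=3.0, seed=11))


@pytest.fixture(scope="session")
def atlas40():
    """Normative atlas fitted on 40 independent noisy phantoms (the
    default study training-cohort size)."""
    vols = [make_normal_phantom(PhantomSpec(seed=s))[0] for s in range(40)]
    return NormativeAtlas().fit(vols)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
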