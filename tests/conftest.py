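import numpy as np
import pytest

from dermcad import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_params():
    """Noise-free, hair-free parameters: a pure two-level ellipse."""
    return synthetic.SyntheticParams(
        n_hairs=0,
        salt_pepper_fraction=0.0,
        border_irregularity=0.0,
        texture_sd_lesion=0.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def clean_sample(clean_params):
    return synthetic.generate_lesion_image(clean_params, synthetic.MELANOMA)


@pytest.fixture(scope="session")
def default_melanoma():
    return synthetic.generate_lesion_image(
        synthetic.SyntheticParams(seed=7), synthetic.MELANOMA
    )
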