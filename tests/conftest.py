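import numpy as np
import pytest

from villimorph.synthhist import MucosaSpec, generate_mucosa_image


@pytest.fixture(scope="session")
def default_spec():
    return MucosaSpec(
        n_villi=3,
        villus_height_um=300.0,
        villus_width_um=110.0,
        crypt_depth_um=160.0,
        muscularis_length_um=600.0,
        noise_sd=5.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def default_section(default_spec):
    return generate_mucosa_image(default_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
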