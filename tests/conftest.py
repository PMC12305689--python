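import numpy as np
import pytest

from gfapquant.phantom import PhantomConfig, generate_phantom


def tiny_config(**overrides):
    """A very small phantom (0.6 x 0.8 mm) for fast structural tests."""
    base = dict(
        image_shape=(300, 400),
        beam_diameter_um=600.0,
        peak_depth_um=250.0,
        peak_sigma_um=80.0,
        distal_sigma_um=35.0,
        penumbra_sigma_um=60.0,
        cortex_margin_um=100.0,
        cell_size_um=100.0,
        dose_grid_spacing_um=20.0,
    )
    base.update(overrides)
    return PhantomConfig.small(**base)


@pytest.fixture(scope="session")
def sham_small():
    return generate_phantom(PhantomConfig.small(seed=11, prescription_dose=0.0))


@pytest.fixture(scope="session")
def irradiated_small():
    return generate_phantom(PhantomConfig.small(seed=7, prescription_dose=85.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
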