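import numpy as np
import pytest

from octeval.synthetic import (Cyst, SrfPocket, generate_scene,
                               make_scene_params)


@pytest.fixture(scope="session")
def flat_params():
    """Flat layers (ILM 40, RPE 80, choroid 120), no pit, no lesions."""
    return make_scene_params(width=160, height=128, ilm_level=40,
                             thickness=40, band2_thickness=40,
                             fovea_depth=0.0, speckle_level=0.0)


@pytest.fixture(scope="session")
def flat_scene(flat_params):
    return generate_scene(flat_params, seed=0)


@pytest.fixture(scope="session")
def lesion_params():
    """Pit retina with one interior cyst and one SRF pocket, no speckle."""
    return make_scene_params(
        cysts=(Cyst(center_x=80, center_y=75, semi_axis_x=6, semi_axis_y=4),),
        srf_pockets=(SrfPocket(x_start=150, x_end=200, max_height_px=10),),
        speckle_level=0.0,
    )


@pytest.fixture(scope="session")
def lesion_scene(lesion_params):
    return generate_scene(lesion_params, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
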