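import numpy as np
import pytest

import fdglong as fl
from fdglong.phantom import RegionEffect


@pytest.fixture(scope="session")
def small_atlas() -> fl.LabelAtlas:
    """Desk-scale atlas with small subcortical regions present."""
    return fl.make_atlas((24, 28, 24), 8, seed=11)


@pytest.fixture(scope="session")
def standard_phantom():
    """The standard 40x48x40 phantom: atlas, one noiseless blurred visit, truth."""
    atlas = fl.make_atlas((40, 48, 40), 10, seed=7)
    names = tuple(atlas.names[k] for k in sorted(atlas.names))
    subjects, truth = fl.simulate_cohort(
        4, effect_params=None, seed=1, region_names=names
    )
    blurred = fl.render_visit_image(
        truth, "sub000", 0, atlas, psf_fwhm_mm=8.0, noise_sd=0.0, seed=0
    )
    return atlas, blurred, truth


@pytest.fixture(scope="session")
def two_region_effects() -> dict:
    return {
        "cerebellum": RegionEffect(1.0, 0.0, 0.0),
        "parietal": RegionEffect(1.05, -0.002, -0.0005),
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
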