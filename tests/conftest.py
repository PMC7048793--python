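import numpy as np
import pytest
from hypothesis import settings

import marmoconn as mc
from marmoconn import phantom

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cfg():
    """A fast phantom: 48^3 at 0.35 mm, 6 areas, 1500 cells per injection."""
    return mc.PhantomConfig(
        grid_shape=(48, 48, 48),
        voxel_size=(0.35, 0.35, 0.35),
        n_areas=6,
        outer_radius=7.5,
        cortex_thickness=2.0,
        cells_per_injection=1500,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_phantom(small_cfg):
    """(template, injections, cells, distance matrix) on the fast phantom."""
    return phantom.make_phantom(small_cfg)


@pytest.fixture(scope="session")
def small_cost(small_phantom):
    tpl = small_phantom[0]
    return mc.build_cost_field(tpl)


@pytest.fixture(scope="session")
def default_template():
    """The full-size default phantom template (80^3 at 0.25 mm, 8 areas)."""
    cfg = mc.PhantomConfig(seed=11)
    return cfg, mc.build_template(cfg)


@pytest.fixture(scope="session")
def default_dmat(default_template):
    _, tpl = default_template
    return mc.pairwise_area_distances(tpl)


@pytest.fixture(scope="session")
def uniform_cost():
    """A 21^3 uniform-speed medium with 1 mm voxels, seedable at the center."""
    from marmoconn.wiring import CostField

    return CostField(
        speed=np.ones((21, 21, 21)), f_wm=1.0, f_gm=1.0,
        voxel_size=(1.0, 1.0, 1.0), origin=np.zeros(3),
    )
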