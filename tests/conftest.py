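import numpy as np
import pytest
from hypothesis import settings

from hybridose.calibration import CameraConfig, default_rc_table
from hybridose.nuclide import LU177_LAMBDA_PHYS
from hybridose.phantom import OrganSpec, PhantomSpec, build_phantom

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def camera():
    return CameraConfig()


@pytest.fixture
def sharp_camera():
    """No collimator blur, no scatter: oracle conditions for the planar chain."""
    return CameraConfig(planar_psf_sigma_mm=0.0, scatter_fraction=0.0)


@pytest.fixture
def rc_table():
    return default_rc_table()


def box_organ(name, volume_ml, uptake_mbq, row_cm, col_cm, *, depth=6.0,
              thickness=4.0, lam=LU177_LAMBDA_PHYS, region_class=None, **kw):
    return OrganSpec(
        name, volume_ml, uptake_mbq, lam, depth, row_cm, col_cm,
        thickness_cm=thickness, shape="box", region_class=region_class, **kw
    )


@pytest.fixture
def slab_phantom():
    """Uniform-slab source in a uniform body: closed-form projection case."""
    organs = (
        box_organ("slab", 200.0, 100.0, row_cm=18.0, col_cm=15.0, depth=8.0, thickness=4.0),
    )
    spec = PhantomSpec(
        organs=organs,
        grid_shape=(48, 80, 64),
        background_density_mbq_ml=0.0,
        seed=42,
    )
    return build_phantom(spec)


@pytest.fixture
def multi_organ_box_phantom():
    """Overlap-free multi-organ phantom with box organs and background."""
    organs = (
        box_organ("liver", 1500.0, 150.0, 10.0, 19.0, depth=2.5, thickness=10.0,
                  region_class="liver"),
        box_organ("kidney_right", 150.0, 110.0, 26.0, 8.5, depth=11.0, thickness=4.0,
                  region_class="kidneys"),
        box_organ("kidney_left", 150.0, 110.0, 26.0, 21.5, depth=11.0, thickness=4.0,
                  region_class="kidneys"),
        box_organ("lesion_0", 6.0, 12.0, 33.0, 15.0, depth=13.0, thickness=2.0,
                  region_class="lesion", density_g_ml=1.3),
    )
    spec = PhantomSpec(
        organs=organs, grid_shape=(48, 80, 64), background_density_mbq_ml=0.008, seed=7
    )
    return build_phantom(spec)
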