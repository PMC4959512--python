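import numpy as np
import pytest

from etsim.phantom import GridSpec, PhantomSpec, Primitive, rasterize


@pytest.fixture(scope="session")
def sphere_volume():
    """Rasterized 50 nm-radius sphere on a 2 nm grid (r/voxel = 25)."""
    grid = GridSpec(voxel_nm=2.0, shape=(80, 80, 80))
    prim = Primitive(kind="sphere", center=(80.0, 80.0, 0.0), radius_nm=50.0)
    spec = PhantomSpec(primitives=(prim,), field_of_view_nm=(160.0, 160.0))
    return rasterize(spec, grid), prim


@pytest.fixture(scope="session")
def tube_volume_128():
    """200 nm-diameter solid tube along x in a 128^3 volume (4 nm voxels)."""
    grid = GridSpec(voxel_nm=4.0, shape=(128, 128, 128))
    prim = Primitive(kind="solid-cylinder", center=(256.0, 256.0, 0.0),
                     axis=(1.0, 0.0, 0.0), radius_nm=100.0, length_nm=500.0)
    spec = PhantomSpec(primitives=(prim,), field_of_view_nm=(512.0, 512.0),
                       section_thickness_nm=512.0)
    return rasterize(spec, grid), prim
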