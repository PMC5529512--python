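import numpy as np
import pytest

from cytomech import fttm, piv, synthgen


@pytest.fixture
def substrate48():
    """Soft traction gel on a 48x48 grid at 2 µm spacing."""
    return fttm.GelSubstrate(
        youngs_modulus=1300.0, poisson_ratio=0.48, grid_spacing=2.0, grid_shape=(48, 48)
    )


@pytest.fixture
def dipole_scene(substrate48):
    """A centered contractile dipole (F = 1e5 pN, d = 20 µm) and its field."""
    dip = synthgen.DipoleSpec(
        center=(47.0, 47.0), axis=(1.0, 0.0),
        force_magnitude=1e5, separation=20.0, patch_sigma=3.0,
    )
    scene = synthgen.make_traction_scene(substrate48, [dip])
    return dip, scene


def make_uniform_field(shape, ux, uy, spacing=1.0):
    gx, gy = piv.regular_grid(shape, spacing)
    return piv.DisplacementField(
        grid_x=gx, grid_y=gy,
        u_x=np.full(shape, float(ux)), u_y=np.full(shape, float(uy)),
        valid=np.ones(shape, dtype=bool), pixel_size=spacing,
    )
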