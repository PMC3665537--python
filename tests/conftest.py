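import numpy as np
import pytest

from rostrabeam import phantom_forge as pf
from rostrabeam import section_engine as se


@pytest.fixture(scope="session")
def tube_spec() -> pf.MorphotypeSpec:
    """Uniform circular tube: a = b = 2 cm, wall 5 mm, 10 cm span."""
    return pf.MorphotypeSpec(
        name="tube",
        skull_length=1.0,
        rostral_span=0.1,
        width_profile=pf.constant(0.02),
        height_profile=pf.constant(0.02),
        wall_thickness_profile=pf.constant(0.005),
    )


@pytest.fixture(scope="session")
def tube_volume(tube_spec) -> pf.VoxelVolume:
    return pf.generate_rostrum_volume(tube_spec, voxel_size=0.0005)


@pytest.fixture()
def disc_section() -> se.CrossSection:
    """Rasterized solid circle, radius 200 px at 1 mm/px."""
    r_px = 200
    n = 2 * r_px + 5
    off = np.arange(n) - (n - 1) / 2
    yy, xx = np.meshgrid(off, off, indexing="ij")
    mask = xx**2 + yy**2 <= r_px**2
    return se.CrossSection(mask=mask, pixel_size=(1e-3, 1e-3))
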