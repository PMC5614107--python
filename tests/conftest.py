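import numpy as np
import pytest

from depthctf import CtfParams, TiltGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def base_ctf():
    """300 kV / Cs 2.7 mm / A 0.07 parameters at 4000 nm underfocus."""
    return CtfParams(voltage=300.0, cs=2.7, amplitude_contrast=0.07,
                     defocus=4000.0, pixel_size=2.6)


@pytest.fixture
def small_geometry():
    """48 x 8 x 24 voxel volume at 10 A pixels, seven tilts, 3000 nm defocus."""
    angles = np.arange(-60.0, 61.0, 20.0)
    return TiltGeometry(volume_dims=(48, 8, 24), pixel_size=10.0,
                        tilt_angles=angles,
                        center_defocus=np.full(angles.size, 3000.0))
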