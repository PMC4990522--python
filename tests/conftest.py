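import numpy as np
import pytest

from scatterbmd.phantom import MaterialSpec, PhantomSpec, ScanParams, default_qrm_efp
from scatterbmd.simulate import SliceImage, StreakParams


@pytest.fixture
def small_scan() -> ScanParams:
    """128x128, 0.5 mm spacing (64 mm field of view) -- fast to render."""
    return ScanParams(matrix_size=128, pixel_spacing_mm=0.5)


@pytest.fixture
def qrm50() -> PhantomSpec:
    return default_qrm_efp(50.0)


@pytest.fixture
def streaks() -> StreakParams:
    return StreakParams(gain=10.0, seed=7)


def toy_slice(pixels) -> SliceImage:
    return SliceImage(
        pixels=np.asarray(pixels, dtype=np.int16),
        pixel_spacing_mm=1.0,
        slice_thickness_mm=1.0,
    )
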