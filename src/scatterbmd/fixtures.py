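"""Hand-authored toy images with documented expected segmentation results.

Every fixture is tiny (<= 16x16), generated in code, and ships with the
expected mask sizes / counts used by the unit tests.  The registry:

``ring_8x8``
    8x8 grid, 0 HU background, a one-pixel-thick 5x5 square ring of
    1200 HU at rows/cols 1..5.  Expected: periosteal = the filled 5x5
    square (25 px), wall = the 16 ring pixels, endosteal = the 3x3
    interior (9 px).
``two_components``
    16x16 grid with the 5x5 ring (16 px component) and a disjoint 3x3
    ring (8 px component).  Largest-component selection keeps only the
    5x5 ring; expected periosteal = 25 px.
``exterior_7px``
    The ring_8x8 image with exactly 7 pixels at 600 HU outside the
    periosteal square.  Expected artifact count: 7 at a 500 or 600 HU
    cutoff, 0 at 700 HU.
``constant_zero``
    8x8 all-zero image; every mask downstream is empty.
"""

from __future__ import annotations

import numpy as np

from .simulate import SliceImage

__all__ = ["FIXTURE_NAMES", "FIXTURE_EXPECTATIONS", "make_fixture"]

_SPACING = 1.0
_THICKNESS = 1.0

#: documented expected values, used by tests and available to callers
FIXTURE_EXPECTATIONS: dict[str, dict[str, int]] = {
    "ring_8x8": {"periosteal": 25, "wall": 16, "endosteal": 9},
    "two_components": {"periosteal": 25, "wall": 16, "endosteal": 9},
    "exterior_7px": {
        "periosteal": 25,
        "artifacts_at_500": 7,
        "artifacts_at_600": 7,
        "artifacts_at_700": 0,
    },
    "constant_zero": {"periosteal": 0},
}

FIXTURE_NAMES = tuple(FIXTURE_EXPECTATIONS)


def _slice(pixels: np.ndarray) -> SliceImage:
    return SliceImage(
        pixels=pixels.astype(np.int16),
        pixel_spacing_mm=_SPACING,
        slice_thickness_mm=_THICKNESS,
    )


def _square_ring(img: np.ndarray, top: int, left: int, size: int, hu: int) -> None:
    img[top, left : left + size] = hu
    img[top + size - 1, left : left + size] = hu
    img[top : top + size, left] = hu
    img[top : top + size, left + size - 1] = hu


def make_fixture(name: str) -> SliceImage:
    """Build a registered toy image by name.

    Raises
    ------
    KeyError
        For a name not present in the registry.
    """
    if name not in FIXTURE_EXPECTATIONS:
        raise KeyError(
            f"unknown fixture {name!r}; registered: {sorted(FIXTURE_EXPECTATIONS)}"
        )
    if name == "ring_8x8":
        img = np.zeros((8, 8), dtype=np.int16)
        _square_ring(img, 1, 1, 5, 1200)
        return _slice(img)
    if name == "two_components":
        img = np.zeros((16, 16), dtype=np.int16)
        _square_ring(img, 1, 1, 5, 1200)
        _square_ring(img, 9, 10, 3, 1200)
        return _slice(img)
    if name == "exterior_7px":
        img = np.zeros((8, 8), dtype=np.int16)
        _square_ring(img, 1, 1, 5, 1200)
        # 7 artifact pixels, all outside the filled 5x5 square (rows 1-5, cols 1-5)
        for rc in [(0, 7), (2, 7), (4, 7), (6, 7), (7, 0), (7, 3), (7, 6)]:
            img[rc] = 600
        return _slice(img)
    if name == "constant_zero":
        return _slice(np.zeros((8, 8), dtype=np.int16))
    raise AssertionError("unreachable")
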