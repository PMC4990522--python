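"""Exhaustive per-pixel reimplementation of the segmentation chain.

Pure-Python BFS versions of component labelling (8-neighbor), hole
filling (4-neighbor background flood from the border) and artifact
counting, used as an independent oracle against the scipy-based
pipeline on small images.
"""

from __future__ import annotations

from collections import deque

import numpy as np

_N8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_N4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]


def _flood(mask: np.ndarray, start, neighbors) -> set:
    h, w = mask.shape
    seen = {start}
    q = deque([start])
    while q:
        y, x = q.popleft()
        for dy, dx in neighbors:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and (ny, nx) not in seen:
                seen.add((ny, nx))
                q.append((ny, nx))
    return seen


def largest_component_8(binary: np.ndarray) -> np.ndarray:
    """Largest 8-connected True component (first-found on size ties)."""
    remaining = {tuple(p) for p in np.argwhere(binary)}
    best: set = set()
    while remaining:
        comp = _flood(binary, next(iter(remaining)), _N8)
        remaining -= comp
        if len(comp) > len(best):
            best = comp
    out = np.zeros_like(binary, dtype=bool)
    for y, x in best:
        out[y, x] = True
    return out


def fill_holes_4(mask: np.ndarray) -> np.ndarray:
    """Fill background regions not 4-connected to the image border."""
    h, w = mask.shape
    bg = ~mask
    outside = np.zeros_like(mask, dtype=bool)
    for y in range(h):
        for x in (0, w - 1):
            if bg[y, x] and not outside[y, x]:
                for p in _flood(bg, (y, x), _N4):
                    outside[p] = True
    for x in range(w):
        for y in (0, h - 1):
            if bg[y, x] and not outside[y, x]:
                for p in _flood(bg, (y, x), _N4):
                    outside[p] = True
    return mask | (bg & ~outside)


def periosteal_brute(pixels: np.ndarray, contour_hu: float) -> np.ndarray:
    binary = pixels >= contour_hu
    if not binary.any():
        return np.zeros_like(binary, dtype=bool)
    return fill_holes_4(largest_component_8(binary))


def artifact_count_brute(
    pixels: np.ndarray, contour_hu: float, count_hu: float
) -> int:
    """Exterior pixels >= count_hu, one pixel at a time."""
    perio = periosteal_brute(pixels, contour_hu)
    n = 0
    for y in range(pixels.shape[0]):
        for x in range(pixels.shape[1]):
            if not perio[y, x] and pixels[y, x] >= count_hu:
                n += 1
    return n
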