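"""Artifact extraction and counting on HU slices.

The measurement chain mirrors how scattered-artifact abundance is read
off a CBCT slice of a forearm:

1. periosteal contour -- binarize at a cortical threshold (default
   900 HU), keep the largest connected component (8-neighbor), fill its
   interior holes (4-neighbor background) to obtain the filled region
   enclosed by the periosteal surface;
2. endosteal contour -- inside the periosteal region, pixels below the
   cortical threshold form the cancellous/marrow compartment; the
   remainder is the cortical wall;
3. artifact isolation -- subtract everything inside the periosteal
   surface, then keep exterior pixels at or above a counting threshold;
4. threshold sweep -- repeat the count over a ladder of HU thresholds
   (default 500..900 step 20) for a low- and a high-density stack and
   difference the totals;
5. distribution summaries -- mean/sd and percentile ladder of per-slice
   counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import PERIOSTEAL_THRESHOLD_HU
from .simulate import SliceImage

__all__ = [
    "DEFAULT_SWEEP_THRESHOLDS",
    "ContourSet",
    "ArtifactMap",
    "SweepResult",
    "DistributionSummary",
    "extract_periosteal",
    "extract_endosteal",
    "isolate_artifacts",
    "count_artifact_pixels",
    "threshold_sweep",
    "summarize_counts",
]

#: 500..900 HU in steps of 20 (inclusive), the standard counting ladder.
DEFAULT_SWEEP_THRESHOLDS: tuple[int, ...] = tuple(range(500, 901, 20))

# connectivity conventions, fixed: 8-neighbor for foreground components,
# 4-neighbor for hole filling
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)
_STRUCTURE_4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class ContourSet:
    """Periosteal / endosteal / wall masks on the source image grid.

    ``periosteal`` is the filled region enclosed by the periosteal
    contour (wall included); ``endosteal`` the cancellous interior;
    ``wall`` their difference.  Invariants: endosteal is a subset of
    periosteal and wall = periosteal \\ endosteal.
    """

    periosteal: np.ndarray
    endosteal: np.ndarray
    wall: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.periosteal, self.endosteal, self.wall)}
        if len(shapes) != 1:
            raise ValueError(f"contour masks differ in shape: {shapes}")


@dataclass
class ArtifactMap:
    """Binary mask of artifact-candidate pixels outside the periosteal surface."""

    mask: np.ndarray
    source_slice: int = 0

    @property
    def count(self) -> int:
        return int(self.mask.sum())


@dataclass
class SweepResult:
    """Artifact counts per HU threshold for a low- and a high-density stack.

    ``diff`` is ``counts_high - counts_low`` per threshold (flip with
    ``sign=-1`` in :func:`threshold_sweep` for the opposite convention);
    ``optimal_threshold`` maximizes ``diff``, ties broken toward the
    lowest threshold.
    """

    thresholds: np.ndarray
    counts_low: np.ndarray
    counts_high: np.ndarray
    diff: np.ndarray
    optimal_threshold: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "count_low": self.counts_low,
                "count_high": self.counts_high,
                "diff": self.diff,
            }
        )


@dataclass
class DistributionSummary:
    """Five-number-plus summary of per-slice artifact-pixel counts."""

    mean: float
    sd: float
    p5: float
    p10: float
    p25: float
    p50: float
    p75: float
    p90: float
    p95: float

    @property
    def percentiles(self) -> tuple[float, ...]:
        return (self.p5, self.p10, self.p25, self.p50, self.p75, self.p90, self.p95)


def _empty_contours(shape: tuple[int, int]) -> ContourSet:
    z = np.zeros(shape, dtype=bool)
    return ContourSet(periosteal=z.copy(), endosteal=z.copy(), wall=z.copy())


def extract_periosteal(
    image: SliceImage, hu_threshold: float = PERIOSTEAL_THRESHOLD_HU
) -> ContourSet:
    """Filled periosteal region by thresholding and component analysis.

    Pixels at or above ``hu_threshold`` are binarized; the largest
    8-connected component is retained and its interior holes filled
    (4-neighbor background connectivity).  An image with no pixel above
    the threshold yields empty masks, not an error.  Endosteal and wall
    masks are left empty; see :func:`extract_endosteal`.
    """
    binary = image.pixels >= hu_threshold
    if not binary.any():
        return _empty_contours(image.shape)
    labels, n = ndimage.label(binary, structure=_STRUCTURE_8)
    sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    periosteal = ndimage.binary_fill_holes(labels == largest, structure=_STRUCTURE_4)
    out = _empty_contours(image.shape)
    out.periosteal = periosteal
    return out


def extract_endosteal(
    image: SliceImage,
    contours: ContourSet,
    hu_threshold: float = PERIOSTEAL_THRESHOLD_HU,
) -> ContourSet:
    """Split the periosteal region into cortical wall and marrow compartment.

    The endosteal (cancellous) mask is the sub-threshold interior of the
    periosteal region; the wall is the remainder, so wall and endosteal
    partition the periosteal mask exactly.

    Raises
    ------
    ValueError
        If the periosteal mask is empty (the contract requires a prior
        successful periosteal extraction) or shapes mismatch.
    """
    if contours.periosteal.shape != image.shape:
        raise ValueError("periosteal mask shape does not match the image")
    if not contours.periosteal.any():
        raise ValueError("periosteal mask is empty; extract_periosteal first")
    endosteal = contours.periosteal & (image.pixels < hu_threshold)
    wall = contours.periosteal & ~endosteal
    return ContourSet(
        periosteal=contours.periosteal.copy(), endosteal=endosteal, wall=wall
    )


def isolate_artifacts(
    image: SliceImage, contours: ContourSet, hu_min: float
) -> ArtifactMap:
    """Exterior pixels at or above ``hu_min``: the scattered-artifact mask.

    Everything inside the periosteal surface is subtracted first, so the
    result is disjoint from the periosteal mask by construction.
    """
    if contours.periosteal.shape != image.shape:
        raise ValueError("contour masks were not computed on this image shape")
    mask = (~contours.periosteal) & (image.pixels >= hu_min)
    return ArtifactMap(mask=mask, source_slice=image.slice_index)


def count_artifact_pixels(
    stack: Sequence[SliceImage],
    hu_threshold: float,
    contour_hu: float = PERIOSTEAL_THRESHOLD_HU,
) -> list[int]:
    """Per-slice artifact-pixel counts at one counting threshold.

    Each slice is segmented at ``contour_hu`` (periosteal extraction) and
    its exterior pixels >= ``hu_threshold`` enumerated.
    """
    if len(stack) == 0:
        raise ValueError("stack must contain at least one slice")
    counts = []
    for sl in stack:
        contours = extract_periosteal(sl, hu_threshold=contour_hu)
        counts.append(isolate_artifacts(sl, contours, hu_min=hu_threshold).count)
    return counts


def _exterior_values(sl: SliceImage, contour_hu: float) -> np.ndarray:
    contours = extract_periosteal(sl, hu_threshold=contour_hu)
    return sl.pixels[~contours.periosteal]


def per_slice_counts_over_thresholds(
    stack: Sequence[SliceImage],
    thresholds: Sequence[float],
    contour_hu: float = PERIOSTEAL_THRESHOLD_HU,
) -> np.ndarray:
    """Counts array of shape (n_slices, n_thresholds).

    Segments each slice once and evaluates every counting threshold on
    the same exterior pixel set, so the per-slice rows are non-increasing
    in threshold by construction.
    """
    if len(stack) == 0:
        raise ValueError("stack must contain at least one slice")
    thr = np.asarray(thresholds, dtype=float)
    out = np.empty((len(stack), thr.size), dtype=np.int64)
    for i, sl in enumerate(stack):
        vals = _exterior_values(sl, contour_hu)
        out[i] = (vals[:, None] >= thr[None, :]).sum(axis=0)
    return out


def threshold_sweep(
    stack_low: Sequence[SliceImage],
    stack_high: Sequence[SliceImage],
    thresholds: Iterable[float] = DEFAULT_SWEEP_THRESHOLDS,
    contour_hu: float = PERIOSTEAL_THRESHOLD_HU,
    sign: int = 1,
) -> SweepResult:
    """Count artifacts in both stacks over a threshold ladder.

    Counts are summed over slices per threshold; ``diff`` is
    ``sign * (counts_high - counts_low)`` with the default ``sign=1``
    (high minus low).  ``optimal_threshold`` is the argmax of ``diff``,
    ties resolved toward the lowest threshold.
    """
    thr = np.asarray(list(thresholds), dtype=float)
    if thr.size == 0:
        raise ValueError("threshold list must be non-empty")
    if len(stack_low) == 0 or len(stack_high) == 0:
        raise ValueError("both stacks must be non-empty")
    low = per_slice_counts_over_thresholds(stack_low, thr, contour_hu).sum(axis=0)
    high = per_slice_counts_over_thresholds(stack_high, thr, contour_hu).sum(axis=0)
    diff = sign * (high - low)
    optimal = int(thr[int(np.argmax(diff))])
    return SweepResult(
        thresholds=thr.astype(int),
        counts_low=low,
        counts_high=high,
        diff=diff,
        optimal_threshold=optimal,
    )


def summarize_counts(per_slice_counts: Sequence[float]) -> DistributionSummary:
    """Mean, population SD and percentile ladder of per-slice counts.

    The SD uses the population convention (ddof=0); percentiles use
    linear interpolation between order statistics.
    """
    counts = np.asarray(per_slice_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("need at least one count")
    p = np.percentile(counts, [5, 10, 25, 50, 75, 90, 95])
    return DistributionSummary(
        mean=float(counts.mean()),
        sd=float(counts.std(ddof=0)),
        p5=float(p[0]),
        p10=float(p[1]),
        p25=float(p[2]),
        p50=float(p[3]),
        p75=float(p[4]),
        p90=float(p[5]),
        p95=float(p[6]),
    )
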