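"""Count -> density calibration and low/high-BMD classification.

The Compton scatter model is linear in electron density at fixed
geometry, which motivates an ordinary-least-squares line

    count = slope * density + intercept

fit on (known density, mean artifact count) pairs.  Density for an
unknown sample is then read off by inverse prediction,
``(count - intercept) / slope``, with a first-order uncertainty of
``residual_sd / |slope|``.

Classification is a simple cutoff on the artifact count: fewer artifacts
than the cutoff means lower scatter, hence lower mineral density
("low_bmd"); the boundary count itself is assigned to "normal".  When two
cohort means are available the default cutoff is their midpoint.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "CalibrationModel",
    "DensityEstimate",
    "fit_calibration",
    "estimate_density",
    "classify_bmd",
    "midpoint_cutoff",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Least-squares line mapping density to mean artifact count.

    ``slope`` is in counts per density unit (mg HA cm^-3 or relative
    electron density, whichever the calibration pairs used), ``intercept``
    and ``residual_sd`` in counts; ``residual_sd`` uses the n-2
    denominator (0 for an exactly-determined two-point fit).
    """

    slope: float
    intercept: float
    residual_sd: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a calibration needs at least 2 points")
        if not math.isfinite(self.slope):
            raise ValueError("slope must be finite")

    def predict_count(self, density: float) -> float:
        return self.slope * density + self.intercept


@dataclass(frozen=True)
class DensityEstimate:
    """Inverse-prediction result: density value, 1-sigma sd, sign flag."""

    value: float
    sd: float

    @property
    def negative(self) -> bool:
        """Estimates below zero are physically suspect but reported as-is."""
        return self.value < 0


def fit_calibration(
    pairs: Iterable[tuple[float, float]]
) -> CalibrationModel:
    """Ordinary least squares of mean count on known density.

    Raises
    ------
    ValueError
        With fewer than two pairs, or when all densities coincide
        (degenerate design: the slope is unidentifiable).
    """
    data = np.asarray(list(pairs), dtype=float)
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 2:
        raise ValueError("need >= 2 (density, mean_count) pairs")
    density, count = data[:, 0], data[:, 1]
    if np.unique(density).size < 2:
        raise ValueError("degenerate design: all calibration densities identical")
    design = np.column_stack([density, np.ones_like(density)])
    (slope, intercept), *_ = np.linalg.lstsq(design, count, rcond=None)
    resid = count - (slope * density + intercept)
    n = density.size
    residual_sd = float(np.sqrt((resid**2).sum() / (n - 2))) if n > 2 else 0.0
    return CalibrationModel(
        slope=float(slope),
        intercept=float(intercept),
        residual_sd=residual_sd,
        n_points=int(n),
    )


def estimate_density(count: float, model: CalibrationModel) -> DensityEstimate:
    """Invert the calibration line at an observed artifact count.

    Raises
    ------
    ValueError
        If the model slope is zero (density unidentifiable from counts).
    """
    if model.slope == 0:
        raise ValueError("zero calibration slope: density is unidentifiable")
    value = (count - model.intercept) / model.slope
    sd = model.residual_sd / abs(model.slope)
    return DensityEstimate(value=float(value), sd=float(sd))


def classify_bmd(count: float, cutoff: float) -> str:
    """Binary call from an artifact count: ``"low_bmd"`` or ``"normal"``.

    Counts strictly below the cutoff are low BMD; the boundary
    ``count == cutoff`` is assigned to normal.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    return "low_bmd" if count < cutoff else "normal"


def midpoint_cutoff(mean_a: float, mean_b: float) -> float:
    """Midpoint of two calibration-cohort mean counts."""
    return (mean_a + mean_b) / 2.0


def save_model(model: CalibrationModel, path: str | Path) -> None:
    """Persist a calibration model as a flat YAML mapping."""
    Path(path).write_text(yaml.safe_dump(asdict(model), sort_keys=False))


def load_model(path: str | Path) -> CalibrationModel:
    data = yaml.safe_load(Path(path).read_text())
    return CalibrationModel(**data)


def cohort_counts(per_stack_counts: Sequence[Sequence[float]]) -> np.ndarray:
    """Total artifact count per stack (sum over slices), as an array."""
    return np.asarray([float(np.sum(c)) for c in per_stack_counts])
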