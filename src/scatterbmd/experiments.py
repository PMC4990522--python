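"""End-to-end simulation experiments mirroring the phantom and pilot studies.

Each experiment wires the generator, the measurement pipeline and the
calibration layer together under fixed study conditions:

* density ordering -- two 40-slice stacks whose trabecular compartments
  differ only in relative electron density (1.0 vs 1.2, streak gain 10),
  swept over the 500-900 HU threshold ladder; the denser compartment
  should yield more artifact pixels at the optimal threshold.
* calibration recovery -- stacks simulated at hydroxyapatite densities
  {0, 50, 200} mg HA cm^-3 calibrate a count->density line; stacks at a
  held-out 100 mg HA cm^-3 test inverse prediction.
* cohort classification -- two cohorts of stacks (electron density 1.0
  vs 1.2) classified by a midpoint count cutoff.

All randomness is derived from one experiment seed; per-stack seeds are
spaced so slice streams never overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibrate import (
    classify_bmd,
    estimate_density,
    fit_calibration,
    midpoint_cutoff,
)
from .phantom import PhantomSpec, ScanParams, default_qrm_efp
from .pipeline import (
    DEFAULT_SWEEP_THRESHOLDS,
    per_slice_counts_over_thresholds,
    threshold_sweep,
)
from .simulate import SliceImage, StreakParams, simulate_stack

__all__ = [
    "density_ordering_experiment",
    "calibration_recovery_experiment",
    "cohort_classification_experiment",
    "sweep_monotonicity_violations",
    "DensityOrderingResult",
    "CalibrationRecoveryResult",
    "CohortClassificationResult",
]

# stack seeds are spaced beyond any slice count used here so the
# per-slice streams (seed + slice_index) of different stacks never collide
_SEED_STRIDE = 10_000


def _stack_seed(seed: int, k: int) -> int:
    return (seed + k * _SEED_STRIDE) % (2**31 - 1)


@dataclass
class DensityOrderingResult:
    """Per-seed sweep outcomes for the low- vs high-density comparison."""

    optimal_thresholds: list[int]
    totals_low: list[int]
    totals_high: list[int]
    diffs_at_optimal: list[int]

    @property
    def n_seeds_high_exceeds(self) -> int:
        return sum(h > l for l, h in zip(self.totals_low, self.totals_high))

    @property
    def n_seeds_diff_positive(self) -> int:
        return sum(d > 0 for d in self.diffs_at_optimal)


def density_ordering_experiment(
    seed: int,
    n_seeds: int = 10,
    n_slices: int = 40,
    gain: float = 10.0,
    rho_e_low: float = 1.0,
    rho_e_high: float = 1.2,
    scan: ScanParams | None = None,
) -> DensityOrderingResult:
    """Low- vs high-electron-density stacks through the threshold sweep.

    For each of ``n_seeds`` master seeds, simulate one stack per density,
    run the 500-900 HU sweep and record the totals and their difference at
    the optimal threshold.
    """
    scan = scan or ScanParams()
    params = StreakParams(gain=gain)
    phantom_low = default_qrm_efp(0.0, trabecular_rho_e=rho_e_low)
    phantom_high = default_qrm_efp(0.0, trabecular_rho_e=rho_e_high)
    res = DensityOrderingResult([], [], [], [])
    for k in range(n_seeds):
        low = simulate_stack(phantom_low, scan, params, n_slices,
                             seed=_stack_seed(seed, 2 * k))
        high = simulate_stack(phantom_high, scan, params, n_slices,
                              seed=_stack_seed(seed, 2 * k + 1))
        sweep = threshold_sweep(low, high)
        i_opt = int(np.argmax(sweep.diff))
        res.optimal_thresholds.append(sweep.optimal_threshold)
        res.totals_low.append(int(sweep.counts_low[i_opt]))
        res.totals_high.append(int(sweep.counts_high[i_opt]))
        res.diffs_at_optimal.append(int(sweep.diff[i_opt]))
    return res


def _mean_slice_count(stack: list[SliceImage], threshold: float) -> float:
    counts = per_slice_counts_over_thresholds(stack, [threshold])
    return float(counts[:, 0].mean())


@dataclass
class CalibrationRecoveryResult:
    """Calibration fit and held-out inverse prediction."""

    slope: float
    intercept: float
    held_out_density: float
    estimated_density: float

    @property
    def relative_error(self) -> float:
        return abs(self.estimated_density - self.held_out_density) / self.held_out_density


def calibration_recovery_experiment(
    seed: int,
    densities: tuple[float, ...] = (0.0, 50.0, 200.0),
    held_out: float = 100.0,
    n_seeds: int = 10,
    n_slices: int = 20,
    gain: float = 400.0,
    count_threshold: float = 500.0,
    scan: ScanParams | None = None,
) -> CalibrationRecoveryResult:
    """Fit count = slope * density + intercept and recover a held-out density.

    The streak gain is large enough that counts land in the thousands per
    stack, so the round-to-integer streak count resolves the 50 mg HA
    cm^-3 spacing of the calibration densities.  The scan uses the full
    1024 x 1024 acquisition matrix: at coarser grids the streak-bearing
    annulus outside the cortical ring spans only a few pixels, overlapping
    streaks saturate it, and the count readout stops responding to
    density.  Mean per-slice counts are averaged over ``n_seeds`` stacks
    per density.

    The design is paired: every density is simulated under the same
    ``n_seeds`` scatter realizations (common random numbers), so shared
    streak-placement noise cancels between densities and the recovery
    error reflects the count->density response, not the Monte Carlo
    noise of individual stacks.
    """
    scan = scan or ScanParams(matrix_size=1024, pixel_spacing_mm=0.0625)
    params = StreakParams(gain=gain)

    def mean_count(rho_ha: float) -> float:
        phantom = default_qrm_efp(rho_ha)
        vals = []
        for k in range(n_seeds):
            st = simulate_stack(
                phantom, scan, params, n_slices, seed=_stack_seed(seed, k)
            )
            vals.append(_mean_slice_count(st, count_threshold))
        return float(np.mean(vals))

    pairs = [(rho, mean_count(rho)) for rho in densities]
    model = fit_calibration(pairs)
    held_count = mean_count(held_out)
    est = estimate_density(held_count, model)
    return CalibrationRecoveryResult(
        slope=model.slope,
        intercept=model.intercept,
        held_out_density=held_out,
        estimated_density=est.value,
    )


@dataclass
class CohortClassificationResult:
    """Midpoint-cutoff classification of two simulated cohorts."""

    counts_low: np.ndarray
    counts_high: np.ndarray
    cutoff: float
    accuracy: float
    separation_sd: float


def cohort_classification_experiment(
    seed: int,
    n_stacks: int = 10,
    n_slices: int = 40,
    gain: float = 15.0,
    rho_e_low: float = 1.0,
    rho_e_high: float = 1.2,
    scan: ScanParams | None = None,
) -> CohortClassificationResult:
    """Two cohorts of stacks classified at the midpoint count cutoff.

    The low-electron-density cohort plays the osteoporosis group, the
    high-density cohort the healthy group.  The counting threshold is the
    optimal threshold from a sweep of the first stack pair, echoing how
    the measurement threshold is chosen on a calibration scan before
    classifying.  Separation is (mean_high - mean_low) / pooled sd.
    """
    scan = scan or ScanParams()
    params = StreakParams(gain=gain)
    phantom_low = default_qrm_efp(0.0, trabecular_rho_e=rho_e_low)
    phantom_high = default_qrm_efp(0.0, trabecular_rho_e=rho_e_high)

    stacks_low = [
        simulate_stack(phantom_low, scan, params, n_slices,
                       seed=_stack_seed(seed, 2 * k))
        for k in range(n_stacks)
    ]
    stacks_high = [
        simulate_stack(phantom_high, scan, params, n_slices,
                       seed=_stack_seed(seed, 2 * k + 1))
        for k in range(n_stacks)
    ]
    sweep = threshold_sweep(stacks_low[0], stacks_high[0])
    thr = float(sweep.optimal_threshold)

    totals_low = np.array(
        [per_slice_counts_over_thresholds(st, [thr])[:, 0].sum() for st in stacks_low],
        dtype=float,
    )
    totals_high = np.array(
        [per_slice_counts_over_thresholds(st, [thr])[:, 0].sum() for st in stacks_high],
        dtype=float,
    )
    cutoff = midpoint_cutoff(totals_low.mean(), totals_high.mean())
    calls_low = [classify_bmd(c, cutoff) for c in totals_low]
    calls_high = [classify_bmd(c, cutoff) for c in totals_high]
    correct = sum(c == "low_bmd" for c in calls_low) + sum(
        c == "normal" for c in calls_high
    )
    accuracy = correct / (2 * n_stacks)
    pooled_sd = float(np.sqrt((totals_low.var(ddof=1) + totals_high.var(ddof=1)) / 2))
    separation = (totals_high.mean() - totals_low.mean()) / pooled_sd if pooled_sd else np.inf
    return CohortClassificationResult(
        counts_low=totals_low,
        counts_high=totals_high,
        cutoff=cutoff,
        accuracy=accuracy,
        separation_sd=float(separation),
    )


def sweep_monotonicity_violations(
    seed: int,
    n_slices: int = 100,
    gain: float = 10.0,
    trabecular_rho_ha: float = 50.0,
    thresholds=DEFAULT_SWEEP_THRESHOLDS,
    scan: ScanParams | None = None,
) -> int:
    """Number of (slice, threshold-step) pairs where counts increase.

    Counts per slice must be non-increasing across the ascending
    threshold ladder; the return value is 0 when the invariant holds for
    every simulated slice.  Counting runs the full segment-and-count
    chain independently at every threshold rather than the vectorized
    sweep path, so the invariant is measured, not built in.
    """
    from .pipeline import count_artifact_pixels

    scan = scan or ScanParams()
    params = StreakParams(gain=gain)
    phantom = default_qrm_efp(trabecular_rho_ha)
    stack = simulate_stack(phantom, scan, params, n_slices, seed=seed)
    counts = np.column_stack(
        [count_artifact_pixels(stack, thr) for thr in thresholds]
    )
    return int((np.diff(counts, axis=1) > 0).sum())
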