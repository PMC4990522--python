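# Methods

## Scatter model

The physics layer is the classical single-sphere Compton description:
photons scattered from the center of a sphere of radius *r* per unit
radius, `dI_s(r) = (I/A)·exp(−μ(E)·r)·ρ·θ`, and its integral over the
sphere, `I_s = exp(−μ(E)·r)·ρ·S`, with ρ the relative electron density
and *S* the average scatter intensity per electron. Both are
proportionalities: the absolute photon scale is unknowable without a
detector model, so *S* (`ScanParams.s_per_electron`) and the streak
`gain` are free parameters with arbitrary units. `I(r)`, `A(r)` and
`θ(r)` are treated as constants (uniform beam, fixed solid angle); no
functional forms are assumed. The closed-form integral
`(I/A)·θ·ρ·(1−e^(−μR))/μ` is exposed separately and checked against
numerical quadrature.

Beam quality enters only through the effective photon energy: each
material carries a scalar μ(E). When not set explicitly, μ is modeled
as `μ_water · ρ_e` with `μ_water = 0.2 cm⁻¹` (water near the ~65 keV
effective energy of a 130 kVp beam) — a Compton-dominated,
single-energy approximation. There is no polychromatic spectrum, no
beam hardening, and no projection/reconstruction step; tube voltage,
current and exposure time are metadata only.

## Phantom and image model

Phantoms are circular cross-sections of the European Forearm Phantom
type: a trabecular insert (disk) inside a cortical ring (annulus,
default wall 1.2 mm, selectable 2.5 mm, 800 mg HA cm⁻³), embedded in a
water-equivalent body disk, air outside. The multi-insert layout of the
physical phantom is approximated by one insert per simulated stack. The
body disk radius (default 20 mm) is a free geometric choice at
forearm-soft-tissue scale.

Two affine material maps, both config-overridable:

* CT number: `HU = 1.4 · ρ_HA` (HU per mg HA cm⁻³), pinning water to
  0 HU, placing the 800 mg HA cm⁻³ cortical wall at 1120 HU — above the
  900 HU periosteal threshold — and all standard inserts
  (≤ 200 mg HA cm⁻³ → ≤ 280 HU) below the 500 HU counting floor.
* electron density: `ρ_e = 1 + 5·10⁻⁴ · ρ_HA`, unless set explicitly.
  Everything density-dependent is keyed on ρ_e, so experiments can vary
  electron density directly (e.g. cohorts at ρ_e 1.0 vs 1.2) without
  committing to the HA map.

Slices are int16 HU grids clamped to [−1024, 3071]; air is −1000 HU.
Grid convention: row-major, origin top-left, pixel centers at integer
coordinates, phantom axis at the grid center plus an optional offset.

## Streak artifact generator

The streak layer encodes density in the *number* of streaks — matching
a pixel-counting readout — not in per-pixel intensity. Per slice,
`n = round(gain · I_s)` rays are drawn, with `I_s` evaluated for the
trabecular compartment (r = endosteal radius in cm). Each ray starts
just outside the periosteal surface at a uniform random angle; its peak
HU is uniform in [500, 1100] (overlapping the 500–900 counting window,
so counts respond to the threshold), its amplitude decays with length
constant 3 mm over at most 12 mm, and it is flanked by dark bands at
−150 HU relative to the body. Bright pixels compose by maximum, dark by
minimum; only pixels strictly outside the periosteal surface are
touched, so the ring and interior stay bit-identical to the base image
(artifact isolation then cannot leak interior signal). Rounding
`gain · I_s` to zero streaks is legal and yields the base image.

Randomness: one `numpy` Generator per slice, seeded `master_seed +
slice_index`. Per-streak (angle, peak) pairs are drawn interleaved, so
the first *k* streaks of an *n*-streak slice coincide with a *k*-streak
slice under the same seed — this prefix stability enables paired
designs in which different densities share scatter realizations.

## Measurement chain

* **Periosteal contour**: binarize at 900 HU (≥), keep the largest
  8-connected component, fill interior holes with 4-connected
  background flood — threshold → component → fill stands in for
  clinical auto-contouring, which is not algorithmically standardized.
  No pixel above threshold ⇒ empty mask, not an error.
* **Endosteal contour**: sub-threshold pixels inside the periosteal
  region; the remainder is the cortical wall. Wall and endosteal masks
  partition the periosteal mask exactly.
* **Artifact isolation**: pixels outside the periosteal mask with
  HU ≥ the counting threshold. Only bright streaks are counted; dark
  streaks sit below the 500 HU floor by construction.
* **Sweep**: counting thresholds 500–900 HU step 20 (21 values);
  per-stack totals per threshold; `diff = high − low` following the
  figure-caption convention (a `sign` flag flips it, as the prose
  convention is reversed); optimal threshold = argmax of `diff`, ties
  to the lowest HU (retains the most signal).
* **Summaries**: mean, population SD (ddof = 0), percentiles
  5/10/25/50/75/90/95 with linear interpolation.

Counts are non-increasing in the counting threshold for every slice
because the periosteal mask depends only on the fixed 900 HU contour
threshold; the property is nevertheless measured end-to-end, not
assumed, by re-running the full segment-and-count chain per threshold.

## Calibration and classification

`I_s` is linear in ρ at fixed geometry, so the calibration is ordinary
least squares of mean artifact count on known density; `residual_sd`
uses the n−2 denominator (0 for a two-point fit). Density for an
unknown stack is the inverse prediction `(count − intercept)/slope`
with first-order uncertainty `residual_sd/|slope|` — no full confidence
interval, and negative estimates are reported and flagged rather than
clipped. Classification compares a stack's count to a cutoff (default:
midpoint of two cohort means); fewer artifacts ⇒ `low_bmd`; the
boundary count is assigned `normal`.

## Experiment design and problem sizes

The packaged experiments (`scatterbmd.experiments`) fix the study
conditions:

* **Density ordering**: 40-slice stacks, ρ_e 1.0 vs 1.2, gain 10, ten
  independent seed pairs, full sweep; read out at the optimal
  threshold. Runs on a 256² grid at 0.25 mm spacing (64 mm field of
  view) where streak counts per slice are small and overlap is
  negligible.
* **Calibration recovery**: fit on inserts {0, 50, 200} mg HA cm⁻³,
  predict held-out 100; ten seeds × 20 slices per density, gain 400,
  counts at the 500 HU floor. This experiment uses the full 1024²
  acquisition matrix (0.0625 mm spacing): at coarser grids the
  streak-bearing annulus outside the ring is only a few pixels wide,
  the ~340 overlapping streaks saturate it, and the count stops
  responding to density. Gain 400 keeps the integer streak-count
  quantization (±0.5 streak) near 1 mg HA cm⁻³. The design is paired:
  every density is simulated under the same scatter realizations
  (common random numbers), so shared streak-placement noise cancels
  and the recovery error measures the count→density response itself
  rather than the Monte Carlo noise of individual stacks.
* **Cohort classification**: two cohorts of ten 40-slice stacks
  (ρ_e 1.0 vs 1.2, gain 15), counted at the optimal threshold from a
  sweep of the first stack pair, classified at the midpoint cutoff.
  The 40-slice stack is the per-region stack size of the phantom
  protocol; it yields ≈ 6 pooled-SD separation between cohort count
  distributions.

Stack seeds are spaced 10 000 apart so per-slice streams of different
stacks never collide.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the measurement problem —
a segmentable cortical ring, exterior bright/dark streaks whose number
scales with electron density through the scatter model, counts that
fall with the threshold — so passing tests demonstrate that the
pipeline isolates exterior artifacts exactly, orders densities
correctly, and recovers a density linearly encoded in artifact counts.
They do not validate the physics of real CBCT scatter: real streaks
arise in the projection domain and are shaped by reconstruction,
detector response, beam hardening and object-pair geometry, none of
which are modeled. Absolute counts are in arbitrary units (gain × S is
free), so calibrations do not transfer across simulator settings, let
alone scanners. Real multi-bone anatomy (radius + ulna), off-center or
non-circular sections, and motion/ring/metal artifact classes are out
of scope; the largest-component rule handles exactly one bone.

## Numerical conventions

Connectivity is fixed at 8-neighbor for foreground components and
4-neighbor for hole filling. HU thresholds are inclusive (≥). Argmax
ties break to the lowest threshold. Streak pixels are rounded to the
nearest integer HU and clamped to the int16 display window. Percentile
interpolation is linear. The μ → 0 limit of the scatter integral is
taken analytically (`prefactor · R`), not numerically.
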