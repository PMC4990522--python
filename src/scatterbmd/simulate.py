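"""Synthetic CBCT slice rendering with Compton-scatter streak artifacts.

The simulator produces what the measurement pipeline consumes: a base
attenuation image of a forearm phantom (air at -1000 HU, materials at
their CT numbers) plus a stochastic layer of bright radial streaks with
dark flanking bands outside the cortical ring -- the appearance of
scattered-photon artifacts around a dense object.

The *number* of streaks, not their per-pixel intensity, carries the
density signal.  It is tied to the single-sphere Compton scatter model:

    dI_s(r) = (I / A) * exp(-mu(E) * r) * rho_e * theta        (per radius)
    I_s     =           exp(-mu(E) * r) * rho_e * S            (total)

where mu(E) is the linear attenuation coefficient at the effective
energy, rho_e the relative electron density, and S the average scatter
intensity per electron.  Both are proportionalities; the absolute scale
is absorbed into the free streak ``gain``.  A slice draws
``round(gain * I_s)`` streaks, with I_s evaluated for the trabecular
compartment (r = interior radius in cm).

Everything stochastic is driven by a seeded ``numpy.random.Generator``;
per-slice streams are derived as ``master_seed + slice_index`` so stacks
are independent across slices yet exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .phantom import (
    PhantomSpec,
    ScanParams,
    attenuation_coefficient,
    electron_density,
    hu_from_density,
)

__all__ = [
    "HU_AIR",
    "HU_MIN",
    "HU_MAX",
    "SliceImage",
    "ScatterGeometry",
    "StreakParams",
    "scatter_intensity",
    "scatter_intensity_differential",
    "scatter_integral",
    "expected_streak_count",
    "render_base_image",
    "render_streak_artifacts",
    "simulate_stack",
]

HU_AIR = -1000
HU_MIN = -1024
HU_MAX = 3071


@dataclass(frozen=True)
class SliceImage:
    """A single HU slice: int16 grid plus geometry metadata."""

    pixels: np.ndarray
    pixel_spacing_mm: float
    slice_thickness_mm: float
    slice_index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"pixels must be a 2D grid, got ndim={px.ndim}")
        if self.pixel_spacing_mm <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("pixel spacing and slice thickness must be > 0")
        if px.min() < HU_MIN or px.max() > HU_MAX:
            raise ValueError(f"HU values must lie in [{HU_MIN}, {HU_MAX}]")
        object.__setattr__(self, "pixels", px.astype(np.int16, copy=False))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ScatterGeometry:
    """Constant-factor geometry of the single-sphere scatter model.

    ``i0`` (incident photons per unit volume), ``area`` (beam area, cm^2)
    and ``theta`` (solid angle, sr) are treated as constants: uniform
    beam, fixed detector solid angle.
    """

    i0: float = 1.0
    area: float = 1.0
    theta: float = 1.0

    def __post_init__(self) -> None:
        if self.i0 < 0:
            raise ValueError("i0 must be >= 0")
        if self.area <= 0:
            raise ValueError("beam area must be > 0")
        if not 0 < self.theta <= 4 * math.pi:
            raise ValueError("solid angle must lie in (0, 4*pi]")


@dataclass(frozen=True)
class StreakParams:
    """Appearance and abundance parameters of the streak layer.

    ``gain`` converts the (arbitrary-unit) scatter intensity I_s into a
    streak count per slice.  Bright streak peak HU values are drawn
    uniformly from ``bright_hu_range`` and decay radially with length
    constant ``decay_length_mm``; each bright core is flanked by dark
    bands offset by ``dark_hu_offset`` (negative).  The default bright
    range [500, 1100] overlaps the 500-900 HU counting window so pixel
    counts respond to the threshold sweep.
    """

    gain: float = 10.0
    bright_hu_range: tuple[float, float] = (500.0, 1100.0)
    dark_hu_offset: float = -150.0
    streak_width_px: int = 1
    decay_length_mm: float = 3.0
    max_length_mm: float = 12.0
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.bright_hu_range
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if not lo < hi:
            raise ValueError("bright_hu_range must be an increasing interval")
        if self.dark_hu_offset >= 0:
            raise ValueError("dark_hu_offset must be negative")
        if self.streak_width_px < 1:
            raise ValueError("streak_width_px must be >= 1")
        if self.decay_length_mm <= 0 or self.max_length_mm <= 0:
            raise ValueError("decay and max streak lengths must be > 0")


def scatter_intensity(mu: float, r: float, rho_e: float, s: float) -> float:
    """Total scatter intensity I_s = exp(-mu*r) * rho_e * s.

    Parameters are the linear attenuation coefficient (cm^-1), the sphere
    radius (cm), the relative electron density and the average scatter
    intensity per electron (arbitrary units).  Linear in ``rho_e`` and
    ``s``; strictly decreasing in ``mu * r``.
    """
    if mu < 0 or rho_e < 0 or s < 0:
        raise ValueError("mu, rho_e and s must be >= 0")
    if r <= 0:
        raise ValueError(f"radius must be > 0, got {r}")
    return math.exp(-mu * r) * rho_e * s


def scatter_intensity_differential(
    geom: ScatterGeometry, mu: float, rho_e: float, r: float
) -> float:
    """Scattered photons per unit radius at radius ``r`` (cm).

    dI_s(r) = (i0/area) * exp(-mu*r) * rho_e * theta.  Its definite
    integral over [0, R] is (i0/area) * theta * rho_e * (1 - e^(-mu R))/mu
    (R in the mu -> 0 limit); see :func:`scatter_integral`.
    """
    if r <= 0:
        raise ValueError(f"radius must be > 0, got {r}")
    if mu < 0 or rho_e < 0:
        raise ValueError("mu and rho_e must be >= 0")
    return (geom.i0 / geom.area) * math.exp(-mu * r) * rho_e * geom.theta


def scatter_integral(
    geom: ScatterGeometry, mu: float, rho_e: float, radius: float
) -> float:
    """Closed-form integral of the differential model over [0, radius]."""
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if mu < 0 or rho_e < 0:
        raise ValueError("mu and rho_e must be >= 0")
    prefactor = (geom.i0 / geom.area) * geom.theta * rho_e
    if mu == 0:
        return prefactor * radius
    return prefactor * (1.0 - math.exp(-mu * radius)) / mu


def expected_streak_count(
    phantom: PhantomSpec, scan: ScanParams, params: StreakParams
) -> int:
    """Streaks drawn per slice: round(gain * I_s) for the trabecular insert.

    I_s is evaluated with the insert's mu(E) and electron density and
    r = interior (endosteal) radius in cm.
    """
    i_s = scatter_intensity(
        mu=attenuation_coefficient(phantom.trabecular),
        r=phantom.interior_radius_mm / 10.0,
        rho_e=electron_density(phantom.trabecular),
        s=scan.s_per_electron,
    )
    return int(round(params.gain * i_s))


def _radius_grid(shape: tuple[int, int], spacing: float,
                 center_mm: tuple[float, float]) -> np.ndarray:
    """Distance (mm) of each pixel center from the phantom axis."""
    ny, nx = shape
    cy = (ny - 1) / 2.0 + center_mm[0] / spacing
    cx = (nx - 1) / 2.0 + center_mm[1] / spacing
    yy, xx = np.mgrid[0:ny, 0:nx]
    return np.hypot(yy - cy, xx - cx) * spacing


def render_base_image(
    phantom: PhantomSpec, scan: ScanParams, slice_index: int = 0
) -> SliceImage:
    """Deterministic attenuation image of the phantom cross-section.

    Air background at -1000 HU; body, cortical annulus and trabecular
    insert filled with their material CT numbers.

    Raises
    ------
    ValueError
        If the phantom body does not fit inside the field of view.
    """
    half_fov = scan.fov_mm / 2.0
    if phantom.body_radius_mm + max(map(abs, phantom.center_mm)) >= half_fov:
        raise ValueError(
            f"phantom (body radius {phantom.body_radius_mm} mm) does not fit "
            f"in the {scan.fov_mm:g} mm field of view"
        )
    n = scan.matrix_size
    r = _radius_grid((n, n), scan.pixel_spacing_mm, phantom.center_mm)
    img = np.full((n, n), HU_AIR, dtype=np.int16)
    img[r <= phantom.body_radius_mm] = int(round(phantom.body.hu))
    ring = (r <= phantom.outer_radius_mm) & (r > phantom.interior_radius_mm)
    img[ring] = int(round(phantom.cortical.hu))
    img[r <= phantom.interior_radius_mm] = int(round(phantom.trabecular.hu))
    return SliceImage(
        pixels=img,
        pixel_spacing_mm=scan.pixel_spacing_mm,
        slice_thickness_mm=scan.slice_thickness_mm,
        slice_index=slice_index,
    )


def _draw_streaks(
    base_pixels: np.ndarray,
    phantom: PhantomSpec,
    scan: ScanParams,
    params: StreakParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Add streaks to a copy of ``base_pixels``; return (pixels, angles).

    Streaks are radial rays starting just outside the periosteal surface;
    only strictly exterior pixels (radius > outer radius) are touched, so
    the cortical ring and everything inside it stay bit-identical.
    """
    n_streaks = expected_streak_count(phantom, scan, params)
    pixels = base_pixels.astype(np.float64)
    shape = pixels.shape
    spacing = scan.pixel_spacing_mm
    r_grid = _radius_grid(shape, spacing, phantom.center_mm)
    exterior = r_grid > phantom.outer_radius_mm

    # one (angle, peak) draw pair per streak, interleaved: the first k
    # streaks of an n-streak slice equal the streaks of a k-streak slice
    # under the same RNG state, enabling paired designs across densities
    u = rng.uniform(size=(n_streaks, 2))
    angles = 2.0 * math.pi * u[:, 0]
    lo, hi = params.bright_hu_range
    peaks = lo + (hi - lo) * u[:, 1]

    cy = (shape[0] - 1) / 2.0 + phantom.center_mm[0] / spacing
    cx = (shape[1] - 1) / 2.0 + phantom.center_mm[1] / spacing
    # radial sample points, one per pixel step
    d_mm = np.arange(0.0, params.max_length_mm, spacing)
    start_mm = phantom.outer_radius_mm + spacing
    decay = np.exp(-d_mm / params.decay_length_mm)
    body_hu = float(round(phantom.body.hu))
    dark_value = np.maximum(body_hu + params.dark_hu_offset * decay, HU_MIN)

    half_w = (params.streak_width_px - 1) // 2
    bright_offsets = range(-half_w, params.streak_width_px - half_w)
    dark_offsets = (-(half_w + 1), params.streak_width_px - half_w)

    for angle, peak in zip(angles, peaks):
        ca, sa = math.cos(angle), math.sin(angle)
        radii_px = (start_mm + d_mm) / spacing
        ys = cy + radii_px * sa
        xs = cx + radii_px * ca
        # perpendicular unit vector for width/flank offsets
        py, px_ = ca, -sa
        bright = peak * decay
        for off in bright_offsets:
            iy = np.rint(ys + off * py).astype(np.intp)
            ix = np.rint(xs + off * px_).astype(np.intp)
            ok = (iy >= 0) & (iy < shape[0]) & (ix >= 0) & (ix < shape[1])
            iy, ix = iy[ok], ix[ok]
            keep = exterior[iy, ix]
            iy, ix = iy[keep], ix[keep]
            np.maximum.at(pixels, (iy, ix), bright[ok][keep])
        for off in dark_offsets:
            iy = np.rint(ys + off * py).astype(np.intp)
            ix = np.rint(xs + off * px_).astype(np.intp)
            ok = (iy >= 0) & (iy < shape[0]) & (ix >= 0) & (ix < shape[1])
            iy, ix = iy[ok], ix[ok]
            keep = exterior[iy, ix]
            iy, ix = iy[keep], ix[keep]
            np.minimum.at(pixels, (iy, ix), dark_value[ok][keep])

    out = np.clip(np.rint(pixels), HU_MIN, HU_MAX).astype(np.int16)
    return out, angles


def render_streak_artifacts(
    base: SliceImage,
    phantom: PhantomSpec,
    scan: ScanParams,
    params: StreakParams,
    rng: np.random.Generator | None = None,
) -> SliceImage:
    """Overlay scatter streak artifacts on a base slice.

    Draws ``round(gain * I_s)`` radial streaks outward from the cortical
    ring; a count rounding to zero yields the base image unchanged.
    Reproducible: a fixed ``rng`` state (or ``params.seed``) gives
    identical output.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    pixels, _ = _draw_streaks(base.pixels, phantom, scan, params, rng)
    return replace(base, pixels=pixels)


def simulate_stack(
    phantom: PhantomSpec,
    scan: ScanParams,
    params: StreakParams,
    n_slices: int,
    seed: int,
) -> list[SliceImage]:
    """Simulate an ordered stack of artifact-bearing slices.

    The base image is shared across slices (rigid phantom); the streak
    layer of slice ``i`` uses an RNG seeded with ``seed + i``, so stacks
    are reproducible per master seed and slices mutually independent.
    """
    if n_slices < 1:
        raise ValueError(f"n_slices must be >= 1, got {n_slices}")
    base = render_base_image(phantom, scan)
    stack: list[SliceImage] = []
    for i in range(n_slices):
        rng = np.random.default_rng(seed + i)
        sl = render_streak_artifacts(base, phantom, scan, params, rng=rng)
        stack.append(replace(sl, slice_index=i))
    return stack
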