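"""Materials and geometry of synthetic forearm phantoms.

The phantoms emulate the European Forearm Phantom (QRM-EFP): a resin,
water-equivalent body enclosing a cortical ring of dense bone-equivalent
material (800 mg hydroxyapatite per cm^3, wall thickness 1.2 or 2.5 mm)
around a trabecular insert of graded hydroxyapatite (HA) content
(typically 0, 50, 100 or 200 mg HA cm^-3).

Two simple material models tie HA content to image and physics quantities:

* ``hu_from_density`` -- an affine CT-number map, HU = a * rho_ha with
  water pinned to 0 HU.  The default slope a = 1.4 HU/(mg HA cm^-3)
  places cortical bone (800 mg HA cm^-3 -> 1120 HU) above the 900 HU
  periosteal segmentation threshold and all standard trabecular inserts
  well below the 500-900 HU counting window.
* ``electron_density`` -- relative electron density (water = 1), either
  set explicitly on the material or derived as 1 + c * rho_ha with
  c = 5e-4 per (mg HA cm^-3).  Compton scatter yield is proportional to
  this quantity.

Both slopes are configurable; the defaults are module constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "DEFAULT_HU_SLOPE",
    "DEFAULT_ELECTRON_DENSITY_SLOPE",
    "DEFAULT_MU_WATER",
    "PERIOSTEAL_THRESHOLD_HU",
    "MaterialSpec",
    "PhantomSpec",
    "ScanParams",
    "hu_from_density",
    "electron_density",
    "attenuation_coefficient",
    "default_qrm_efp",
    "WATER",
    "CORTICAL_BONE",
]

#: HU per (mg HA cm^-3); water (rho_ha = 0) maps to 0 HU by construction.
DEFAULT_HU_SLOPE = 1.4

#: Relative-electron-density increment per (mg HA cm^-3).
DEFAULT_ELECTRON_DENSITY_SLOPE = 5e-4

#: Linear attenuation coefficient of water at the effective beam energy
#: (~65 keV for a 130 kVp spectrum), cm^-1.  Materials without an explicit
#: mu scale this by their relative electron density (Compton-dominated
#: approximation).
DEFAULT_MU_WATER = 0.2

#: Default HU threshold for the periosteal (outer cortical) contour.
PERIOSTEAL_THRESHOLD_HU = 900.0


def hu_from_density(rho_ha: float, slope: float = DEFAULT_HU_SLOPE) -> float:
    """Map hydroxyapatite content (mg HA cm^-3) to a CT number in HU.

    Affine with water fixed at 0 HU: HU = slope * rho_ha.  Strictly
    increasing for positive ``slope``.

    Raises
    ------
    ValueError
        If ``rho_ha`` is negative.
    """
    if rho_ha < 0:
        raise ValueError(f"hydroxyapatite density must be >= 0, got {rho_ha}")
    return slope * rho_ha


@dataclass(frozen=True)
class MaterialSpec:
    """A phantom material.

    Parameters
    ----------
    name:
        Label used in configs and reports.
    rho_ha:
        Hydroxyapatite content, mg HA cm^-3 (>= 0).
    rho_e:
        Relative electron density (water = 1).  When ``None`` it is derived
        from ``rho_ha`` by :func:`electron_density`.
    mu:
        Linear attenuation coefficient at the effective energy, cm^-1.
        When ``None`` it is derived by :func:`attenuation_coefficient`.
    """

    name: str
    rho_ha: float = 0.0
    rho_e: float | None = None
    mu: float | None = None

    def __post_init__(self) -> None:
        if self.rho_ha < 0:
            raise ValueError(f"rho_ha must be >= 0, got {self.rho_ha}")
        if self.rho_e is not None and self.rho_e <= 0:
            raise ValueError(f"rho_e must be > 0, got {self.rho_e}")
        if self.mu is not None and self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")

    @property
    def hu(self) -> float:
        """CT number of the material under the default affine map."""
        return hu_from_density(self.rho_ha)


def electron_density(
    material: MaterialSpec,
    slope: float = DEFAULT_ELECTRON_DENSITY_SLOPE,
) -> float:
    """Relative electron density of a material (water = 1).

    An explicitly set ``rho_e`` always wins; otherwise the default linear
    model ``1 + slope * rho_ha`` is used, which is monotone non-decreasing
    in HA content.
    """
    if material.rho_e is not None:
        return material.rho_e
    return 1.0 + slope * material.rho_ha


def attenuation_coefficient(
    material: MaterialSpec,
    mu_water: float = DEFAULT_MU_WATER,
) -> float:
    """Linear attenuation coefficient mu(E) of a material, cm^-1.

    An explicit ``mu`` wins; otherwise mu scales with relative electron
    density (Compton-dominated single-energy approximation),
    ``mu = mu_water * rho_e``.
    """
    if material.mu is not None:
        return material.mu
    return mu_water * electron_density(material)


WATER = MaterialSpec(name="water", rho_ha=0.0)
CORTICAL_BONE = MaterialSpec(name="cortical_bone", rho_ha=800.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Circular cross-section forearm phantom.

    Geometry is a concentric layout: trabecular insert (disk of radius
    ``outer_radius_mm - cortical_wall_mm``) inside the cortical ring
    (annulus of the stated wall thickness), embedded in a water-equivalent
    body disk of radius ``body_radius_mm``; air outside.  ``center_mm`` is
    the offset of the phantom axis from the grid center.
    """

    outer_radius_mm: float = 10.0
    cortical_wall_mm: float = 1.2
    cortical: MaterialSpec = CORTICAL_BONE
    trabecular: MaterialSpec = WATER
    body: MaterialSpec = WATER
    body_radius_mm: float = 20.0
    center_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not 0 < self.cortical_wall_mm < self.outer_radius_mm:
            raise ValueError(
                "cortical wall thickness must satisfy "
                f"0 < {self.cortical_wall_mm} < outer radius {self.outer_radius_mm}"
            )
        if self.body_radius_mm < self.outer_radius_mm:
            raise ValueError("body radius must be >= outer (periosteal) radius")

    @property
    def interior_radius_mm(self) -> float:
        """Radius of the trabecular compartment (endosteal surface)."""
        return self.outer_radius_mm - self.cortical_wall_mm

    def validate_contrast(self, contour_hu: float = PERIOSTEAL_THRESHOLD_HU) -> None:
        """Check that the periosteal threshold separates wall from insert/body.

        Raises ``ValueError`` when the cortical wall does not clear the
        contour threshold or the trabecular/body materials do.
        """
        if self.cortical.hu <= contour_hu:
            raise ValueError(
                f"cortical HU {self.cortical.hu:.0f} does not exceed the "
                f"contour threshold {contour_hu:.0f}"
            )
        for m in (self.trabecular, self.body):
            if m.hu >= contour_hu:
                raise ValueError(
                    f"material {m.name!r} HU {m.hu:.0f} reaches the contour "
                    f"threshold {contour_hu:.0f}; segmentation would merge it "
                    "with the cortical wall"
                )


@dataclass(frozen=True)
class ScanParams:
    """Acquisition parameters of a (simulated) peripheral CBCT scan.

    ``kvp``/``ma``/``exposure_ms`` are carried as metadata; the physics of
    the simulator sees only the effective photon energy through each
    material's mu(E) and the per-electron scatter intensity
    ``s_per_electron`` (the proportionality constant S of the scatter
    model, arbitrary units).
    """

    kvp: float = 130.0
    ma: float = 10.0
    exposure_ms: float = 20.0
    energy_kev: float = 65.0
    matrix_size: int = 256
    pixel_spacing_mm: float = 0.25
    slice_thickness_mm: float = 0.2162
    s_per_electron: float = 1.0

    def __post_init__(self) -> None:
        if self.matrix_size < 16:
            raise ValueError(f"matrix_size must be >= 16, got {self.matrix_size}")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be > 0")
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice_thickness_mm must be > 0")
        if self.s_per_electron <= 0:
            raise ValueError("s_per_electron must be > 0")

    @property
    def fov_mm(self) -> float:
        return self.matrix_size * self.pixel_spacing_mm


def default_qrm_efp(
    trabecular_rho_ha: float,
    wall_mm: float = 1.2,
    trabecular_rho_e: float | None = None,
) -> PhantomSpec:
    """Build a QRM-EFP-like phantom with the given trabecular insert.

    Parameters
    ----------
    trabecular_rho_ha:
        Insert HA content in mg HA cm^-3, within [0, 800] (0 = water
        insert; the cortical wall itself is 800).
    wall_mm:
        Cortical wall thickness; the physical phantom offers 1.2 and
        2.5 mm sections.
    trabecular_rho_e:
        Optional explicit relative electron density of the insert,
        overriding the default HA-derived model.  Useful because scatter
        abundance is keyed on electron density, not HA content.
    """
    if not 0 <= trabecular_rho_ha <= 800:
        raise ValueError(
            f"trabecular density must lie in [0, 800] mg HA cm^-3, "
            f"got {trabecular_rho_ha}"
        )
    insert = MaterialSpec(
        name=f"trabecular_{trabecular_rho_ha:g}",
        rho_ha=trabecular_rho_ha,
        rho_e=trabecular_rho_e,
    )
    return PhantomSpec(cortical_wall_mm=wall_mm, trabecular=insert)


def with_trabecular(phantom: PhantomSpec, material: MaterialSpec) -> PhantomSpec:
    """Return a copy of ``phantom`` with a different trabecular insert."""
    return replace(phantom, trabecular=material)
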