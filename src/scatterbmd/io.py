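"""Reading and writing HU slice stacks, plus run configuration.

Two on-disk layouts are supported:

* a NIfTI volume (``.nii`` / ``.nii.gz``), int16 HU, with in-plane pixel
  spacing and slice thickness in the header zooms;
* a directory of numbered 16-bit TIFF or PNG slices
  (``slice_0000.tif`` ...) with a ``stack.yaml`` sidecar carrying the
  spacing metadata.

Round trips are lossless for integer HU data.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import yaml

from .phantom import PERIOSTEAL_THRESHOLD_HU
from .simulate import SliceImage

__all__ = [
    "StackReadError",
    "InconsistentShapeError",
    "MissingMetadataError",
    "RunConfig",
    "read_stack",
    "write_stack",
    "parse_threshold_spec",
]

_SIDECAR = "stack.yaml"
_SLICE_RE = re.compile(r"slice_(\d+)\.(tif|tiff|png)$")


class StackReadError(RuntimeError):
    """The stack path is missing, unreadable or not a recognized layout."""


class InconsistentShapeError(StackReadError):
    """Slices in a directory stack do not share one shape."""


class MissingMetadataError(StackReadError):
    """Pixel spacing / slice thickness could not be determined."""


@dataclass
class RunConfig:
    """Configuration of a pipeline run, loadable from flat YAML.

    ``thresholds`` is a ``start:stop:step`` spec in HU (inclusive stop);
    the master ``seed`` is recorded in every output manifest.
    """

    output_dir: str = "."
    inputs: list[str] = field(default_factory=list)
    thresholds: str = "500:900:20"
    contour_hu: float = PERIOSTEAL_THRESHOLD_HU
    seed: int = 0
    n_slices: int = 40
    trabecular_rho_ha: float = 50.0
    gain: float = 10.0
    verbosity: str = "info"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    def threshold_list(self) -> list[int]:
        return parse_threshold_spec(self.thresholds)


def parse_threshold_spec(spec: str) -> list[int]:
    """Expand ``"start:stop:step"`` into an inclusive ascending HU list."""
    try:
        start, stop, step = (int(x) for x in spec.split(":"))
    except ValueError as exc:
        raise ValueError(f"bad threshold spec {spec!r}; want start:stop:step") from exc
    if step <= 0 or stop < start:
        raise ValueError(f"threshold spec {spec!r} must be ascending with step > 0")
    return list(range(start, stop + 1, step))


def _to_volume(stack: Sequence[SliceImage]) -> np.ndarray:
    shapes = {sl.shape for sl in stack}
    if len(shapes) != 1:
        raise InconsistentShapeError(f"slices differ in shape: {shapes}")
    return np.stack([sl.pixels for sl in stack]).astype(np.int16)


def write_stack(
    stack: Sequence[SliceImage], path: str | Path, format: str = "nifti"
) -> Path:
    """Persist a stack as a NIfTI volume or numbered TIFF/PNG slices.

    ``format`` is ``"nifti"``, ``"tiff"`` or ``"png"``; directory formats
    get a ``stack.yaml`` sidecar with spacing metadata.  Deterministic
    output for fixed input.
    """
    if len(stack) == 0:
        raise ValueError("cannot write an empty stack")
    path = Path(path)
    vol = _to_volume(stack)
    spacing = stack[0].pixel_spacing_mm
    thickness = stack[0].slice_thickness_mm
    if format == "nifti":
        # axes: (slice, row, col) -> NIfTI (x, y, z) = (col, row, slice)
        affine = np.diag([spacing, spacing, thickness, 1.0])
        img = nib.Nifti1Image(vol.transpose(2, 1, 0), affine)
        img.header.set_zooms((spacing, spacing, thickness))
        nib.save(img, str(path))
        return path
    if format in ("tiff", "png"):
        import imageio.v3 as iio
        import tifffile

        path.mkdir(parents=True, exist_ok=True)
        ext = "tif" if format == "tiff" else "png"
        for i, sl in enumerate(stack):
            fname = path / f"slice_{i:04d}.{ext}"
            if format == "tiff":
                tifffile.imwrite(fname, sl.pixels.astype(np.int16))
            else:
                # PNG is unsigned 16-bit; shift by 1024 so air (-1000) fits
                iio.imwrite(fname, (sl.pixels.astype(np.int32) + 1024).astype(np.uint16))
        sidecar = {
            "pixel_spacing_mm": float(spacing),
            "slice_thickness_mm": float(thickness),
            "n_slices": len(stack),
            "format": format,
            "hu_offset": 1024 if format == "png" else 0,
        }
        (path / _SIDECAR).write_text(yaml.safe_dump(sidecar, sort_keys=False))
        return path
    raise ValueError(f"unknown format {format!r}; use nifti, tiff or png")


def read_stack(path: str | Path) -> list[SliceImage]:
    """Load a stack written by :func:`write_stack`.

    Accepts a NIfTI file or a directory of numbered TIFF/PNG slices with
    sidecar metadata; slices come back ordered with indices 0..n-1.

    Raises
    ------
    StackReadError / InconsistentShapeError / MissingMetadataError
        For unreadable paths, mixed slice shapes, or absent spacing
        metadata respectively.
    """
    path = Path(path)
    if path.is_file():
        return _read_nifti(path)
    if path.is_dir():
        return _read_slice_dir(path)
    raise StackReadError(f"no such stack: {path}")


def _read_nifti(path: Path) -> list[SliceImage]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise StackReadError(f"cannot read NIfTI {path}: {exc}") from exc
    zooms = img.header.get_zooms()
    if len(zooms) < 3 or zooms[0] <= 0 or zooms[2] <= 0:
        raise MissingMetadataError(f"NIfTI {path} lacks usable voxel spacing")
    vol = np.asanyarray(img.dataobj).astype(np.int16)
    vol = vol.transpose(2, 1, 0)  # back to (slice, row, col)
    return [
        SliceImage(
            pixels=vol[i],
            pixel_spacing_mm=float(zooms[0]),
            slice_thickness_mm=float(zooms[2]),
            slice_index=i,
        )
        for i in range(vol.shape[0])
    ]


def _read_slice_dir(path: Path) -> list[SliceImage]:
    sidecar = path / _SIDECAR
    if not sidecar.exists():
        raise MissingMetadataError(f"directory stack {path} lacks {_SIDECAR}")
    meta = yaml.safe_load(sidecar.read_text())
    try:
        spacing = float(meta["pixel_spacing_mm"])
        thickness = float(meta["slice_thickness_mm"])
    except (KeyError, TypeError) as exc:
        raise MissingMetadataError(f"{sidecar} is missing spacing keys") from exc
    offset = int(meta.get("hu_offset", 0))

    files = sorted(
        (p for p in path.iterdir() if _SLICE_RE.search(p.name)),
        key=lambda p: int(_SLICE_RE.search(p.name).group(1)),
    )
    if not files:
        raise StackReadError(f"no numbered slice files in {path}")
    import imageio.v3 as iio

    slices = []
    shape = None
    for i, f in enumerate(files):
        arr = np.asarray(iio.imread(f)).astype(np.int32) - offset
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise InconsistentShapeError(
                f"slice {f.name} has shape {arr.shape}, expected {shape}"
            )
        slices.append(
            SliceImage(
                pixels=arr.astype(np.int16),
                pixel_spacing_mm=spacing,
                slice_thickness_mm=thickness,
                slice_index=i,
            )
        )
    return slices
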