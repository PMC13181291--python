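"""NIfTI readers/writers and field-of-view cropping.

Volumes are exchanged as NIfTI-1 with a diagonal (axis-aligned) affine;
oblique orientations are rejected.  On disk, HU volumes are int16, masks
uint8 and dose float32; in memory the array axis order is (z, y, x) while
NIfTI stores (x, y, z), so arrays are transposed on the way through.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .core import DoseGrid, Grid, ImageVolume, StructureSet


def _affine(spacing_zyx, origin_zyx) -> np.ndarray:
    sx, sy, sz = spacing_zyx[::-1]
    ox, oy, oz = origin_zyx[::-1]
    aff = np.diag([sx, sy, sz, 1.0])
    aff[:3, 3] = (ox, oy, oz)
    return aff


def _parse_affine(aff: np.ndarray):
    rot = aff[:3, :3]
    if np.abs(rot - np.diag(np.diag(rot))).max() > 1e-6:
        raise ValueError("oblique/rotated NIfTI orientations are unsupported")
    diag = np.diag(rot)
    if np.any(diag <= 0):
        raise ValueError("flipped NIfTI orientations are unsupported")
    spacing = tuple(float(s) for s in diag[::-1])   # (z, y, x)
    origin = tuple(float(o) for o in aff[:3, 3][::-1])
    return spacing, origin


def write_volume(vol: ImageVolume, path) -> None:
    """Write an HU volume as int16 NIfTI (values rounded to whole HU)."""
    data = np.round(vol.voxels).astype(np.int16).T
    nib.save(nib.Nifti1Image(data, _affine(vol.spacing, vol.origin)), str(path))


def read_volume(path) -> ImageVolume:
    img = nib.load(str(path))
    spacing, origin = _parse_affine(img.affine)
    return ImageVolume(np.asarray(img.dataobj).astype(np.float64).T, spacing, origin)


def write_mask(mask: np.ndarray, grid: Grid, path) -> None:
    data = np.asarray(mask, dtype=np.uint8).T
    nib.save(nib.Nifti1Image(data, _affine(grid.spacing, grid.origin)), str(path))


def read_mask(path) -> tuple[np.ndarray, Grid]:
    img = nib.load(str(path))
    spacing, origin = _parse_affine(img.affine)
    data = np.asarray(img.dataobj).T
    return data.astype(bool), Grid(data.shape, spacing, origin)


def write_dose(dose: DoseGrid, path) -> None:
    data = dose.dose.astype(np.float32).T
    nib.save(nib.Nifti1Image(data, _affine(dose.spacing, dose.origin)), str(path))


def read_dose(path) -> DoseGrid:
    img = nib.load(str(path))
    spacing, origin = _parse_affine(img.affine)
    return DoseGrid(np.asarray(img.dataobj).astype(np.float64).T, spacing, origin)


@dataclass(frozen=True)
class FOVSpec:
    """Axis-aligned field-of-view box.

    Either voxel ``index_ranges`` (half-open, (z, y, x) order) or a
    physical box given by ``center_mm`` and ``extent_mm``.
    """

    index_ranges: tuple[tuple[int, int], ...] | None = None
    center_mm: tuple[float, float, float] | None = None
    extent_mm: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.index_ranges is None and (self.center_mm is None
                                          or self.extent_mm is None):
            raise ValueError("FOV needs index ranges or a physical box")
        if self.extent_mm is not None and any(e <= 0 for e in self.extent_mm):
            raise ValueError("FOV extents must be positive")

    def slices(self, grid: Grid) -> tuple[slice, slice, slice]:
        """Voxel slices of the FOV intersected with the grid."""
        if self.index_ranges is not None:
            rng = self.index_ranges
        else:
            rng = []
            for a in range(3):
                lo_mm = self.center_mm[a] - self.extent_mm[a] / 2.0
                hi_mm = self.center_mm[a] + self.extent_mm[a] / 2.0
                lo = int(np.ceil((lo_mm - grid.origin[a]) / grid.spacing[a] - 1e-9))
                hi = int(np.floor((hi_mm - grid.origin[a]) / grid.spacing[a] + 1e-9)) + 1
                rng.append((lo, hi))
        out = []
        for a, (lo, hi) in enumerate(rng):
            lo, hi = max(0, lo), min(grid.shape[a], hi)
            if lo >= hi:
                raise ValueError("FOV does not intersect the grid")
            out.append(slice(lo, hi))
        return tuple(out)


def _cropped_origin(grid: Grid, sl) -> tuple[float, float, float]:
    return tuple(grid.origin[a] + sl[a].start * grid.spacing[a] for a in range(3))


def crop_to_fov(obj, fov: FOVSpec):
    """Crop an :class:`ImageVolume` or :class:`DoseGrid` to the FOV box."""
    if isinstance(obj, ImageVolume):
        sl = fov.slices(obj.grid)
        return ImageVolume(obj.voxels[sl], obj.spacing, _cropped_origin(obj.grid, sl))
    if isinstance(obj, DoseGrid):
        sl = fov.slices(obj.grid)
        return DoseGrid(obj.dose[sl], obj.spacing, _cropped_origin(obj.grid, sl))
    raise TypeError(f"cannot crop object of type {type(obj).__name__}")


def crop_mask(mask: np.ndarray, grid: Grid, fov: FOVSpec) -> tuple[np.ndarray, Grid]:
    """Crop a mask; an originally nonempty structure falling entirely
    outside the FOV raises rather than returning a silent empty mask."""
    sl = fov.slices(grid)
    out = np.asarray(mask, dtype=bool)[sl]
    if np.asarray(mask).any() and not out.any():
        raise ValueError("structure lies entirely outside the FOV")
    new_grid = Grid(out.shape, grid.spacing, _cropped_origin(grid, sl))
    return out, new_grid


def crop_structures(structures: StructureSet, fov: FOVSpec) -> StructureSet:
    sl = fov.slices(structures.grid)
    new_grid = None
    masks = {}
    for name in structures.names():
        masks[name], new_grid = crop_mask(structures[name], structures.grid, fov)
    return StructureSet(new_grid, masks)
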