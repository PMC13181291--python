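"""Core in-memory containers shared by every stage of the pipeline.

All volumes live on axis-aligned regular grids.  Array axes are ordered
``(z, y, x)``; ``spacing`` and ``origin`` follow the same order and are in
millimetres.  Physical coordinates of voxel centres are
``origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HU_MIN = -1024.0
HU_MAX = 3071.0


def _as_triple(v) -> tuple[float, float, float]:
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected a length-3 sequence, got {v!r}")
    return t


@dataclass(frozen=True)
class Grid:
    """Geometry descriptor: shape (z, y, x), spacing and origin in mm."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", _as_triple(self.spacing))
        object.__setattr__(self, "origin", _as_triple(self.origin))
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"invalid grid shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size of the grid (voxel-centre span plus one voxel)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis 1D arrays of voxel-centre coordinates in mm."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        )

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class ImageVolume:
    """A 3D scalar image in Hounsfield units.

    The common currency of the pipeline: planning CT, CBCT and synthetic CT
    are all ``ImageVolume`` instances.  HU values must be finite and within
    the representable CT range [-1024, 3071].
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU volume contains non-finite values")
        lo, hi = self.voxels.min(), self.voxels.max()
        if lo < HU_MIN or hi > HU_MAX:
            raise ValueError(
                f"HU values outside [{HU_MIN:g}, {HU_MAX:g}]: range [{lo:g}, {hi:g}]"
            )

    @property
    def grid(self) -> Grid:
        return Grid(self.voxels.shape, self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def with_voxels(self, voxels: np.ndarray) -> "ImageVolume":
        """New volume on the same grid with different voxel data."""
        return ImageVolume(voxels, self.spacing, self.origin)


@dataclass
class DoseGrid:
    """A 3D absorbed-dose distribution in Gy on a regular grid."""

    dose: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=np.float64)
        if self.dose.ndim != 3:
            raise ValueError("dose must be a 3D array")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.dose)):
            raise ValueError("dose grid contains non-finite values")
        if self.dose.min() < 0:
            raise ValueError("dose must be nonnegative")

    @property
    def grid(self) -> Grid:
        return Grid(self.dose.shape, self.spacing, self.origin)


@dataclass
class StructureSet:
    """Named binary masks on a shared reference grid.

    Masks are stored as boolean arrays with exactly the reference grid's
    shape.  Used both for reference (physician) contours and for
    auto/perturbed contours under evaluation.
    """

    grid: Grid
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for name in list(self.masks):
            self.masks[name] = self._validate(name, self.masks[name])

    def _validate(self, name: str, mask: np.ndarray) -> np.ndarray:
        mask = np.asarray(mask)
        if mask.dtype != bool:
            vals = np.unique(mask)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(f"mask {name!r} is not binary")
            mask = mask.astype(bool)
        if mask.shape != self.grid.shape:
            raise ValueError(
                f"mask {name!r} shape {mask.shape} != grid shape {self.grid.shape}"
            )
        return mask

    def add(self, name: str, mask: np.ndarray) -> None:
        self.masks[name] = self._validate(name, mask)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> list[str]:
        return list(self.masks)
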