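"""CT-number fidelity analysis.

Per-structure mean HU and reference-minus-test differences, line
profiles through the volume with Spearman rank correlation against a
reference profile, and the piecewise-linear HU → relative electron
density conversion used by the dose model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import map_coordinates

from .core import ImageVolume, StructureSet


@dataclass(frozen=True)
class LineProfile:
    """HU samples along a straight segment.

    ``positions_mm`` run from 0 at ``p0`` to the segment length at ``p1``.
    """

    positions_mm: np.ndarray
    values: np.ndarray
    p0_mm: tuple[float, float, float]
    p1_mm: tuple[float, float, float]

    def __post_init__(self):
        if len(self.positions_mm) != len(self.values):
            raise ValueError("positions and values differ in length")
        if np.any(np.diff(self.positions_mm) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass(frozen=True)
class REDCurve:
    """HU → relative electron density conversion curve.

    Knots must have strictly increasing HU and nondecreasing rED; queries
    are piecewise-linearly interpolated and clamped to the end knots.
    The default is a 3-knot water-anchored curve: air (-1000 HU) → 0,
    water (0 HU) → 1, dense bone (2000 HU) → 2.2.
    """

    hu: tuple[float, ...] = (-1000.0, 0.0, 2000.0)
    red: tuple[float, ...] = (0.0, 1.0, 2.2)

    def __post_init__(self):
        if len(self.hu) != len(self.red):
            raise ValueError("knot arrays differ in length")
        if len(self.hu) < 2:
            raise ValueError("conversion curve needs at least 2 knots")
        if np.any(np.diff(self.hu) <= 0):
            raise ValueError("HU knots must be strictly increasing")
        if np.any(np.diff(self.red) < 0):
            raise ValueError("rED knots must be nondecreasing")
        if min(self.red) < 0:
            raise ValueError("rED must be nonnegative")


def hu_to_red(hu, curve: REDCurve = REDCurve()):
    """Convert HU to relative electron density (clamped linear interpolation)."""
    out = np.interp(np.asarray(hu, dtype=np.float64), curve.hu, curve.red)
    return out if np.ndim(hu) else float(out)


def mean_hu(vol: ImageVolume, mask: np.ndarray) -> float:
    """Arithmetic mean HU over the mask voxels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.shape:
        raise ValueError("mask is not on the volume's grid")
    if not mask.any():
        raise ValueError("mean HU over an empty mask is undefined")
    return float(vol.voxels[mask].mean())


def hu_difference(ref: ImageVolume, test: ImageVolume,
                  structures: StructureSet) -> pd.DataFrame:
    """Per-structure mean-HU comparison table.

    Columns: structure, mean_hu_ref, mean_hu_test, diff_hu (ref − test,
    matching the reference-minus-test sign convention used for dose),
    abs_diff_hu.
    """
    if ref.shape != test.shape:
        raise ValueError("reference and test volumes are on different grids")
    rows = []
    for name in structures.names():
        m_ref = mean_hu(ref, structures[name])
        m_test = mean_hu(test, structures[name])
        rows.append({
            "structure": name,
            "mean_hu_ref": m_ref,
            "mean_hu_test": m_test,
            "diff_hu": m_ref - m_test,
            "abs_diff_hu": abs(m_ref - m_test),
        })
    return pd.DataFrame(rows)


def line_profile(vol: ImageVolume, p0_mm, p1_mm, n: int = 100) -> LineProfile:
    """Sample HU along the segment p0→p1 with trilinear interpolation.

    ``n`` equidistant samples including both endpoints.  The whole segment
    must lie inside the volume's physical extent (voxel-centre hull).
    """
    if n < 2:
        raise ValueError("a profile needs at least 2 samples")
    p0 = np.asarray(p0_mm, dtype=np.float64)
    p1 = np.asarray(p1_mm, dtype=np.float64)
    origin = np.asarray(vol.origin)
    spacing = np.asarray(vol.spacing)
    hi = origin + (np.asarray(vol.shape) - 1) * spacing
    for p in (p0, p1):
        if np.any(p < origin - 1e-9) or np.any(p > hi + 1e-9):
            raise ValueError(f"profile endpoint {tuple(p)} exits the volume")
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = p0[None, :] + t * (p1 - p0)[None, :]
    idx = (pts - origin) / spacing
    vals = map_coordinates(vol.voxels, idx.T, order=1, mode="nearest")
    length = float(np.linalg.norm(p1 - p0))
    return LineProfile(t[:, 0] * length, vals, tuple(p0), tuple(p1))


def spearman(a, b) -> float:
    """Spearman rank correlation (ties get average ranks)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1D sequences of equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Spearman correlation undefined for a constant sequence")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)
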