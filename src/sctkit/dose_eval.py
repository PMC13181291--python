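"""Dose comparison: cumulative DVH, Dx% statistics and 3D global gamma.

The gamma index combines a dose-difference criterion (a percentage of the
reference maximum — "global" normalisation) with a distance-to-agreement
(DTA) criterion.  For each reference voxel above the low-dose threshold,

    gamma(r0) = min over r of sqrt( ((D_test(r) - D_ref(r0)) / dD)^2
                                    + (|r - r0| / dta)^2 )

and a voxel passes when gamma <= 1.  The minimisation is a dense search
over spatial offsets on a sub-voxel step with trilinear interpolation of
the test dose, organised in shells of increasing radius so voxels whose
current gamma can no longer improve drop out early.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .core import DoseGrid

# Numerical tolerance on the pass test gamma <= 1, so exact-boundary cases
# (dose off by exactly the criterion) do not fail on float rounding.
_PASS_TOL = 1e-9


@dataclass(frozen=True)
class GammaCriteria:
    """(dose %, DTA mm) acceptance criterion with low-dose threshold.

    ``dose_percent`` is global: the dose tolerance is that percentage of
    the reference maximum.  Voxels whose reference dose falls below
    ``low_dose_threshold_percent`` of the reference maximum are excluded
    from evaluation.  ``search_radius_factor`` bounds the DTA search (in
    units of dta) and ``step_fraction`` sets the search step as a fraction
    of dta.
    """

    dose_percent: float
    dta_mm: float
    low_dose_threshold_percent: float = 10.0
    search_radius_factor: float = 2.0
    step_fraction: float = 0.1

    def __post_init__(self):
        for name in ("dose_percent", "dta_mm", "low_dose_threshold_percent",
                     "search_radius_factor", "step_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.step_fraction > 1:
            raise ValueError("step_fraction must be <= 1")

    @property
    def label(self) -> str:
        return f"{self.dose_percent:g}%/{self.dta_mm:g}mm"


@dataclass
class GammaResult:
    """Per-voxel gamma map (NaN outside the evaluated mask) and pass rate."""

    gamma: np.ndarray
    evaluated: np.ndarray
    pass_rate_percent: float

    @property
    def n_evaluated(self) -> int:
        return int(self.evaluated.sum())


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative DVH: volume_percent[i] of the mask receives >= dose_gy[i]."""

    dose_gy: np.ndarray
    volume_percent: np.ndarray


@dataclass(frozen=True)
class DVHStats:
    """Dx% and max-point-dose comparison between a reference and a test dose.

    Differences follow the reference-minus-test convention; relative
    differences are percentages of the reference value.
    """

    d2_ref: float
    d50_ref: float
    d98_ref: float
    d2_test: float
    d50_test: float
    d98_test: float
    d2_diff: float
    d50_diff: float
    d98_diff: float
    d2_diff_percent: float
    d50_diff_percent: float
    d98_diff_percent: float
    max_ref: float
    max_test: float
    max_diff: float
    max_diff_percent: float


def _mask_doses(dose: DoseGrid, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.dose.shape:
        raise ValueError("mask is not on the dose grid")
    if not mask.any():
        raise ValueError("empty mask")
    return dose.dose[mask]


def cumulative_dvh(dose: DoseGrid, mask: np.ndarray, bin_width_gy: float = 0.1) -> DVHCurve:
    """Cumulative dose-volume histogram of the masked voxels.

    V(d) is the percentage of mask voxels receiving at least d Gy,
    evaluated on a regular dose axis from 0 to just past the maximum;
    V(0) = 100 and the curve is nonincreasing.
    """
    if bin_width_gy <= 0:
        raise ValueError("bin width must be positive")
    d = _mask_doses(dose, mask)
    n_bins = int(np.ceil(d.max() / bin_width_gy)) + 1
    axis = np.arange(n_bins + 1) * bin_width_gy
    vol = 100.0 * np.mean(d[None, :] >= axis[:, None], axis=1)
    return DVHCurve(axis, vol)


def dose_at_volume(dose: DoseGrid, mask: np.ndarray, x_percent: float) -> float:
    """Dx%: the dose received by at least x% of the masked volume.

    Nearest-rank convention: with the masked doses sorted descending,
    returns the value at rank ceil(x/100 * N).
    """
    if not (0.0 < x_percent <= 100.0):
        raise ValueError("x_percent must be in (0, 100]")
    d = np.sort(_mask_doses(dose, mask))[::-1]
    rank = int(np.ceil(x_percent / 100.0 * len(d)))
    return float(d[rank - 1])


def dose_stats(ref: DoseGrid, test: DoseGrid, gtv: np.ndarray) -> DVHStats:
    """DVH statistics of the target plus global max point dose comparison."""
    if ref.dose.shape != test.dose.shape:
        raise ValueError("reference and test dose grids differ in shape")
    vals = {}
    for x, key in ((2, "d2"), (50, "d50"), (98, "d98")):
        r = dose_at_volume(ref, gtv, x)
        t = dose_at_volume(test, gtv, x)
        vals[f"{key}_ref"] = r
        vals[f"{key}_test"] = t
        vals[f"{key}_diff"] = r - t
        vals[f"{key}_diff_percent"] = 100.0 * (r - t) / r if r != 0 else np.nan
    max_ref = float(ref.dose.max())
    max_test = float(test.dose.max())
    return DVHStats(
        **vals,
        max_ref=max_ref,
        max_test=max_test,
        max_diff=max_ref - max_test,
        max_diff_percent=100.0 * (max_ref - max_test) / max_ref if max_ref else np.nan,
    )


def _offset_shells(radius_mm: float, step_mm: float):
    """Spatial offsets within the search sphere, grouped in shells of one
    step width and sorted by radius.  Yields (shell_min_radius, offsets)."""
    n = int(np.floor(radius_mm / step_mm))
    ax = np.arange(-n, n + 1) * step_mm
    oz, oy, ox = np.meshgrid(ax, ax, ax, indexing="ij")
    offsets = np.stack([oz.ravel(), oy.ravel(), ox.ravel()], axis=1)
    norms = np.linalg.norm(offsets, axis=1)
    keep = norms <= radius_mm + 1e-12
    offsets, norms = offsets[keep], norms[keep]
    shell_idx = np.floor(norms / step_mm).astype(int)
    order = np.argsort(shell_idx, kind="stable")
    offsets, norms, shell_idx = offsets[order], norms[order], shell_idx[order]
    for k in np.unique(shell_idx):
        sel = shell_idx == k
        yield k * step_mm, offsets[sel], norms[sel]


def gamma_map(ref: DoseGrid, test: DoseGrid, crit: GammaCriteria) -> GammaResult:
    """3D global gamma of ``test`` against ``ref``.

    The grids must share a physical space but may differ in shape,
    spacing or origin; the test dose is trilinearly interpolated at every
    searched position.  Reference voxels below the low-dose threshold are
    not evaluated.  The search is capped at ``search_radius_factor * dta``,
    which caps reported gamma values accordingly.
    """
    ref_max = float(ref.dose.max())
    if ref_max <= 0:
        raise ValueError("reference dose maximum must be positive")
    threshold = crit.low_dose_threshold_percent / 100.0 * ref_max
    evaluated = ref.dose >= threshold
    if not evaluated.any():
        raise ValueError("no reference voxel reaches the low-dose threshold")

    dd = crit.dose_percent / 100.0 * ref_max
    dta = crit.dta_mm
    step = crit.step_fraction * dta
    radius = crit.search_radius_factor * dta

    idx = np.argwhere(evaluated)
    pos_mm = np.asarray(ref.origin) + idx * np.asarray(ref.spacing)
    ref_vals = ref.dose[evaluated]

    test_origin = np.asarray(test.origin)
    test_spacing = np.asarray(test.spacing)

    def test_at(points_mm: np.ndarray) -> np.ndarray:
        coords = ((points_mm - test_origin) / test_spacing).T
        return map_coordinates(test.dose.astype(np.float64), coords,
                               order=1, mode="constant", cval=np.nan)

    # gamma^2 at zero offset: pure dose difference
    t0 = test_at(pos_mm)
    diff0 = np.where(np.isnan(t0), np.inf, (t0 - ref_vals) / dd)
    g2 = diff0 ** 2

    active = np.arange(len(ref_vals))
    for shell_min, offsets, norms in _offset_shells(radius, step):
        if shell_min == 0.0:
            continue  # zero offset already done
        spatial_floor = (shell_min / dta) ** 2
        # voxels that can no longer improve are finalised
        active = active[g2[active] > spatial_floor]
        if len(active) == 0:
            break
        pts = pos_mm[active]
        # chunk offsets so the coordinate block stays modest
        max_block = max(1, int(4_000_000 / max(1, len(active))))
        for s in range(0, len(offsets), max_block):
            off = offsets[s:s + max_block]
            nrm = norms[s:s + max_block]
            q = (pts[None, :, :] + off[:, None, :]).reshape(-1, 3)
            tv = test_at(q).reshape(len(off), len(active))
            dose_term = (tv - ref_vals[active][None, :]) / dd
            cand = np.where(np.isnan(tv), np.inf,
                            dose_term ** 2 + ((nrm / dta) ** 2)[:, None])
            g2[active] = np.minimum(g2[active], cand.min(axis=0))

    gamma_vals = np.sqrt(g2)
    gmap = np.full(ref.dose.shape, np.nan)
    gmap[evaluated] = gamma_vals
    pass_rate = 100.0 * np.mean(gamma_vals <= 1.0 + _PASS_TOL)
    return GammaResult(gmap, evaluated, float(pass_rate))


def gamma_summary(ref: DoseGrid, test: DoseGrid,
                  criteria: list[GammaCriteria]) -> pd.DataFrame:
    """Pass rates for a list of criteria, one row per criterion."""
    if not criteria:
        raise ValueError("at least one gamma criterion is required")
    rows = []
    for crit in criteria:
        res = gamma_map(ref, test, crit)
        rows.append({
            "criteria": crit.label,
            "dose_percent": crit.dose_percent,
            "dta_mm": crit.dta_mm,
            "pass_rate_percent": res.pass_rate_percent,
            "n_evaluated": res.n_evaluated,
        })
    return pd.DataFrame(rows)
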