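"""Seeded digital pelvis phantoms for exercising the full pipeline.

Real paired CBCT/CT data are IRB-restricted, so every experiment here runs
on a procedurally generated cohort that reproduces the *statistical*
structure of a pelvic case: an ellipsoid-composite anatomy (soft tissue,
bladder, prostate, rectum with a gas pocket, femoral heads, sacrum), a
CBCT degraded by cupping, noise, streaks and a global HU shift, a
"deformably registered" CT carrying residual deformation plus a local
structural mismatch (the gas pocket exists on the CBCT but not on the
registered CT), and an analytic multi-beam dose distribution.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import HU_MAX, HU_MIN, DoseGrid, Grid, ImageVolume, StructureSet
from .hu_eval import REDCurve, hu_to_red

AIR_HU = -1000.0


@dataclass(frozen=True)
class StructureDef:
    """An ellipsoidal structure: geometry in mm plus an HU distribution.

    ``priority`` resolves painting order where structures overlap; a
    higher priority paints over a lower one.  Two overlapping structures
    with equal priority are a spec error.
    """

    name: str
    center_mm: tuple[float, float, float]  # (z, y, x)
    radii_mm: tuple[float, float, float]
    hu_mean: float
    hu_sigma: float
    priority: int

    def __post_init__(self):
        if self.hu_sigma < 0:
            raise ValueError(f"{self.name}: hu_sigma must be >= 0")
        if not (HU_MIN <= self.hu_mean <= HU_MAX):
            raise ValueError(f"{self.name}: hu_mean outside the HU range")
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError(f"{self.name}: radii must be positive")


@dataclass(frozen=True)
class BeamSpec:
    """A parallel pencil-beam field rotating in the axial plane.

    ``gantry_angle_deg`` = 0 points the beam along +y (anterior→posterior
    in this phantom's layout), 90 along +x.  ``sigma_mm`` is the lateral
    Gaussian width, ``mu_per_mm`` the effective linear attenuation
    coefficient in water-equivalent depth.
    """

    gantry_angle_deg: float = 0.0
    sigma_mm: float = 15.0
    entrance_dose_gy: float = 1.0
    mu_per_mm: float = 0.005

    def direction(self) -> np.ndarray:
        g = math.radians(self.gantry_angle_deg)
        d = np.array([0.0, math.cos(g), math.sin(g)])
        # snap rounding dust (sin(pi) ~ 1e-16) so cardinal beams march on
        # exact grid lines instead of drifting infinitesimally off-grid
        d[np.abs(d) < 1e-12] = 0.0
        return d / np.linalg.norm(d)


# pelvis layout as fractions of the grid extent (z, y, x); the mm values in
# the comments refer to the default 48 x 192 x 192 mm grid
_PELVIS_LAYOUT = (
    # name, centre fractions, radius fractions, hu_mean, hu_sigma, priority
    ("body", (0.5, 0.5, 0.5), (2.5, 0.365, 0.443), 20, 15, 0),          # trunk
    ("bladder", (0.5, 0.406, 0.5), (0.333, 0.094, 0.104), 5, 10, 1),
    ("prostate", (0.5, 0.542, 0.5), (0.25, 0.057, 0.068), 45, 10, 2),
    ("rectum", (0.5, 0.656, 0.5), (0.417, 0.0625, 0.0625), 25, 15, 3),
    ("rectum_gas", (0.5, 0.656, 0.5), (0.208, 0.0365, 0.0365), -950, 25, 4),
    ("femur_l", (0.5, 0.542, 0.1875), (0.833, 0.0833, 0.0677), 500, 80, 5),
    ("femur_r", (0.5, 0.542, 0.8125), (0.833, 0.0833, 0.0677), 500, 80, 6),
    ("sacrum", (0.5, 0.771, 0.5), (0.729, 0.0625, 0.115), 400, 80, 7),
)


def default_structures(shape=(16, 64, 64), spacing=(3.0, 3.0, 3.0),
                       origin=(0.0, 0.0, 0.0)) -> tuple[StructureDef, ...]:
    """Pelvis-like layout scaled to the grid's physical extent."""
    extent = np.asarray(shape) * np.asarray(spacing)
    org = np.asarray(origin)
    out = []
    for name, cf, rf, mean, sigma, prio in _PELVIS_LAYOUT:
        center = tuple(org + np.asarray(cf) * extent)
        radii = tuple(np.asarray(rf) * extent)
        out.append(StructureDef(name, center, radii, mean, sigma, prio))
    return tuple(out)


def default_beams() -> tuple[BeamSpec, ...]:
    """Four-field box, 1 Gy per-beam entrance dose."""
    return tuple(BeamSpec(gantry_angle_deg=a) for a in (0.0, 90.0, 180.0, 270.0))


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to generate one paired phantom sample."""

    shape: tuple[int, int, int] = (16, 64, 64)   # (z, y, x) voxels
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    structures: tuple[StructureDef, ...] | None = None  # None: scaled pelvis
    # CBCT artifact strengths
    cupping_amplitude_hu: float = 60.0
    noise_sigma_hu: float = 25.0
    streak_count: int = 4
    streak_intensity_hu: float = 150.0
    global_shift_hu: float = 30.0
    # residual-registration deformation
    max_displacement_mm: float = 4.0
    deformation_smoothness_vox: float = 3.0
    # structure present on the CBCT but absent from the registered CT
    mismatch_structure: str | None = "rectum_gas"
    beams: tuple[BeamSpec, ...] = field(default_factory=default_beams)
    dose_step_mm: float = 1.0

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing) or any(n <= 0 for n in self.shape):
            raise ValueError("invalid grid")
        if self.structures is None:
            object.__setattr__(self, "structures",
                               default_structures(self.shape, self.spacing,
                                                  self.origin))
        if self.noise_sigma_hu < 0 or self.cupping_amplitude_hu < 0:
            raise ValueError("artifact strengths must be >= 0")
        if self.streak_count < 0 or self.streak_intensity_hu < 0:
            raise ValueError("streak parameters must be >= 0")
        if self.deformation_smoothness_vox <= 0:
            raise ValueError("deformation smoothness must be positive")
        if self.dose_step_mm <= 0:
            raise ValueError("dose ray-march step must be positive")
        names = [s.name for s in self.structures]
        if len(set(names)) != len(names):
            raise ValueError("duplicate structure names")
        if self.mismatch_structure is not None and self.mismatch_structure not in names:
            raise ValueError(f"unknown mismatch structure {self.mismatch_structure!r}")


@dataclass
class PairedSample:
    """One training/evaluation unit: all members share a single grid."""

    ct: ImageVolume
    cbct: ImageVolume
    registered_ct: ImageVolume
    mismatch_mask: np.ndarray
    structures: StructureSet
    ref_dose: DoseGrid


def _voxel_center_coords(spec: PhantomSpec) -> list[np.ndarray]:
    return [
        spec.origin[a] + np.arange(spec.shape[a]) * spec.spacing[a]
        for a in range(3)
    ]


def _ellipsoid_mask(spec: PhantomSpec, s: StructureDef) -> np.ndarray:
    cz, cy, cx = _voxel_center_coords(spec)
    z, y, x = np.meshgrid(cz, cy, cx, indexing="ij")
    q = (
        ((z - s.center_mm[0]) / s.radii_mm[0]) ** 2
        + ((y - s.center_mm[1]) / s.radii_mm[1]) ** 2
        + ((x - s.center_mm[2]) / s.radii_mm[2]) ** 2
    )
    return q <= 1.0


def make_phantom_ct(spec: PhantomSpec, seed: int) -> tuple[ImageVolume, StructureSet]:
    """Paint the HU phantom structure by structure and return its masks.

    Voxels start at air (-1000 HU); each structure paints its ellipsoid
    (clipped to the body where one exists) with ``N(hu_mean, hu_sigma^2)``
    noise, higher priority painting over lower.  Masks are the full
    painted ellipsoids, so an organ containing a higher-priority insert
    (rectum around its gas pocket) keeps the insert inside its own mask.
    """
    rng = np.random.default_rng(seed)
    vox = np.full(spec.shape, AIR_HU)
    ordered = sorted(spec.structures, key=lambda s: s.priority)
    for a, b in zip(ordered, ordered[1:]):
        if a.priority == b.priority:
            ma, mb = _ellipsoid_mask(spec, a), _ellipsoid_mask(spec, b)
            if (ma & mb).any():
                raise ValueError(
                    f"structures {a.name!r} and {b.name!r} overlap at equal priority"
                )
    body_mask = None
    masks = {}
    for s in ordered:
        m = _ellipsoid_mask(spec, s)
        if s.name == "body":
            body_mask = m
        elif body_mask is not None:
            m = m & body_mask  # anatomical containment
        masks[s.name] = m
        vox[m] = s.hu_mean + (rng.standard_normal(int(m.sum())) * s.hu_sigma
                              if s.hu_sigma > 0 else 0.0)
    np.clip(vox, HU_MIN, HU_MAX, out=vox)
    structures = StructureSet(Grid(spec.shape, spec.spacing, spec.origin), masks)
    return ImageVolume(vox, spec.spacing, spec.origin), structures


def cupping_field(spec: PhantomSpec) -> np.ndarray:
    """Analytic radial bias field: -A at the in-plane centre, 0 at the
    in-plane corner radius, quadratic in between."""
    cz, cy, cx = _voxel_center_coords(spec)
    yc = 0.5 * (cy[0] + cy[-1])
    xc = 0.5 * (cx[0] + cx[-1])
    y, x = np.meshgrid(cy - yc, cx - xc, indexing="ij")
    r2 = y ** 2 + x ** 2
    r2max = r2.max()
    if r2max == 0:
        field2d = np.zeros_like(r2)
    else:
        field2d = -spec.cupping_amplitude_hu * (1.0 - r2 / r2max)
    return np.broadcast_to(field2d[None, :, :], spec.shape).copy()


def degrade_to_cbct(ct: ImageVolume, spec: PhantomSpec, seed: int) -> ImageVolume:
    """Apply CBCT-like artifacts: cupping, noise, gas streaks, HU shift.

    With all artifact strengths zero the input is reproduced exactly.
    Streaks emanate from gas voxels inside the body at random in-plane
    angles, with Gaussian lateral profile and exponential attenuation
    along the line.
    """
    rng = np.random.default_rng(seed)
    vox = ct.voxels.copy()
    dirty = False
    if spec.cupping_amplitude_hu > 0:
        vox += cupping_field(spec)
        dirty = True
    if spec.noise_sigma_hu > 0:
        vox += rng.standard_normal(vox.shape) * spec.noise_sigma_hu
        dirty = True
    if spec.streak_count > 0 and spec.streak_intensity_hu > 0:
        interior = ndimage.binary_fill_holes(ct.voxels > -300)
        gas = interior & (ct.voxels < -500)
        gas_idx = np.argwhere(gas)
        if len(gas_idx):
            cz, cy, cx = _voxel_center_coords(spec)
            y, x = np.meshgrid(cy, cx, indexing="ij")
            for _ in range(spec.streak_count):
                gz, gy, gx = gas_idx[rng.integers(len(gas_idx))]
                phi = rng.uniform(0, 2 * np.pi)
                sign = 1.0 if rng.uniform() < 0.5 else -1.0
                oy, ox = cy[gy], cx[gx]
                # signed distances along / across the streak line
                u = (y - oy) * np.cos(phi) + (x - ox) * np.sin(phi)
                v = -(y - oy) * np.sin(phi) + (x - ox) * np.cos(phi)
                profile = (sign * spec.streak_intensity_hu
                           * np.exp(-(v ** 2) / (2 * 2.0 ** 2))
                           * np.exp(-np.abs(u) / 60.0))
                vox[gz] += profile
            dirty = True
    if spec.global_shift_hu != 0:
        vox += spec.global_shift_hu
        dirty = True
    if dirty:
        np.clip(vox, HU_MIN, HU_MAX, out=vox)
    return ImageVolume(vox, ct.spacing, ct.origin)


def displacement_field(spec: PhantomSpec, seed: int) -> np.ndarray:
    """Smooth random displacement field (mm), shape (3, *grid shape).

    Gaussian-smoothed white noise per component, rescaled so the maximum
    vector norm equals ``max_displacement_mm``; identically zero when the
    bound is zero.
    """
    if spec.max_displacement_mm < 0:
        raise ValueError("max displacement must be >= 0")
    if spec.max_displacement_mm == 0:
        return np.zeros((3, *spec.shape))
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((3, *spec.shape))
    smooth = np.stack([
        ndimage.gaussian_filter(raw[c], spec.deformation_smoothness_vox, mode="nearest")
        for c in range(3)
    ])
    norms = np.sqrt((smooth ** 2).sum(axis=0))
    peak = norms.max()
    if peak == 0:
        return smooth
    return smooth * (spec.max_displacement_mm / peak)


def make_registered_ct(ct: ImageVolume, cbct_structures: StructureSet,
                       spec: PhantomSpec, seed: int) -> tuple[ImageVolume, np.ndarray]:
    """Emulate a deformably registered planning CT.

    The true CT is warped by a smooth bounded displacement field (the
    residual error a real DIR would leave) and, if a mismatch structure is
    configured, that structure's region is replaced by surrounding-tissue
    HU — emulating anatomy (e.g. a gas pocket) present at treatment time
    but absent from the planning CT.  Returns the registered volume and a
    mask marking exactly the replaced region.
    """
    if spec.mismatch_structure is not None and spec.max_displacement_mm <= 0:
        raise ValueError("a structural mismatch requires a positive displacement bound")
    disp = displacement_field(spec, seed)
    if np.any(disp):
        idx = np.indices(spec.shape, dtype=np.float64)
        coords = idx + disp / np.asarray(spec.spacing)[:, None, None, None]
        warped = ndimage.map_coordinates(ct.voxels, coords, order=1, mode="nearest")
    else:
        warped = ct.voxels.copy()
    if spec.mismatch_structure is None:
        mismatch = np.zeros(spec.shape, dtype=bool)
    else:
        mismatch = np.asarray(cbct_structures[spec.mismatch_structure], dtype=bool).copy()
        shell = ndimage.binary_dilation(mismatch, iterations=2) & ~mismatch
        fill_hu = float(np.median(warped[shell])) if shell.any() else 0.0
        warped[mismatch] = fill_hu
    np.clip(warped, HU_MIN, HU_MAX, out=warped)
    return ImageVolume(warped, ct.spacing, ct.origin), mismatch


def make_dose(ct: ImageVolume, spec: PhantomSpec,
              curve: REDCurve = REDCurve()) -> DoseGrid:
    """Analytic exponential-attenuation Gaussian pencil-beam dose.

    dose = sum over beams of entrance_dose * exp(-lat^2 / 2 sigma^2)
    * exp(-mu * radiological depth), where radiological depth is the
    midpoint-rule line integral of relative electron density along the
    beam direction from the grid boundary to the voxel (rED outside the
    grid counts as zero).  Deterministic; error if a beam's central axis
    misses the grid.
    """
    if not spec.beams:
        raise ValueError("at least one beam is required")
    cz, cy, cx = _voxel_center_coords(spec)
    z, y, x = np.meshgrid(cz, cy, cx, indexing="ij")
    pts = np.stack([z.ravel(), y.ravel(), x.ravel()], axis=1)
    origin = np.asarray(ct.origin)
    spacing = np.asarray(ct.spacing)
    lo = origin
    hi = origin + (np.asarray(ct.shape) - 1) * spacing
    iso = 0.5 * (lo + hi)
    red = hu_to_red(ct.voxels, curve)
    diag = float(np.linalg.norm(hi - lo))
    step = spec.dose_step_mm
    ts = np.arange(step / 2.0, diag + step, step)
    dose = np.zeros(pts.shape[0])
    for beam in spec.beams:
        d = beam.direction()
        _check_axis_hits_grid(iso, d, lo, hi)
        v = pts - iso
        along = v @ d
        lat2 = (v ** 2).sum(axis=1) - along ** 2
        raddepth = np.zeros(pts.shape[0])
        for t in ts:
            q = pts - d[None, :] * t
            coords = ((q - origin) / spacing).T
            raddepth += ndimage.map_coordinates(red, coords, order=1,
                                                mode="constant", cval=0.0)
        raddepth *= step
        dose += (beam.entrance_dose_gy
                 * np.exp(-lat2 / (2.0 * beam.sigma_mm ** 2))
                 * np.exp(-beam.mu_per_mm * raddepth))
    return DoseGrid(dose.reshape(spec.shape), ct.spacing, ct.origin)


def _check_axis_hits_grid(iso, d, lo, hi):
    """Slab test: does the line iso + t*d intersect the grid box?"""
    tmin, tmax = -np.inf, np.inf
    for a in range(3):
        if abs(d[a]) < 1e-12:
            if iso[a] < lo[a] or iso[a] > hi[a]:
                raise ValueError("beam axis misses the grid")
        else:
            t1 = (lo[a] - iso[a]) / d[a]
            t2 = (hi[a] - iso[a]) / d[a]
            tmin = max(tmin, min(t1, t2))
            tmax = min(tmax, max(t1, t2))
    if tmin > tmax:
        raise ValueError("beam axis misses the grid")


_BOX = ndimage.generate_binary_structure(3, 3)


def perturb_contour(mask: np.ndarray, mode: str, magnitude: float,
                    seed: int = 0) -> np.ndarray:
    """Fabricate an "auto-segmented" contour from a reference one.

    Modes: ``dilate``/``erode`` by ``magnitude`` voxels in every
    direction (3x3x3 box structuring element, so a cube grows by one
    voxel per face *and* corner: a 10^3 cube dilated once becomes 12^3),
    ``boundary_noise`` (toggle each boundary-band voxel with probability
    ``magnitude``), ``shift`` (rigid shift by ``magnitude`` voxels along
    a seeded random direction).  Magnitude 0 is the identity for every
    mode.
    """
    mask = np.asarray(mask, dtype=bool)
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if magnitude == 0:
        return mask.copy()
    if mode == "dilate":
        return ndimage.binary_dilation(mask, structure=_BOX,
                                       iterations=int(round(magnitude)))
    if mode == "erode":
        return ndimage.binary_erosion(mask, structure=_BOX,
                                      iterations=int(round(magnitude)))
    if mode == "boundary_noise":
        rng = np.random.default_rng(seed)
        band = (ndimage.binary_dilation(mask, structure=_BOX)
                ^ ndimage.binary_erosion(mask, structure=_BOX))
        flip = band & (rng.uniform(size=mask.shape) < min(magnitude, 1.0))
        return mask ^ flip
    if mode == "shift":
        rng = np.random.default_rng(seed)
        vec = rng.standard_normal(3)
        vec /= np.linalg.norm(vec)
        shift = np.round(vec * magnitude).astype(int)
        out = np.zeros_like(mask)
        src = [slice(max(0, -s), mask.shape[a] - max(0, s)) for a, s in enumerate(shift)]
        dst = [slice(max(0, s), mask.shape[a] - max(0, -s)) for a, s in enumerate(shift)]
        out[tuple(dst)] = mask[tuple(src)]
        return out
    raise ValueError(f"unknown perturbation mode {mode!r}")


def make_paired_sample(spec: PhantomSpec, seed: int,
                       curve: REDCurve = REDCurve(),
                       include_dose: bool = True) -> PairedSample:
    """Generate a complete paired sample (CT, CBCT, registered CT, masks,
    mismatch mask, reference dose) from one seed.

    ``include_dose=False`` skips the dose calculation (the slow part) for
    callers that only need images, leaving ``ref_dose`` as ``None``.
    """
    rng = np.random.default_rng(seed)
    s_ct, s_cbct, s_reg = (int(rng.integers(2 ** 31)) for _ in range(3))
    ct, structures = make_phantom_ct(spec, s_ct)
    cbct = degrade_to_cbct(ct, spec, s_cbct)
    registered, mismatch = make_registered_ct(ct, structures, spec, s_reg)
    ref_dose = make_dose(ct, spec, curve) if include_dose else None
    return PairedSample(ct, cbct, registered, mismatch, structures, ref_dose)
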