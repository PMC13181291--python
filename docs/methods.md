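# Methods

This note records the models, conventions and numerical choices behind
`sctkit`, in enough detail to reproduce or critique them.

## The translation model and its loss

**Pairing.**  Training assumes *pre-registered* pairs: each CBCT volume
comes with a deformably registered planning CT on the same grid.  No
registration is performed in this package; the phantom generator produces
the registered CT directly (see below).

**Preprocessing.**  Axial slices are resampled (centre-aligned bilinear)
to a square in-plane grid — 256x256 at 1.6 mm by default, 64x64 at 3 mm in
the toy configuration — and intensities are clipped to [-1000, 2000] HU and
mapped affinely to [-1, 1].  Clipping before rescaling makes the intensity
map exactly invertible on the clipped range; postprocessing inverts the
map and resamples back to the original grid.  HU outside the window cannot
be represented (air below -1000 HU saturates at -1), which is the standard
trade-off of windowed normalisation.

**Generator.**  A 2D ResUnet: an encoder/decoder whose channel width
doubles per level, short residual blocks at every level, and long
(concatenation) skip connections on the early levels only (the first three
of five at full scale; the first of two in the toy configuration).  The
network predicts a *residual correction* that is added to the input slice,
and the sum is bounded to [-1, 1] by a hard-saturating clip.  This global
identity skip is the natural parameterisation for artifact correction —
the target image is the input minus its artifacts — and it means an
untrained generator is already the identity, so training only has to learn
the artifact inverse.  At the small training budgets used here that is the
difference between converging and not.

**Discriminator.**  A least-squares patchGAN: stacked 4x4 convolutions
(stride 2 except the last), instance normalisation after all but the
first, leaky-ReLU (0.2), and a 1-channel projection.  The canonical
4-layer stack maps a 256x256 slice to a 30x30 patch-score map.

**Loss.**  For a CBCT slice x and registered CT slice y the generator
objective is

    lambda_ssim * [ mean(W(x,y) . |G(x) - y|) + mean(W(y,x) . |F(y) - x|) ]
  + lambda_cycle * [ mean|F(G(x)) - x| + mean|G(F(y)) - y| ]
  + lambda_adv  * [ LSGAN generator terms for both discriminators ]

with W the *thresholded local SSIM map*: per-pixel SSIM over uniform
(unweighted) 7x7 patches with reflection padding, stability constants
C1 = (0.01 L)^2, C2 = (0.03 L)^2 for dynamic range L = 2, kept where it is
at least alpha = 0.5 and set to zero below.  The weight map is a function
of the data pair only; it is treated as a constant during optimisation (no
gradient flows through it), acting as a mask on the supervised residual.
Weights default to lambda_cycle = lambda_ssim = 10, lambda_adv = 1.  No
identity loss is used.  The same alpha serves both translation directions.

**Optimisation.**  Adam (beta1 = 0.5), batch size 4, learning rate 2e-4
held constant for the first half of training and then decreased linearly
to exactly zero at the final epoch (sampled at epoch start; 40 epochs with
the break at 20 by default).  Per batch the discriminators update first on
detached fakes, then both generators take one joint step.  Everything is
seeded — model initialisation, batch shuffling — so repeated runs are
bitwise identical; a NaN in any loss term aborts with the term's name.

## The digital pelvis phantom

The phantom exists to exercise the method and its evaluation, not to be
anatomically realistic.  It emulates the *statistical* structure of a
pelvic case:

* **Anatomy** — an ellipsoid composite scaled to the grid extent: body
  soft tissue (20 ± 15 HU), bladder (5 ± 10), prostate (45 ± 10), rectum
  (25 ± 15) containing a gas pocket (-950 ± 25), femoral heads and sacrum
  (500 ± 80 / 400 ± 80).  Overlaps resolve by explicit priority; equal
  priorities overlapping is an error.  Default grid 64x64x16 at 3 mm.
* **CBCT degradation** — a radial cupping field (-A at the in-plane
  centre, zero at the corner radius, A = 60 HU default), additive Gaussian
  noise (sigma = 25 HU), streaks through gas voxels at random in-plane
  angles (Gaussian lateral profile, exponential attenuation along the
  line, ±150 HU, 4 per volume), and a global +30 HU shift.  Zero-strength
  parameters reproduce the input exactly; mean absolute error grows
  monotonically with each knob.  These magnitudes are plausible for
  clinical CBCT but are not calibrated against any scanner.
* **Registered CT** — the true CT warped by Gaussian-smoothed random
  displacement vectors rescaled so the maximum norm equals the bound
  (4 mm default), after which the gas pocket's region is replaced by the
  median HU of its surrounding shell.  That replaced region *is* the
  structural mismatch: anatomy real on the CBCT, absent from the
  registered CT, marked exactly by the returned mask.
* **Dose** — parallel Gaussian pencil beams in the axial plane:
  dose = entrance * exp(-lat^2 / 2 sigma^2) * exp(-mu * d_rad), with
  radiological depth d_rad the midpoint-rule line integral of relative
  electron density (rED outside the grid counts as zero) at 1 mm steps.
  mu = 0.005/mm and sigma = 15 mm approximate a 6 MV beam; the default
  plan is a four-field box.  Dose is exactly linear in entrance dose and
  has a closed-form central-axis solution used as a test oracle.

What the phantom does **not** model: projection-domain physics (real
scatter, beam hardening spectra, ring artifacts), realistic organ shapes
or textures, heterogeneity corrections beyond the rED line integral, and
inter-fraction anatomy change beyond the single mismatch structure.
Passing tests on phantoms therefore demonstrates that the *mechanisms*
work (loss masking, metric correctness, pipeline plumbing), not that the
model reaches clinical image quality.

## Evaluation conventions

* **HU → rED** — piecewise-linear with clamped ends; default 3-knot
  water-anchored curve (-1000, 0), (0, 1), (2000, 2.2).
* **Surfaces** — a mask voxel is on the surface when a 6-neighbour is
  background or off-grid; surface points are voxel centres in mm.  This
  makes DSC/MDA/HD exactly reproducible by enumeration at the cost of
  voxel-spacing quantisation.  Distances use exact KD-tree nearest
  neighbours in mm (anisotropic spacing handled by construction).
  dice(empty, empty) = 1; distance metrics on an empty surface raise.
* **Dx%** — nearest-rank on the descending sorted doses
  (rank = ceil(x/100 * N)), the dose received by at least x% of the
  volume; D2% is the near-maximum and D98% the near-minimum dose.  This
  diverges from DVH engines that interpolate between samples, and is
  chosen because it is exact and oracle-matched.
* **Gamma** — global normalisation to the reference maximum; voxels below
  the low-dose threshold (default 10% of reference max) are not
  evaluated.  The DTA minimisation is a dense search within
  2 x dta at step dta/10 with trilinear interpolation of the test dose,
  organised in shells of increasing radius with early per-voxel
  finalisation; gamma is capped at the search boundary.  Positions
  outside the test grid's extent do not contribute.  The pass test
  gamma <= 1 carries a 1e-9 relative tolerance so that exact-boundary
  cases (a uniform field off by exactly the dose criterion) classify as
  passing rather than failing on float rounding.
* **Contour perturbations** — dilate/erode use a 3x3x3 box structuring
  element ("one voxel in every direction", so a 10^3 cube dilated once is
  12^3); boundary noise toggles voxels in the one-voxel boundary band
  with the given probability; shift is rigid along a seeded random
  direction.
* **FOV cropping** — an axis-aligned box (the cylindrical CBCT FOV is
  approximated by its bounding box); masks that vanish entirely under
  cropping raise instead of silently returning empty structures.
* **NIfTI** — diagonal affines only (axis-aligned volumes); HU stored as
  int16, masks as uint8, dose as float32.

## Problem sizes used in the shipped experiments

The test suite and `scripts/acceptance.py` run everything at desk scale,
chosen so the full study is a few minutes on one CPU: toy networks
(2 levels, 8 base channels; 3-layer discriminator), 64x64 slices at 3 mm,
a training cohort of 10 phantoms x 15 slices = 150 slice pairs, 5 epochs,
and 3 held-out phantoms.  The full-scale configuration (5 levels, 256x256
at 1.6 mm, 40 epochs) is available through the same specs but is not part
of any shipped experiment.

## Observed behaviour and known limitations

* On held-out phantoms the toy model reduces the body-masked MAE versus
  the true CT below the CBCT baseline while staying close to the CBCT
  inside the mismatch region (hundreds of HU closer than to the
  registered CT) — the end-to-end signature of the SSIM masking.  The
  margins are what a 190-step training budget buys; they are not clinical
  image quality.
* Rank correlation of line profiles against the reference CT is dominated
  by the bone/soft-tissue dynamic range when the profile crosses the
  femurs; on this phantom both CBCT and sCT correlate highly and the sCT
  advantage reported for clinical images need not emerge.
* The analytic dose model smooths HU errors heavily (line integrals +
  lateral Gaussian), so refCT-vs-sCT gamma pass rates on phantoms sit at
  or near 100% for all clinical criteria; the gamma implementation itself
  is validated separately against an exhaustive dense-search oracle on
  deliberately disagreeing dose pairs.
* The windowed SSIM map is not invariant under pixel permutations (its
  windows are spatial); permutation invariance holds only for the cycle
  and adversarial terms.
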