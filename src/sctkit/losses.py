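"""Loss arithmetic for SSIM-weighted cycle-consistent CBCT→CT translation.

The central idea: when training on a CBCT paired with a deformably
registered CT, residual registration error means that some regions of the
"paired" CT simply do not match today's anatomy (gas pockets, bowel
motion).  A per-pixel local SSIM map between the CBCT slice ``x`` and the
registered CT slice ``y`` identifies where the pair actually agrees; the
supervised L1 term is weighted by that map, with weights below a threshold
``alpha`` set to zero so that mismatched regions contribute nothing and are
governed by the cycle-consistency loss instead.  This is what preserves
CBCT structures the registered CT does not contain.

All image inputs are expected on the normalised [-1, 1] intensity scale
produced by :func:`sctkit.model.preprocess`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter


@dataclass(frozen=True)
class LossConfig:
    """Configuration of the composite generator loss.

    Parameters
    ----------
    alpha:
        SSIM threshold in [0, 1]; local SSIM below ``alpha`` gets weight 0.
    window:
        Odd side length of the square SSIM patch (pixels).
    c1, c2:
        SSIM stability constants.  Defaults follow the usual
        ``(0.01 L)^2`` / ``(0.03 L)^2`` with dynamic range ``L = 2`` for
        [-1, 1]-scaled images.
    lambda_cycle, lambda_ssim, lambda_adv:
        Nonnegative weights of the cycle, SSIM-weighted-L1 and adversarial
        terms in the total generator loss.
    """

    alpha: float = 0.5
    window: int = 7
    c1: float = (0.01 * 2.0) ** 2
    c2: float = (0.03 * 2.0) ** 2
    lambda_cycle: float = 10.0
    lambda_ssim: float = 10.0
    lambda_adv: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("stability constants must be positive")
        if min(self.lambda_cycle, self.lambda_ssim, self.lambda_adv) < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class LossBreakdown:
    """Per-term decomposition of the generator objective."""

    ssim_weighted_l1: float
    cycle: float
    adversarial: float
    total: float

    @classmethod
    def compose(cls, ssim_weighted_l1: float, cycle: float, adversarial: float,
                cfg: LossConfig) -> "LossBreakdown":
        parts = (ssim_weighted_l1, cycle, adversarial)
        if not all(np.isfinite(p) for p in parts):
            raise ValueError(f"non-finite loss part in {parts}")
        total = (cfg.lambda_ssim * ssim_weighted_l1
                 + cfg.lambda_cycle * cycle
                 + cfg.lambda_adv * adversarial)
        return cls(ssim_weighted_l1, cycle, adversarial, total)


def _check_same_shape(*arrays):
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch between inputs: {sorted(shapes)}")


def local_ssim_map(x: np.ndarray, y: np.ndarray, cfg: LossConfig = LossConfig()) -> np.ndarray:
    """Per-pixel local SSIM between two registered slices.

    For every pixel, SSIM of the ``window``×``window`` patch centred there
    is computed from patch means, (population) variances and covariance
    with stability constants ``c1``/``c2``.  A uniform (unweighted) window
    is used and boundaries are handled by reflection padding, so the output
    has the same shape as the inputs.  Values are clipped to [-1, 1] to
    absorb floating-point overshoot.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    _check_same_shape(x, y)
    w = cfg.window
    # mode="reflect" repeats the edge sample, matching np.pad(..., "symmetric")
    mu_x = uniform_filter(x, size=w, mode="reflect")
    mu_y = uniform_filter(y, size=w, mode="reflect")
    mu_xx = uniform_filter(x * x, size=w, mode="reflect")
    mu_yy = uniform_filter(y * y, size=w, mode="reflect")
    mu_xy = uniform_filter(x * y, size=w, mode="reflect")
    var_x = mu_xx - mu_x * mu_x
    var_y = mu_yy - mu_y * mu_y
    cov = mu_xy - mu_x * mu_y
    num = (2.0 * mu_x * mu_y + cfg.c1) * (2.0 * cov + cfg.c2)
    den = (mu_x * mu_x + mu_y * mu_y + cfg.c1) * (var_x + var_y + cfg.c2)
    return np.clip(num / den, -1.0, 1.0)


def ssim_weight_map(ssim: np.ndarray, alpha: float) -> np.ndarray:
    """Thresholded SSIM weights: the SSIM value where it is >= alpha, else 0."""
    ssim = np.asarray(ssim, dtype=np.float64)
    return np.where(ssim >= alpha, ssim, 0.0)


def ssim_weighted_l1(x: np.ndarray, y: np.ndarray, gx: np.ndarray,
                     cfg: LossConfig = LossConfig()) -> float:
    """One direction of the SSIM-weighted L1 term.

    ``x`` is the source slice (e.g. CBCT), ``y`` its registered target
    (e.g. CT) and ``gx`` the generator output for ``x``.  Returns
    ``mean( w(x, y) * |gx - y| )`` where ``w`` is the thresholded local
    SSIM map of the *inputs* — the weights depend on the data pair only,
    never on the generator output, so a mismatched region (weight 0) exerts
    no supervised pull on the generator.
    """
    gx = np.asarray(gx, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    _check_same_shape(np.asarray(x), y, gx)
    w = ssim_weight_map(local_ssim_map(x, y, cfg), cfg.alpha)
    return float(np.mean(w * np.abs(gx - y)))


def cycle_consistency_loss(x: np.ndarray, y: np.ndarray,
                           fgx: np.ndarray, gfy: np.ndarray) -> float:
    """L1 cycle-consistency: mean |F(G(x)) - x| + mean |G(F(y)) - y|."""
    x, y = np.asarray(x, dtype=np.float64), np.asarray(y, dtype=np.float64)
    fgx, gfy = np.asarray(fgx, dtype=np.float64), np.asarray(gfy, dtype=np.float64)
    _check_same_shape(x, fgx)
    _check_same_shape(y, gfy)
    return float(np.mean(np.abs(fgx - x)) + np.mean(np.abs(gfy - y)))


def adversarial_losses(d_real: np.ndarray, d_fake: np.ndarray) -> tuple[float, float]:
    """Least-squares GAN terms from discriminator patch-score maps.

    Returns ``(gen_term, disc_term)`` with
    ``gen_term = mean((d_fake - 1)^2)`` and
    ``disc_term = mean((d_real - 1)^2) + mean(d_fake^2)``.
    """
    d_real = np.asarray(d_real, dtype=np.float64)
    d_fake = np.asarray(d_fake, dtype=np.float64)
    if not (np.all(np.isfinite(d_real)) and np.all(np.isfinite(d_fake))):
        raise ValueError("discriminator scores must be finite")
    gen_term = float(np.mean((d_fake - 1.0) ** 2))
    disc_term = float(np.mean((d_real - 1.0) ** 2) + np.mean(d_fake ** 2))
    return gen_term, disc_term


def total_generator_loss(ssim_weighted_l1_part: float, cycle_part: float,
                         adversarial_part: float,
                         cfg: LossConfig = LossConfig()) -> LossBreakdown:
    """Compose the weighted generator objective from its parts."""
    return LossBreakdown.compose(ssim_weighted_l1_part, cycle_part,
                                 adversarial_part, cfg)
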