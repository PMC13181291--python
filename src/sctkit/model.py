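"""CBCT→sCT translation model: preprocessing, networks, training, inference.

The generator is a 2D ResUnet: an encoder/decoder with short residual
blocks at every level and long (concatenation) skip connections on the
first few levels only.  The discriminator is a patchGAN stack of strided
convolutions.  Training is paired and slice-wise: each CBCT axial slice is
paired with the corresponding slice of the deformably registered CT, and
the generator objective combines least-squares adversarial, L1 cycle, and
the thresholded SSIM-weighted L1 terms.

Defaults follow the reference protocol (256×256 at 1.6 mm, 40 epochs,
Adam at 2e-4 constant for 20 epochs then linearly decayed to zero, batch
4); the toy configurations used throughout the tests shrink the grid and
network, not the procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates

from . import nn
from .core import HU_MAX, HU_MIN, ImageVolume
from .losses import (LossBreakdown, LossConfig, local_ssim_map, ssim_weight_map,
                     total_generator_loss)


# ---------------------------------------------------------------------------
# pre/post-processing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreprocessSpec:
    """In-plane resampling target and HU normalisation window."""

    target_size: int = 256
    target_pixel_mm: float = 1.6
    hu_low: float = -1000.0
    hu_high: float = 2000.0

    def __post_init__(self):
        if self.target_size <= 0 or self.target_pixel_mm <= 0:
            raise ValueError("target size and pixel spacing must be positive")
        if self.hu_low >= self.hu_high:
            raise ValueError("hu_low must be below hu_high")


@dataclass(frozen=True)
class GeometryRecord:
    """Everything needed to invert preprocess back to the original grid."""

    orig_shape: tuple[int, int, int]
    orig_spacing: tuple[float, float, float]
    orig_origin: tuple[float, float, float]
    spec: PreprocessSpec
    resampled: bool


def _inplane_identity(vol: ImageVolume, spec: PreprocessSpec) -> bool:
    return (vol.shape[1] == vol.shape[2] == spec.target_size
            and abs(vol.spacing[1] - spec.target_pixel_mm) < 1e-12
            and abs(vol.spacing[2] - spec.target_pixel_mm) < 1e-12)


def hu_to_unit(hu, spec: PreprocessSpec = PreprocessSpec()):
    """Clip HU to the window then map affinely to [-1, 1]."""
    hu = np.clip(np.asarray(hu, dtype=np.float64), spec.hu_low, spec.hu_high)
    return 2.0 * (hu - spec.hu_low) / (spec.hu_high - spec.hu_low) - 1.0


def unit_to_hu(u, spec: PreprocessSpec = PreprocessSpec()):
    """Inverse of :func:`hu_to_unit` on the clipped range."""
    u = np.clip(np.asarray(u, dtype=np.float64), -1.0, 1.0)
    return spec.hu_low + (u + 1.0) / 2.0 * (spec.hu_high - spec.hu_low)


def preprocess(vol: ImageVolume, spec: PreprocessSpec = PreprocessSpec()
               ) -> tuple[np.ndarray, GeometryRecord]:
    """Axial slices resampled to the target in-plane grid and normalised.

    Returns a float array of shape (n_slices, S, S) on the [-1, 1] scale
    plus the geometry record needed by :func:`postprocess`.  Resampling is
    centre-aligned bilinear; regions sampled outside the original image
    read as air.  When the volume is already on the target in-plane grid
    no resampling is performed, making the intensity map exactly
    invertible on the clipped range.
    """
    rec = GeometryRecord(vol.shape, vol.spacing, vol.origin, spec,
                         resampled=not _inplane_identity(vol, spec))
    if not rec.resampled:
        return hu_to_unit(vol.voxels, spec), rec
    s = spec.target_size
    nz, ny, nx = vol.shape
    ty = (np.arange(s) - (s - 1) / 2.0) * spec.target_pixel_mm
    # centre-aligned source indices
    iy = (ny - 1) / 2.0 + ty / vol.spacing[1]
    ix = (nx - 1) / 2.0 + ty / vol.spacing[2]
    gy, gx = np.meshgrid(iy, ix, indexing="ij")
    out = np.empty((nz, s, s))
    for k in range(nz):
        out[k] = map_coordinates(vol.voxels[k], [gy, gx], order=1,
                                 mode="constant", cval=-1000.0)
    return hu_to_unit(out, spec), rec


def postprocess(slices: np.ndarray, rec: GeometryRecord) -> ImageVolume:
    """Invert the intensity map, then resample back to the original grid."""
    slices = np.asarray(slices, dtype=np.float64)
    if slices.ndim != 3 or slices.shape[0] != rec.orig_shape[0]:
        raise ValueError("slice stack does not match the geometry record")
    spec = rec.spec
    if not rec.resampled:
        if slices.shape[1:] != rec.orig_shape[1:]:
            raise ValueError("slice stack does not match the geometry record")
        return ImageVolume(unit_to_hu(slices, spec), rec.orig_spacing, rec.orig_origin)
    if slices.shape[1] != spec.target_size or slices.shape[2] != spec.target_size:
        raise ValueError("slice stack does not match the geometry record")
    hu = unit_to_hu(slices, spec)
    nz, ny, nx = rec.orig_shape
    s = spec.target_size
    oy = (np.arange(ny) - (ny - 1) / 2.0) * rec.orig_spacing[1]
    ox = (np.arange(nx) - (nx - 1) / 2.0) * rec.orig_spacing[2]
    iy = (s - 1) / 2.0 + oy / spec.target_pixel_mm
    ix = (s - 1) / 2.0 + ox / spec.target_pixel_mm
    gy, gx = np.meshgrid(iy, ix, indexing="ij")
    out = np.empty(rec.orig_shape)
    for k in range(nz):
        out[k] = map_coordinates(hu[k], [gy, gx], order=1, mode="nearest")
    return ImageVolume(out, rec.orig_spacing, rec.orig_origin)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorSpec:
    """ResUnet topology.  Channel width doubles per level."""

    levels: int = 5
    long_skip_levels: int = 3
    base_channels: int = 32
    res_blocks_per_level: int = 1

    def __post_init__(self):
        if self.levels < 1 or self.base_channels < 1 or self.res_blocks_per_level < 0:
            raise ValueError("invalid generator spec")
        if self.long_skip_levels > self.levels:
            raise ValueError("long_skip_levels cannot exceed levels")

    def channels_at(self, level: int) -> int:
        return self.base_channels * 2 ** level


@dataclass(frozen=True)
class DiscriminatorSpec:
    """PatchGAN: (n_layers) 4×4 convs, the last at stride 1, then a 1-channel
    projection; channel width doubles per layer."""

    n_layers: int = 4
    base_channels: int = 64
    kernel: int = 4

    def __post_init__(self):
        if self.n_layers < 1 or self.base_channels < 1:
            raise ValueError("invalid discriminator spec")

    def score_map_shape(self, h: int, w: int) -> tuple[int, int]:
        """Spatial extent of the patch score map from stride arithmetic."""
        k = self.kernel
        for i in range(self.n_layers):
            s = 2 if i < self.n_layers - 1 else 1
            h = (h + 2 - k) // s + 1
            w = (w + 2 - k) // s + 1
            if h < 1 or w < 1:
                raise ValueError("input smaller than the discriminator receptive field")
        h = (h + 2 - k) // 1 + 1
        w = (w + 2 - k) // 1 + 1
        if h < 1 or w < 1:
            raise ValueError("input smaller than the discriminator receptive field")
        return h, w


class _ResBlock(nn.Module):
    def __init__(self, c: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(c, c, 3, pad=1, rng=rng)
        self.norm1 = nn.InstanceNorm2d(c)
        self.conv2 = nn.Conv2d(c, c, 3, pad=1, rng=rng)
        self.norm2 = nn.InstanceNorm2d(c)

    def __call__(self, x):
        h = nn.relu(self.norm1(self.conv1(x)))
        h = self.norm2(self.conv2(h))
        return x + h


class ResUnetGenerator(nn.Module):
    """Slice-to-slice generator.

    The encoder/decoder predicts a residual correction that is added to
    the input slice and bounded to [-1, 1] by a hard-saturating
    activation — the network starts near the identity and learns the
    artifact inverse, which is the natural parameterisation for
    CBCT→CT restoration and converges quickly at small training budgets.
    """

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        c0 = spec.channels_at(0)
        self.stem = nn.Conv2d(1, c0, 3, pad=1, rng=rng)
        self.stem_norm = nn.InstanceNorm2d(c0)
        self.enc_res = [[_ResBlock(c0, rng) for _ in range(spec.res_blocks_per_level)]]
        self.down, self.down_norm = [], []
        for lv in range(1, spec.levels):
            ci, co = spec.channels_at(lv - 1), spec.channels_at(lv)
            self.down.append(nn.Conv2d(ci, co, 3, stride=2, pad=1, rng=rng))
            self.down_norm.append(nn.InstanceNorm2d(co))
            self.enc_res.append([_ResBlock(co, rng)
                                 for _ in range(spec.res_blocks_per_level)])
        self.up, self.up_norm, self.merge, self.merge_norm, self.dec_res = \
            [], [], [], [], []
        for lv in range(spec.levels - 1, 0, -1):
            ci, co = spec.channels_at(lv), spec.channels_at(lv - 1)
            self.up.append(nn.Conv2d(ci, co, 3, pad=1, rng=rng))
            self.up_norm.append(nn.InstanceNorm2d(co))
            if lv - 1 < spec.long_skip_levels:
                self.merge.append(nn.Conv2d(2 * co, co, 3, pad=1, rng=rng))
                self.merge_norm.append(nn.InstanceNorm2d(co))
            else:
                self.merge.append(None)
                self.merge_norm.append(None)
            self.dec_res.append([_ResBlock(co, rng)
                                 for _ in range(spec.res_blocks_per_level)])
        self.head = nn.Conv2d(spec.channels_at(0), 1, 3, pad=1, rng=rng)

    def parameters(self):
        params = []
        mods = [self.stem, self.stem_norm]
        for blocks in self.enc_res:
            mods.extend(blocks)
        mods.extend(self.down)
        mods.extend(self.down_norm)
        for i in range(len(self.up)):
            mods.extend([self.up[i], self.up_norm[i]])
            if self.merge[i] is not None:
                mods.extend([self.merge[i], self.merge_norm[i]])
            mods.extend(self.dec_res[i])
        mods.append(self.head)
        for m in mods:
            params.extend(m.parameters() if isinstance(m, nn.Module) else [])
        return params

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        h, w = x.shape[2], x.shape[3]
        div = 2 ** (self.spec.levels - 1)
        if h % div or w % div:
            raise ValueError(
                f"slice size {h}x{w} not divisible by 2^(levels-1) = {div}")
        feat = nn.relu(self.stem_norm(self.stem(x)))
        for blk in self.enc_res[0]:
            feat = blk(feat)
        skips = [feat]
        for lv in range(1, self.spec.levels):
            feat = nn.relu(self.down_norm[lv - 1](self.down[lv - 1](feat)))
            for blk in self.enc_res[lv]:
                feat = blk(feat)
            skips.append(feat)
        for i, lv in enumerate(range(self.spec.levels - 1, 0, -1)):
            feat = nn.upsample2(feat)
            feat = nn.relu(self.up_norm[i](self.up[i](feat)))
            if self.merge[i] is not None:
                feat = nn.concat(feat, skips[lv - 1])
                feat = nn.relu(self.merge_norm[i](self.merge[i](feat)))
            for blk in self.dec_res[i]:
                feat = blk(feat)
        return nn.hard_tanh(x + self.head(feat))


class PatchDiscriminator(nn.Module):
    def __init__(self, spec: DiscriminatorSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.convs, self.norms = [], []
        c_in = 1
        for i in range(spec.n_layers):
            c_out = spec.base_channels * 2 ** i
            stride = 2 if i < spec.n_layers - 1 else 1
            self.convs.append(nn.Conv2d(c_in, c_out, spec.kernel,
                                        stride=stride, pad=1, rng=rng))
            self.norms.append(nn.InstanceNorm2d(c_out) if i > 0 else None)
            c_in = c_out
        self.head = nn.Conv2d(c_in, 1, spec.kernel, stride=1, pad=1, rng=rng)

    def parameters(self):
        params = []
        for conv, norm in zip(self.convs, self.norms):
            params.extend(conv.parameters())
            if norm is not None:
                params.extend(norm.parameters())
        params.extend(self.head.parameters())
        return params

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        self.spec.score_map_shape(x.shape[2], x.shape[3])  # validates size
        h = x
        for conv, norm in zip(self.convs, self.norms):
            h = conv(h)
            if norm is not None:
                h = norm(h)
            h = nn.leaky_relu(h, 0.2)
        return self.head(h)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 40
    constant_lr_epochs: int = 20
    base_lr: float = 2e-4
    batch_size: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.constant_lr_epochs > self.epochs:
            raise ValueError("constant_lr_epochs cannot exceed epochs")
        if self.base_lr < 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("invalid training configuration")


def lr_at_epoch(e: int, cfg: TrainConfig = TrainConfig()) -> float:
    """Learning rate at 1-based epoch ``e``: constant at ``base_lr`` through
    ``constant_lr_epochs``, then linear to exactly 0 at the final epoch."""
    if not (1 <= e <= cfg.epochs):
        raise ValueError(f"epoch {e} outside 1..{cfg.epochs}")
    if e <= cfg.constant_lr_epochs or cfg.epochs == cfg.constant_lr_epochs:
        return cfg.base_lr
    return cfg.base_lr * (cfg.epochs - e) / (cfg.epochs - cfg.constant_lr_epochs)


@dataclass
class TrainHistory:
    """Per-epoch mean losses (both generators combined) and LR."""

    epochs: list[int] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    gen: list[LossBreakdown] = field(default_factory=list)
    disc_ct: list[float] = field(default_factory=list)
    disc_cbct: list[float] = field(default_factory=list)


@dataclass
class ModelState:
    """Trained weights plus the specs needed to rebuild the networks."""

    gen_spec: GeneratorSpec
    pre_spec: PreprocessSpec
    g_cbct2ct: list[np.ndarray]
    g_ct2cbct: list[np.ndarray]


def _slice_pairs(samples, pre_spec: PreprocessSpec):
    xs, ys = [], []
    for s in samples:
        x_slices, _ = preprocess(s.cbct, pre_spec)
        y_slices, _ = preprocess(s.registered_ct, pre_spec)
        xs.append(x_slices)
        ys.append(y_slices)
    return np.concatenate(xs, axis=0), np.concatenate(ys, axis=0)


def _batch_weights(x: np.ndarray, y: np.ndarray, cfg: LossConfig) -> np.ndarray:
    """Thresholded SSIM weight maps for a (B, 1, H, W) batch (constants)."""
    w = np.empty_like(x)
    for i in range(x.shape[0]):
        w[i, 0] = ssim_weight_map(local_ssim_map(x[i, 0], y[i, 0], cfg), cfg.alpha)
    return w


def _check_finite(value: float, term: str):
    if not np.isfinite(value):
        raise FloatingPointError(f"non-finite loss in term {term!r}")


def train(samples, gen_spec: GeneratorSpec, disc_spec: DiscriminatorSpec,
          loss_cfg: LossConfig = LossConfig(),
          train_cfg: TrainConfig = TrainConfig(),
          pre_spec: PreprocessSpec = PreprocessSpec(),
          ) -> tuple[ModelState, TrainHistory]:
    """Train both translation directions on paired slices.

    Per batch: discriminators first (least-squares GAN on detached fakes),
    then one joint Adam step over both generators with the weighted sum of
    adversarial, cycle and SSIM-weighted L1 terms.  Fully seeded: model
    initialisation uses ``train_cfg.seed`` + fixed offsets, the batch
    order a separate stream, so repeated runs are bitwise identical.
    """
    if not samples:
        raise ValueError("at least one paired sample is required")
    xs, ys = _slice_pairs(samples, pre_spec)
    n = len(xs)
    seed = train_cfg.seed
    g = ResUnetGenerator(gen_spec, seed=seed)
    f = ResUnetGenerator(gen_spec, seed=seed + 1)
    d_ct = PatchDiscriminator(disc_spec, seed=seed + 2)
    d_cbct = PatchDiscriminator(disc_spec, seed=seed + 3)
    shuffle_rng = np.random.default_rng(seed + 4)
    use_adv = loss_cfg.lambda_adv > 0
    use_ssim = loss_cfg.lambda_ssim > 0

    opt_g = nn.Adam(g.parameters() + f.parameters(), lr=train_cfg.base_lr)
    opt_d = nn.Adam(d_ct.parameters() + d_cbct.parameters(), lr=train_cfg.base_lr) \
        if use_adv else None

    history = TrainHistory()
    for epoch in range(1, train_cfg.epochs + 1):
        lr = lr_at_epoch(epoch, train_cfg)
        opt_g.lr = lr
        if opt_d is not None:
            opt_d.lr = lr
        order = shuffle_rng.permutation(n)
        parts = {"ssim": [], "cycle": [], "adv": [], "d_ct": [], "d_cbct": []}
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            xb = xs[idx][:, None].astype(np.float32)
            yb = ys[idx][:, None].astype(np.float32)
            x_t, y_t = nn.Tensor(xb), nn.Tensor(yb)
            fake_y = g(x_t)
            fake_x = f(y_t)
            if use_adv:
                # discriminator step on detached fakes
                opt_d.zero_grad()
                _, dct_loss = _disc_losses(d_ct, y_t, fake_y.data)
                _, dcb_loss = _disc_losses(d_cbct, x_t, fake_x.data)
                (dct_loss + dcb_loss).backward()
                opt_d.step()
                parts["d_ct"].append(float(dct_loss.data))
                parts["d_cbct"].append(float(dcb_loss.data))
                adv = (nn.mean_square_diff(d_ct(fake_y), 1.0)
                       + nn.mean_square_diff(d_cbct(fake_x), 1.0))
            else:
                adv = nn.Tensor(0.0)
                parts["d_ct"].append(0.0)
                parts["d_cbct"].append(0.0)
            cyc = nn.mean_abs(f(fake_y), x_t) + nn.mean_abs(g(fake_x), y_t)
            if use_ssim:
                w_xy = _batch_weights(xb, yb, loss_cfg)
                w_yx = _batch_weights(yb, xb, loss_cfg)
                sw = (nn.mean_abs(fake_y, y_t, weight=w_xy)
                      + nn.mean_abs(fake_x, x_t, weight=w_yx))
            else:
                sw = nn.Tensor(0.0)
            for term, name in ((sw, "ssim_weighted_l1"), (cyc, "cycle"),
                               (adv, "adversarial")):
                _check_finite(float(term.data), name)
            total = (loss_cfg.lambda_ssim * sw + loss_cfg.lambda_cycle * cyc
                     + loss_cfg.lambda_adv * adv)
            opt_g.zero_grad()
            total.backward()
            opt_g.step()
            parts["ssim"].append(float(sw.data))
            parts["cycle"].append(float(cyc.data))
            parts["adv"].append(float(adv.data))
        history.epochs.append(epoch)
        history.lr.append(lr)
        history.gen.append(total_generator_loss(
            float(np.mean(parts["ssim"])), float(np.mean(parts["cycle"])),
            float(np.mean(parts["adv"])), loss_cfg))
        history.disc_ct.append(float(np.mean(parts["d_ct"])))
        history.disc_cbct.append(float(np.mean(parts["d_cbct"])))

    state = ModelState(gen_spec, pre_spec, g.state_arrays(), f.state_arrays())
    return state, history


def _disc_losses(disc: PatchDiscriminator, real: nn.Tensor, fake_data: np.ndarray):
    d_real = disc(real)
    d_fake = disc(nn.Tensor(fake_data))
    loss = nn.mean_square_diff(d_real, 1.0) + nn.mean_square_diff(d_fake, 0.0)
    return (d_real, loss)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def infer(cbct: ImageVolume, state: ModelState, batch: int = 8) -> ImageVolume:
    """Translate a CBCT volume to a synthetic CT.

    Preprocess → slice-wise generator → postprocess; deterministic, output
    geometry equals input geometry, HU bounded to the normalisation window
    by the generator's saturating output activation.
    """
    g = ResUnetGenerator(state.gen_spec, seed=0)
    g.load_state_arrays(state.g_cbct2ct)
    slices, rec = preprocess(cbct, state.pre_spec)
    out = np.empty_like(slices)
    for start in range(0, len(slices), batch):
        xb = slices[start:start + batch][:, None].astype(np.float32)
        out[start:start + batch] = g(nn.Tensor(xb)).data[:, 0].astype(np.float64)
    return postprocess(out, rec)
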