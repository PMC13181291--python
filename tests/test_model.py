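"""Model-layer tests: pre/post-processing, network contracts, LR schedule,
training determinism and the pure-cycle reduction."""

import numpy as np
import pytest

from sctkit import nn
from sctkit.core import ImageVolume
from sctkit.losses import LossConfig
from sctkit.model import (DiscriminatorSpec, GeneratorSpec, ModelState,
                          PatchDiscriminator, PreprocessSpec, ResUnetGenerator,
                          TrainConfig, infer, lr_at_epoch, postprocess,
                          preprocess, train)
from sctkit.phantom import PhantomSpec, make_paired_sample

TOY_GEN = GeneratorSpec(levels=2, long_skip_levels=1, base_channels=8)
TOY_DISC = DiscriminatorSpec(n_layers=3, base_channels=8)
TOY_PRE = PreprocessSpec(target_size=32, target_pixel_mm=3.0)


class TestPreprocess:
    def test_hu_window_endpoints(self):
        from sctkit.model import hu_to_unit
        spec = PreprocessSpec()
        assert hu_to_unit(-1000.0, spec) == -1.0
        assert hu_to_unit(2000.0, spec) == 1.0
        assert hu_to_unit(500.0, spec) == 0.0
        assert hu_to_unit(3000.0, spec) == 1.0  # clipped then mapped

    def test_same_grid_round_trip_is_clip(self, rng):
        vox = rng.uniform(-1024, 3071, size=(4, 32, 32))
        vol = ImageVolume(vox, (3.0, 3.0, 3.0))
        slices, rec = preprocess(vol, TOY_PRE)
        assert not rec.resampled
        back = postprocess(slices, rec)
        np.testing.assert_allclose(back.voxels, np.clip(vox, -1000, 2000),
                                   atol=1e-9)

    def test_resampling_round_trip_tolerance(self, rng):
        from scipy.ndimage import map_coordinates
        vox = np.clip(200 * rng.standard_normal((4, 24, 24)).cumsum(axis=2),
                      -1000, 2000)
        vol = ImageVolume(vox, (3.0, 2.0, 2.0))
        spec = PreprocessSpec(target_size=32, target_pixel_mm=1.5)
        slices, rec = preprocess(vol, spec)
        assert rec.resampled
        back = postprocess(slices, rec)
        # oracle: two successive centre-aligned linear resamples of the input
        def resample(plane, src_sp, dst_sp, dst_n, cval):
            src_n = plane.shape[0]
            t = (np.arange(dst_n) - (dst_n - 1) / 2) * dst_sp
            i = (src_n - 1) / 2 + t / src_sp
            gy, gx = np.meshgrid(i, i, indexing="ij")
            return map_coordinates(plane, [gy, gx], order=1,
                                   mode="constant" if cval is not None else "nearest",
                                   cval=cval if cval is not None else 0.0)
        oracle = np.empty_like(vox)
        for k in range(4):
            up = resample(vox[k], 2.0, 1.5, 32, cval=-1000.0)
            oracle[k] = resample(up, 1.5, 2.0, 24, cval=None)
        np.testing.assert_allclose(back.voxels, np.clip(oracle, -1000, 2000),
                                   atol=1e-6)

    def test_all_minus_one_slices(self):
        rec_src = ImageVolume(np.zeros((3, 32, 32)), (3.0, 3.0, 3.0))
        _, rec = preprocess(rec_src, TOY_PRE)
        out = postprocess(-np.ones((3, 32, 32)), rec)
        assert np.all(out.voxels == -1000.0)

    def test_stack_mismatch_raises(self):
        vol = ImageVolume(np.zeros((3, 32, 32)), (3.0, 3.0, 3.0))
        _, rec = preprocess(vol, TOY_PRE)
        with pytest.raises(ValueError):
            postprocess(np.zeros((2, 32, 32)), rec)


class TestGenerator:
    def test_output_shape_and_range(self, rng):
        g = ResUnetGenerator(TOY_GEN, seed=0)
        x = nn.Tensor(rng.uniform(-1, 1, size=(2, 1, 32, 32)))
        out = g(x)
        assert out.shape == (2, 1, 32, 32)
        assert out.data.min() >= -1.0 and out.data.max() <= 1.0

    def test_parameter_count_closed_form(self):
        def conv_p(ci, co, k=3):
            return ci * co * k * k + co

        def norm_p(c):
            return 2 * c

        def res_p(c):
            return 2 * (conv_p(c, c) + norm_p(c))

        expected = (
            conv_p(1, 8) + norm_p(8) + res_p(8)          # stem level
            + conv_p(8, 16) + norm_p(16) + res_p(16)     # down level
            + conv_p(16, 8) + norm_p(8)                  # up
            + conv_p(16, 8) + norm_p(8)                  # long-skip merge
            + res_p(8)                                   # decoder residual
            + conv_p(8, 1)                               # head
        )
        assert ResUnetGenerator(TOY_GEN, seed=0).n_parameters() == expected

    def test_same_seed_identical_builds(self):
        a = ResUnetGenerator(TOY_GEN, seed=3).state_arrays()
        b = ResUnetGenerator(TOY_GEN, seed=3).state_arrays()
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_indivisible_size_raises(self, rng):
        g = ResUnetGenerator(GeneratorSpec(levels=3, long_skip_levels=2,
                                           base_channels=4), seed=0)
        with pytest.raises(ValueError):
            g(nn.Tensor(rng.uniform(-1, 1, size=(1, 1, 30, 30))))


class TestDiscriminator:
    def test_reference_stride_arithmetic(self):
        # the canonical 4-layer patch discriminator maps 256x256 to 30x30
        assert DiscriminatorSpec().score_map_shape(256, 256) == (30, 30)

    def test_forward_shape_matches_arithmetic(self, rng):
        d = PatchDiscriminator(TOY_DISC, seed=0)
        out = d(nn.Tensor(rng.uniform(-1, 1, size=(1, 1, 64, 64))))
        assert out.shape[2:] == TOY_DISC.score_map_shape(64, 64)

    def test_zero_weights_constant_map(self, rng):
        d = PatchDiscriminator(TOY_DISC, seed=0)
        for p in d.parameters():
            p.data = np.zeros_like(p.data)
        out = d(nn.Tensor(rng.uniform(-1, 1, size=(1, 1, 32, 32)))).data
        assert np.all(out == out.flat[0])

    def test_too_small_input_raises(self, rng):
        d = PatchDiscriminator(DiscriminatorSpec(n_layers=4, base_channels=4),
                               seed=0)
        with pytest.raises(ValueError):
            d(nn.Tensor(rng.uniform(-1, 1, size=(1, 1, 8, 8))))


class TestLRSchedule:
    def test_reference_points(self):
        cfg = TrainConfig()
        assert lr_at_epoch(10, cfg) == 0.0002
        assert lr_at_epoch(20, cfg) == 0.0002
        assert lr_at_epoch(30, cfg) == 0.0001
        assert lr_at_epoch(40, cfg) == 0.0

    def test_nonincreasing_and_continuous(self):
        cfg = TrainConfig()
        lrs = [lr_at_epoch(e, cfg) for e in range(1, 41)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))
        # one linear step past the breakpoint
        assert abs(lrs[20] - lrs[19]) <= cfg.base_lr / 20 + 1e-15

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            lr_at_epoch(0, TrainConfig())
        with pytest.raises(ValueError):
            lr_at_epoch(41, TrainConfig())


def _tiny_samples(n=1):
    spec = PhantomSpec(shape=(8, 32, 32))
    return [make_paired_sample(spec, 50 + i, include_dose=False) for i in range(n)]


class TestTraining:
    def test_bitwise_deterministic(self):
        samples = _tiny_samples()
        cfg = TrainConfig(epochs=2, constant_lr_epochs=1, batch_size=4, seed=0)
        s1, h1 = train(samples, TOY_GEN, TOY_DISC, LossConfig(), cfg, TOY_PRE)
        s2, h2 = train(samples, TOY_GEN, TOY_DISC, LossConfig(), cfg, TOY_PRE)
        for b1, b2 in zip(h1.gen, h2.gen):
            assert b1.total == b2.total
        assert h1.disc_ct == h2.disc_ct
        assert all(np.array_equal(a, b)
                   for a, b in zip(s1.g_cbct2ct, s2.g_cbct2ct))

    def test_reduces_to_pure_cycle_loop(self):
        """With the SSIM and adversarial weights at zero, one epoch of the
        full loop must match an independently coded cycle-only loop."""
        samples = _tiny_samples()
        loss_cfg = LossConfig(lambda_ssim=0.0, lambda_adv=0.0, lambda_cycle=10.0)
        cfg = TrainConfig(epochs=1, constant_lr_epochs=1, batch_size=4, seed=7)
        state, hist = train(samples, TOY_GEN, TOY_DISC, loss_cfg, cfg, TOY_PRE)

        # independent loop using only the public primitives
        xs, _ = preprocess(samples[0].cbct, TOY_PRE)
        ys, _ = preprocess(samples[0].registered_ct, TOY_PRE)
        g = ResUnetGenerator(TOY_GEN, seed=7)
        f = ResUnetGenerator(TOY_GEN, seed=8)
        shuffle = np.random.default_rng(7 + 4)
        opt = nn.Adam(g.parameters() + f.parameters(), lr=cfg.base_lr)
        order = shuffle.permutation(len(xs))
        cyc_vals = []
        for start in range(0, len(xs), 4):
            idx = order[start:start + 4]
            x_t = nn.Tensor(xs[idx][:, None].astype(np.float32))
            y_t = nn.Tensor(ys[idx][:, None].astype(np.float32))
            cyc = nn.mean_abs(f(g(x_t)), x_t) + nn.mean_abs(g(f(y_t)), y_t)
            total = 10.0 * cyc
            opt.zero_grad()
            total.backward()
            opt.step()
            cyc_vals.append(float(cyc.data))
        np.testing.assert_allclose(hist.gen[0].cycle, np.mean(cyc_vals),
                                   rtol=1e-6)
        for a, b in zip(state.g_cbct2ct, g.state_arrays()):
            np.testing.assert_allclose(a, b, atol=1e-7)

    def test_empty_sample_list_raises(self):
        with pytest.raises(ValueError):
            train([], TOY_GEN, TOY_DISC)


class TestInfer:
    def _identity_state(self):
        g = ResUnetGenerator(TOY_GEN, seed=0)
        arrays = g.state_arrays()
        g.head.w.data = np.zeros_like(g.head.w.data)
        g.head.b.data = np.zeros_like(g.head.b.data)
        return ModelState(TOY_GEN, TOY_PRE, g.state_arrays(),
                          ResUnetGenerator(TOY_GEN, seed=1).state_arrays())

    def test_identity_generator_round_trip(self, rng):
        vox = rng.uniform(-1024, 3071, size=(4, 32, 32))
        cbct = ImageVolume(vox, (3.0, 3.0, 3.0))
        sct = infer(cbct, self._identity_state())
        np.testing.assert_allclose(sct.voxels, np.clip(vox, -1000, 2000),
                                   atol=0.01)  # float32 network pass

    def test_repeated_calls_identical(self, rng):
        cbct = ImageVolume(rng.uniform(-500, 500, size=(3, 32, 32)),
                           (3.0, 3.0, 3.0))
        state = self._identity_state()
        a = infer(cbct, state)
        b = infer(cbct, state)
        np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_output_range_bounded(self, rng):
        cbct = ImageVolume(rng.uniform(-1024, 3071, size=(3, 32, 32)),
                           (3.0, 3.0, 3.0))
        state = ModelState(TOY_GEN, TOY_PRE,
                           ResUnetGenerator(TOY_GEN, seed=9).state_arrays(),
                           ResUnetGenerator(TOY_GEN, seed=10).state_arrays())
        sct = infer(cbct, state)
        assert sct.voxels.min() >= -1000.0 and sct.voxels.max() <= 2000.0
        assert sct.shape == cbct.shape and sct.spacing == cbct.spacing

    def test_translation_consistency(self, rng):
        plane = rng.uniform(-500, 500, size=(32, 32))
        cbct = ImageVolume(np.stack([plane] * 4), (3.0, 3.0, 3.0))
        sct = infer(cbct, self._identity_state())
        for k in range(1, 4):
            np.testing.assert_array_equal(sct.voxels[k], sct.voxels[0])
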