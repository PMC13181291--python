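"""Tests of the digital pelvis phantom generators."""

import numpy as np
import pytest

from sctkit.contour_eval import dice
from sctkit.core import ImageVolume
from sctkit.hu_eval import REDCurve
from sctkit.phantom import (BeamSpec, PhantomSpec, StructureDef, cupping_field,
                            degrade_to_cbct, displacement_field, make_dose,
                            make_paired_sample, make_phantom_ct,
                            make_registered_ct, perturb_contour)


class TestMakePhantomCT:
    def test_deterministic(self, small_spec):
        ct1, ss1 = make_phantom_ct(small_spec, 3)
        ct2, ss2 = make_phantom_ct(small_spec, 3)
        np.testing.assert_array_equal(ct1.voxels, ct2.voxels)
        for name in ss1.names():
            np.testing.assert_array_equal(ss1[name], ss2[name])

    def test_zero_sigma_paints_constant(self):
        spec = PhantomSpec(shape=(8, 32, 32), structures=(
            StructureDef("body", (12, 48, 48), (60, 40, 40), 20, 0, 0),
            StructureDef("femur", (12, 48, 30), (20, 10, 8), 500, 0, 1),
        ), mismatch_structure=None)
        ct, ss = make_phantom_ct(spec, 0)
        assert np.all(ct.voxels[ss["femur"]] == 500.0)

    def test_sample_means_match_configured(self):
        spec = PhantomSpec(shape=(16, 64, 64), structures=(
            StructureDef("body", (24, 96, 96), (120, 80, 80), 20, 15, 0),
            StructureDef("insert", (24, 70, 96), (20, 15, 15), 300, 40, 1),
        ), mismatch_structure=None)
        ct, ss = make_phantom_ct(spec, 11)
        # insert voxels: mean over the mask within 3 sigma / sqrt(n)
        m = ss["insert"]
        n = m.sum()
        assert abs(ct.voxels[m].mean() - 300) < 3 * 40 / np.sqrt(n)
        body_only = ss["body"] & ~m
        assert abs(ct.voxels[body_only].mean() - 20) < 3 * 15 / np.sqrt(body_only.sum())

    def test_equal_priority_overlap_raises(self):
        spec = PhantomSpec(shape=(8, 16, 16), spacing=(3, 3, 3), structures=(
            StructureDef("a", (12, 24, 24), (10, 10, 10), 0, 0, 1),
            StructureDef("b", (12, 24, 30), (10, 10, 10), 100, 0, 1),
        ), mismatch_structure=None)
        with pytest.raises(ValueError, match="'a' and 'b'"):
            make_phantom_ct(spec, 0)

    def test_organ_masks_inside_body(self, small_spec):
        _, ss = make_phantom_ct(small_spec, 5)
        body = ss["body"]
        for name in ss.names():
            assert not np.any(ss[name] & ~body) or name == "body"


class TestDegradeToCBCT:
    def test_zero_strengths_identity(self, small_spec):
        clean = PhantomSpec(shape=small_spec.shape, cupping_amplitude_hu=0,
                            noise_sigma_hu=0, streak_count=0, global_shift_hu=0)
        ct, _ = make_phantom_ct(clean, 2)
        out = degrade_to_cbct(ct, clean, 9)
        np.testing.assert_array_equal(out.voxels, ct.voxels)

    def test_cupping_matches_closed_form(self):
        spec = PhantomSpec(shape=(4, 16, 16), cupping_amplitude_hu=40,
                           noise_sigma_hu=0, streak_count=0, global_shift_hu=0)
        ct = ImageVolume(np.zeros(spec.shape), spec.spacing)
        out = degrade_to_cbct(ct, spec, 0)
        # independent closed form: -A * (1 - r^2 / r_max^2) in-plane
        cy = (np.arange(16) - 7.5) * 3.0
        yy, xx = np.meshgrid(cy, cy, indexing="ij")
        r2 = yy ** 2 + xx ** 2
        expected = -40.0 * (1.0 - r2 / r2.max())
        for k in range(4):
            np.testing.assert_allclose(out.voxels[k], expected, atol=1e-9)

    @pytest.mark.parametrize("knob,levels", [
        ("noise_sigma_hu", (0, 20, 40)),
        ("cupping_amplitude_hu", (0, 30, 60)),
        ("global_shift_hu", (0, 25, 50)),
        ("streak_count", (0, 3, 6)),
    ])
    def test_mae_nondecreasing_in_strength(self, knob, levels):
        base = dict(shape=(6, 24, 24), cupping_amplitude_hu=0, noise_sigma_hu=0,
                    streak_count=0, global_shift_hu=0)
        maes = []
        for level in levels:
            spec = PhantomSpec(**{**base, knob: level})
            vals = []
            for seed in range(5):
                ct, _ = make_phantom_ct(spec, seed)
                cbct = degrade_to_cbct(ct, spec, 100 + seed)
                vals.append(np.abs(cbct.voxels - ct.voxels).mean())
            maes.append(np.mean(vals))
        assert all(a <= b + 1e-12 for a, b in zip(maes, maes[1:]))

    def test_noise_mae_strictly_increasing(self):
        base = dict(shape=(6, 24, 24), cupping_amplitude_hu=0, streak_count=0,
                    global_shift_hu=0)
        maes = []
        for sigma in (0, 20, 40):
            spec = PhantomSpec(**{**base, "noise_sigma_hu": sigma})
            vals = []
            for seed in range(10):
                ct, _ = make_phantom_ct(spec, seed)
                vals.append(np.abs(degrade_to_cbct(ct, spec, 50 + seed).voxels
                                   - ct.voxels).mean())
            maes.append(np.mean(vals))
        assert maes[0] < maes[1] < maes[2]


class TestMakeRegisteredCT:
    def test_zero_displacement_no_mismatch_is_identity(self):
        spec = PhantomSpec(shape=(8, 32, 32), max_displacement_mm=0,
                           mismatch_structure=None)
        ct, ss = make_phantom_ct(spec, 4)
        reg, mask = make_registered_ct(ct, ss, spec, 0)
        np.testing.assert_array_equal(reg.voxels, ct.voxels)
        assert not mask.any()

    def test_mismatch_region_replaced(self, small_spec):
        ct, ss = make_phantom_ct(small_spec, 6)
        reg, mask = make_registered_ct(ct, ss, small_spec, 1)
        np.testing.assert_array_equal(mask, ss["rectum_gas"])
        inside = np.abs(reg.voxels - ct.voxels)[mask].mean()
        assert inside > 500  # gas (~ -950 HU) replaced by soft tissue
        outside = np.abs(reg.voxels - ct.voxels)[ss["body"] & ~mask]
        assert np.median(outside) < 100  # bounded by deformation smoothness

    def test_displacement_bounded(self, small_spec):
        field = displacement_field(small_spec, 42)
        norms = np.sqrt((field ** 2).sum(axis=0))
        assert norms.max() <= small_spec.max_displacement_mm + 1e-9

    def test_mismatch_with_zero_bound_raises(self):
        spec = PhantomSpec(shape=(8, 32, 32), max_displacement_mm=0)
        ct, ss = make_phantom_ct(spec, 0)
        with pytest.raises(ValueError):
            make_registered_ct(ct, ss, spec, 0)


class TestMakeDose:
    def test_central_axis_attenuation(self):
        spec = PhantomSpec(shape=(4, 32, 32), beams=(
            BeamSpec(gantry_angle_deg=0.0, sigma_mm=1e6, entrance_dose_gy=2.0,
                     mu_per_mm=0.005),), dose_step_mm=0.5)
        ct = ImageVolume(np.zeros(spec.shape), spec.spacing)  # water: rED = 1
        dose = make_dose(ct, spec)
        # depth along +y from the entry face (voxel-centre y = 0)
        for iy in (0, 8, 16, 31):
            depth = iy * 3.0
            expected = 2.0 * np.exp(-0.005 * depth)
            got = dose.dose[2, iy, 16]
            assert abs(got - expected) / expected < 0.005  # ray-march step tol

    def test_zero_entrance_dose(self):
        spec = PhantomSpec(shape=(4, 16, 16),
                           beams=(BeamSpec(entrance_dose_gy=0.0),))
        ct = ImageVolume(np.zeros(spec.shape), spec.spacing)
        assert np.all(make_dose(ct, spec).dose == 0.0)

    def test_opposed_beams_symmetric(self):
        spec = PhantomSpec(shape=(4, 32, 32), beams=(
            BeamSpec(gantry_angle_deg=0.0), BeamSpec(gantry_angle_deg=180.0)))
        vox = np.zeros(spec.shape)
        vox[:, 8:24, 8:24] = 40.0  # mirror-symmetric insert
        ct = ImageVolume(vox, spec.spacing)
        dose = make_dose(ct, spec).dose
        np.testing.assert_allclose(dose, dose[:, ::-1, :], atol=1e-9)

    def test_linear_in_entrance_dose(self):
        spec1 = PhantomSpec(shape=(4, 16, 16),
                            beams=(BeamSpec(entrance_dose_gy=1.0),))
        spec3 = PhantomSpec(shape=(4, 16, 16),
                            beams=(BeamSpec(entrance_dose_gy=3.0),))
        ct, _ = make_phantom_ct(PhantomSpec(shape=(4, 16, 16)), 0)
        d1 = make_dose(ct, spec1).dose
        d3 = make_dose(ct, spec3).dose
        np.testing.assert_allclose(d3, 3.0 * d1, rtol=1e-12, atol=1e-12)

    def test_axis_missing_grid_raises(self):
        # a z-parallel axis displaced outside the box must be rejected
        from sctkit.phantom import _check_axis_hits_grid
        with pytest.raises(ValueError):
            _check_axis_hits_grid(np.array([0.0, -50.0, 0.0]),
                                  np.array([1.0, 0.0, 0.0]),
                                  np.zeros(3), np.array([9.0, 45.0, 45.0]))


class TestPerturbContour:
    @pytest.mark.parametrize("mode", ["dilate", "erode", "boundary_noise", "shift"])
    def test_zero_magnitude_identity(self, mode, rng):
        mask = rng.uniform(size=(8, 8, 8)) > 0.6
        np.testing.assert_array_equal(perturb_contour(mask, mode, 0, seed=1), mask)

    def test_dilated_cube_dice(self):
        mask = np.zeros((16, 16, 16), dtype=bool)
        mask[3:13, 3:13, 3:13] = True  # 10^3 cube
        big = perturb_contour(mask, "dilate", 1)
        assert big.sum() == 12 ** 3  # one voxel added in every direction
        np.testing.assert_allclose(dice(mask, big),
                                   2 * 1000 / (1000 + 1728), rtol=1e-12)

    def test_erode_shrinks(self, rng):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[2:8, 2:8, 2:8] = True
        assert perturb_contour(mask, "erode", 1).sum() < mask.sum()

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError):
            perturb_contour(np.ones((3, 3, 3), dtype=bool), "inflate", 1)

    def test_deterministic(self, rng):
        mask = rng.uniform(size=(8, 8, 8)) > 0.5
        a = perturb_contour(mask, "boundary_noise", 0.4, seed=5)
        b = perturb_contour(mask, "boundary_noise", 0.4, seed=5)
        np.testing.assert_array_equal(a, b)


def test_paired_sample_consistency(paired_sample):
    s = paired_sample
    assert s.ct.shape == s.cbct.shape == s.registered_ct.shape
    assert s.mismatch_mask.shape == s.ct.shape
    body = s.structures["body"]
    assert not np.any(s.mismatch_mask & ~body)
    assert s.ref_dose.dose.max() > 0
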