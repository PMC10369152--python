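import numpy as np
import pytest

from fdopa import (KineticParameters, PhantomSpec, build_phantom,
                   extract_tac, patlak_consistent_tac, patlak_fit,
                   patlak_transform, suvr)
from fdopa.denoise import TVConfig
from fdopa.kinetics import patlak_region, patlak_voxelwise
from fdopa.pet_io import DynamicImage, FrameSchedule, LabelVolume, \
    TimeActivityCurve
from fdopa.phantom import FengInput, default_schedule, simulate_tissue_tac


def reference_tac():
    sched = default_schedule()
    return simulate_tissue_tac(KineticParameters(K1=0.1, k2=0.1),
                               FengInput(1.0, 100.0), sched), sched


class TestPatlakTransform:
    def test_target_equal_reference_gives_unit_ratio(self):
        ref, _ = reference_tac()
        pts = patlak_transform(ref, ref)
        assert np.allclose(pts.y, 1.0)

    def test_constant_reference_x_approaches_time(self):
        mid = np.linspace(1, 90, 30)
        ref = TimeActivityCurve(mid=mid, value=np.full(30, 5.0))
        pts = patlak_transform(ref, ref)
        # with the implicit (0,0) anchor, x(t) = t - mid[0]/2 -> t
        assert np.allclose(pts.x, mid - mid[0] / 2.0)
        assert pts.x[-1] / mid[-1] == pytest.approx(1.0, abs=0.01)

    def test_three_point_hand_computed_oracle(self):
        # trapezoid from (0,0): I = [1, 4, 12]; x = I/ref; y = target/ref
        ref = TimeActivityCurve(mid=[1.0, 2.0, 4.0], value=[2.0, 4.0, 4.0])
        tgt = TimeActivityCurve(mid=[1.0, 2.0, 4.0], value=[1.0, 2.0, 3.0])
        pts = patlak_transform(tgt, ref)
        assert np.allclose(pts.x, [0.5, 1.0, 3.0])
        assert np.allclose(pts.y, [0.5, 0.5, 0.75])

    def test_nonpositive_reference_points_dropped(self):
        ref = TimeActivityCurve(mid=[1.0, 2.0, 3.0], value=[0.0, 4.0, 4.0])
        tgt = TimeActivityCurve(mid=[1.0, 2.0, 3.0], value=[1.0, 2.0, 3.0])
        pts = patlak_transform(tgt, ref)
        assert pts.n_dropped == 1 and len(pts.x) == 2

    def test_mismatched_mid_times_rejected(self):
        a = TimeActivityCurve(mid=[1.0, 2.0], value=[1.0, 1.0])
        b = TimeActivityCurve(mid=[1.0, 3.0], value=[1.0, 1.0])
        with pytest.raises(ValueError):
            patlak_transform(a, b)


class TestPatlakFit:
    def test_exact_recovery_of_constructed_tac(self):
        ref, _ = reference_tac()
        tgt = patlak_consistent_tac(ref, ki=0.0137, intercept=1.5)
        fit = patlak_fit(patlak_transform(tgt, ref), t_star=20.0)
        assert fit.ki == pytest.approx(0.0137, abs=1e-10)
        assert fit.intercept == pytest.approx(1.5, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_identical_curves_fit_slope_zero_intercept_one(self):
        ref, _ = reference_tac()
        fit = patlak_fit(patlak_transform(ref, ref))
        assert fit.ki == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)

    def test_requires_three_late_points(self):
        ref = TimeActivityCurve(mid=[1.0, 2.0, 25.0, 30.0],
                                value=[1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            patlak_fit(patlak_transform(ref, ref), t_star=20.0)

    def test_matches_normal_equations_oracle(self, rng):
        ref, _ = reference_tac()
        noisy = TimeActivityCurve(
            mid=ref.mid, value=ref.value * (1 + 0.05 * rng.standard_normal(
                len(ref))))
        pts = patlak_transform(noisy, ref)
        fit = patlak_fit(pts, t_star=20.0)
        late = pts.mid >= 20.0
        X = np.column_stack([pts.x[late], np.ones(late.sum())])
        beta = np.linalg.solve(X.T @ X, X.T @ pts.y[late])
        assert fit.ki == pytest.approx(beta[0], abs=1e-12)
        assert fit.intercept == pytest.approx(beta[1], abs=1e-12)

    def test_negative_slope_not_clipped(self):
        ref, _ = reference_tac()
        tgt = patlak_consistent_tac(ref, ki=-0.0009, intercept=1.0)
        fit = patlak_fit(patlak_transform(tgt, ref))
        assert fit.ki == pytest.approx(-0.0009, abs=1e-10)

    def test_monotone_in_trapping_rate(self):
        sched = default_schedule()
        plasma = FengInput(1.0, 100.0)
        ref = simulate_tissue_tac(KineticParameters(K1=0.1, k2=0.1),
                                  plasma, sched)
        slopes = []
        for k3 in (0.005, 0.01, 0.015, 0.02, 0.025):
            tgt = simulate_tissue_tac(KineticParameters(K1=0.13, k2=0.1,
                                                        k3=k3),
                                      plasma, sched)
            slopes.append(patlak_fit(patlak_transform(tgt, ref)).ki)
        assert np.all(np.diff(slopes) > 0)


class TestVoxelwise:
    def test_voxel_mean_matches_region_fit(self, noisy_phantom):
        img, labels, _ = noisy_phantom
        ref = extract_tac(img, labels, "cerebellum")
        region_fit = patlak_region(extract_tac(img, labels, "striatum"), ref)
        robust = float(np.percentile(img.data, 99.5))
        pmap = patlak_voxelwise(img, ref, labels.labels > 0,
                                tv=TVConfig(weight=0.02 * robust))
        vox_mean = np.nanmean(pmap.ki_map[labels.mask("striatum")])
        assert vox_mean == pytest.approx(region_fit.ki, rel=0.05)

    def test_background_region_near_zero(self, noisy_phantom):
        img, labels, _ = noisy_phantom
        ref = extract_tac(img, labels, "cerebellum")
        pmap = patlak_voxelwise(img, ref, labels.labels > 0, tv=None)
        bg = np.nanmean(pmap.ki_map[labels.mask("background")])
        assert abs(bg - 0.0005) < 0.001

    def test_zero_voxels_become_nan_without_crash(self, noiseless_phantom):
        img, labels, _ = noiseless_phantom
        ref = extract_tac(img, labels, "cerebellum")
        mask = np.zeros(img.shape3d, dtype=bool)
        mask[0, 0, 0] = True          # outside the head: all-zero series
        mask[16, 18, 13] = True
        pmap = patlak_voxelwise(img, ref, mask, tv=None)
        assert np.isnan(pmap.ki_map[0, 0, 0])

    def test_tv_weight_zero_matches_no_denoising(self, noiseless_phantom):
        img, labels, _ = noiseless_phantom
        ref = extract_tac(img, labels, "cerebellum")
        mask = labels.mask("striatum")
        a = patlak_voxelwise(img, ref, mask, tv=None)
        b = patlak_voxelwise(img, ref, mask, tv=TVConfig(weight=0.0))
        assert np.allclose(np.nan_to_num(a.ki_map), np.nan_to_num(b.ki_map),
                           atol=1e-6)

    def test_scale_invariance(self, noiseless_phantom):
        from dataclasses import replace
        img, labels, _ = noiseless_phantom
        scaled = replace(img, data=3.5 * img.data)
        for image in (img, scaled):
            ref = extract_tac(image, labels, "cerebellum")
            fit = patlak_region(extract_tac(image, labels, "striatum"), ref)
            sv = suvr(image, labels, "striatum", "cerebellum")
            if image is img:
                base = (fit.ki, fit.intercept, sv.suvr)
        assert fit.ki == pytest.approx(base[0], rel=1e-9)
        assert fit.intercept == pytest.approx(base[1], rel=1e-9)
        assert sv.suvr == pytest.approx(base[2], rel=1e-9)


class TestSuvr:
    def _image_with_ratio(self, ratio):
        sched = default_schedule()
        data = np.zeros((4, 4, 2, len(sched)))
        tac = np.linspace(1, 10, len(sched))
        data[0, 0, 0, :] = ratio * tac
        data[1, 0, 0, :] = tac
        labels = np.zeros((4, 4, 2), dtype=np.int16)
        labels[0, 0, 0], labels[1, 0, 0] = 1, 2
        img = DynamicImage(data=data, voxel_size=(2, 2, 2), schedule=sched)
        lab = LabelVolume(labels=labels, names={"target": 1, "ref": 2})
        return img, lab

    def test_equal_activity_gives_unity(self):
        img, lab = self._image_with_ratio(1.0)
        assert suvr(img, lab, "target", "ref").suvr == pytest.approx(1.0)

    def test_double_activity_gives_two(self):
        img, lab = self._image_with_ratio(2.0)
        assert suvr(img, lab, "target", "ref").suvr == pytest.approx(2.0)

    def test_window_weights_match_hand_computation(self, noiseless_phantom):
        # frames of the default schedule tile [60, 75] exactly (3 x 300 s)
        img, labels, _ = noiseless_phantom
        tac = extract_tac(img, labels, "striatum")
        sel = (img.schedule.start >= 60.0) & (img.schedule.end <= 75.0)
        expected = tac.value[sel].mean()
        from fdopa.kinetics import windowed_mean_activity
        got = windowed_mean_activity(tac, img.schedule, (60.0, 75.0))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_phantom_suvr_within_population_envelope(self, noiseless_phantom):
        img, labels, _ = noiseless_phantom
        sv = suvr(img, labels, "striatum", "cerebellum")
        assert 1.71 <= sv.suvr <= 3.11

    def test_window_outside_scan_rejected(self):
        img, lab = self._image_with_ratio(1.0)
        with pytest.raises(ValueError):
            suvr(img, lab, "target", "ref", window=(200.0, 210.0))
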