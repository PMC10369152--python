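import numpy as np
import pytest

from fdopa import (FengInput, KineticParameters, PhantomSpec, RigidTransform,
                   build_phantom, extract_tac, input_function, inject_motion,
                   patlak_consistent_tac, simulate_tissue_tac)
from fdopa.kinetics import integrate_tac_from_zero, patlak_region
from fdopa.phantom import default_schedule
from fdopa.pet_io import DynamicImage, FrameSchedule, TimeActivityCurve


class TestKineticParameters:
    def test_net_uptake_formula(self):
        p = KineticParameters(K1=0.13, k2=0.10, k3=0.02)
        assert p.ki_true == pytest.approx(0.13 * 0.02 / 0.12)

    def test_zero_trapping_means_zero_uptake(self):
        assert KineticParameters(K1=0.1, k2=0.1).ki_true == 0.0

    def test_for_net_uptake_round_trips(self):
        p = KineticParameters.for_net_uptake(0.0137)
        assert p.ki_true == pytest.approx(0.0137, rel=1e-12)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            KineticParameters(K1=-0.1, k2=0.1)


class TestInputFunction:
    def test_zero_scale_gives_zero_curve(self):
        model = FengInput(peak_time=1.0, scale=0.0)
        t = np.linspace(0, 95, 200)
        assert np.all(model(t) == 0)

    def test_zero_at_injection_and_nonnegative(self):
        model = FengInput(peak_time=1.0, scale=100.0)
        assert model(0.0) == 0.0
        t = np.linspace(0, 95, 2000)
        assert np.all(model(t) >= 0)

    def test_peak_occurs_at_configured_time(self):
        # dense-grid argmax oracle
        for peak in (0.5, 1.0, 2.0):
            model = FengInput(peak_time=peak, scale=50.0)
            t = np.linspace(0, 10, 100001)
            t_max = t[int(np.argmax(model(t)))]
            assert t_max == pytest.approx(peak, abs=1e-3)
            assert model(t).max() == pytest.approx(50.0, rel=1e-6)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            input_function(default_schedule(), scale=-1.0)


class TestSimulateTissueTac:
    def test_no_delivery_gives_zero_tac(self):
        plasma = FengInput(1.0, 100.0)
        tac = simulate_tissue_tac(KineticParameters(K1=0.0, k2=0.1, k3=0.01),
                                  plasma, default_schedule())
        assert np.all(tac.value == 0)

    def test_linear_in_plasma_scale(self):
        sched = default_schedule()
        p = KineticParameters(K1=0.1, k2=0.1, k3=0.02)
        t1 = simulate_tissue_tac(p, FengInput(1.0, 50.0), sched)
        t2 = simulate_tissue_tac(p, FengInput(1.0, 100.0), sched)
        assert np.allclose(t2.value, 2.0 * t1.value, rtol=1e-9)

    def test_constant_infusion_equilibrium_ratio_is_k1_over_k2(self):
        # closed-form step response: C1(t) = (K1/k2) Cp (1 - exp(-k2 t))
        sched = default_schedule()
        p = KineticParameters(K1=0.12, k2=0.2, k3=0.0)
        cp = 10.0
        tac = simulate_tissue_tac(p, lambda t: np.full_like(
            np.asarray(t, dtype=float), cp), sched)
        t_late = sched.mid[-1]
        expected = (p.K1 / p.k2) * cp * (1 - np.exp(-p.k2 * t_late))
        assert tac.value[-1] == pytest.approx(expected, rel=1e-4)

    def test_agrees_with_adaptive_ode_solver(self):
        # independent oracle: scipy adaptive integration
        from scipy.integrate import solve_ivp
        sched = default_schedule()
        p = KineticParameters(K1=0.13, k2=0.1, k3=0.019)
        plasma = FengInput(1.0, 100.0)
        mine = simulate_tissue_tac(p, plasma, sched)
        sol = solve_ivp(
            lambda t, y: [p.K1 * plasma(t) - (p.k2 + p.k3) * y[0],
                          p.k3 * y[0]],
            (0, 95), [0, 0], t_eval=sched.mid, rtol=1e-10, atol=1e-12,
            method="LSODA")
        expected = sol.y.sum(axis=0)
        assert np.abs(mine.value - expected).max() < 1e-4 * expected.max()


class TestPatlakConsistentTac:
    def _ref(self):
        sched = default_schedule()
        return simulate_tissue_tac(KineticParameters(K1=0.1, k2=0.1),
                                   FengInput(1.0, 100.0), sched)

    def test_zero_ki_scales_reference(self):
        ref = self._ref()
        out = patlak_consistent_tac(ref, ki=0.0, intercept=1.5)
        assert np.allclose(out.value, 1.5 * ref.value)

    def test_unit_intercept_zero_ki_is_identity(self):
        ref = self._ref()
        out = patlak_consistent_tac(ref, ki=0.0, intercept=1.0)
        assert np.allclose(out.value, ref.value)

    def test_construction_matches_integral_definition(self):
        ref = self._ref()
        out = patlak_consistent_tac(ref, ki=0.0137, intercept=1.5)
        expected = 1.5 * ref.value + 0.0137 * integrate_tac_from_zero(
            ref.mid, ref.value)
        assert np.allclose(out.value, expected, rtol=1e-14)


class TestBuildPhantom:
    def test_same_seed_is_bit_identical(self):
        spec = PhantomSpec(seed=5, noise_sigma0=1.0)
        img1, _, _ = build_phantom(spec)
        img2, _, _ = build_phantom(spec)
        assert np.array_equal(img1.data, img2.data)

    def test_different_seed_differs(self):
        img1, _, _ = build_phantom(PhantomSpec(seed=5, noise_sigma0=1.0))
        img2, _, _ = build_phantom(PhantomSpec(seed=6, noise_sigma0=1.0))
        assert not np.array_equal(img1.data, img2.data)

    def test_motion_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(seed=1, motion=[RigidTransform()])

    def test_striatal_patlak_slope_within_population_range(
            self, noiseless_phantom):
        img, labels, _ = noiseless_phantom
        ref = extract_tac(img, labels, "cerebellum")
        tar = extract_tac(img, labels, "striatum")
        fit = patlak_region(tar, ref)
        assert 0.0102 <= fit.ki <= 0.0246

    def test_ground_truth_predicts_all_regional_tacs(self, noiseless_phantom):
        img, labels, truth = noiseless_phantom
        plasma = FengInput(**truth["plasma"])
        for region, rec in truth["regions"].items():
            params = KineticParameters(**rec["params"])
            predicted = simulate_tissue_tac(params, plasma, img.schedule)
            measured = extract_tac(img, labels, region)
            assert np.allclose(measured.value, predicted.value, rtol=1e-9)


class TestInjectMotion:
    def test_identity_transforms_leave_image_unchanged(self, noiseless_phantom):
        img, _, _ = noiseless_phantom
        out = inject_motion(img, [RigidTransform()] * img.n_frames)
        assert np.array_equal(out.data, img.data)

    def test_integer_voxel_translation_is_exact_shift(self):
        img, _, _ = build_phantom(PhantomSpec(seed=2, shape=(16, 16, 12)))
        shift_mm = img.voxel_size[0]  # one voxel along x
        tr = [RigidTransform()] * img.n_frames
        tr[5] = RigidTransform(translation=(shift_mm, 0, 0))
        out = inject_motion(img, tr)
        assert np.allclose(out.data[1:, :, :, 5], img.data[:-1, :, :, 5],
                           atol=1e-10)

    def test_round_trip_within_interpolation_tolerance(self):
        # trilinear interpolation error scales with curvature, so the
        # oracle is a smooth blob (24 mm width at 4 mm voxels)
        shape = (32, 32, 24)
        x, y, z = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
        blob = 100.0 * np.exp(-(((x - 15.5) / 6.0) ** 2
                                + ((y - 15.5) / 6.0) ** 2
                                + ((z - 11.5) / 6.0) ** 2) / 2.0)
        data = np.stack([blob, blob], axis=-1)
        img = DynamicImage(
            data=data, voxel_size=(4.0, 4.0, 4.0),
            schedule=FrameSchedule.from_durations([1.0, 1.0]))
        t = RigidTransform(translation=(1.3, -0.7, 0.4),
                           rotation=(0.02, -0.01, 0.03))
        out = inject_motion(inject_motion(img, [t] * 2), [t.inverse()] * 2)
        sl = (slice(2, -2),) * 3
        err = np.abs(out.data[sl] - img.data[sl]).max()
        assert err < 0.02 * np.ptp(img.data)

    def test_transform_count_must_match_frames(self, noiseless_phantom):
        img, _, _ = noiseless_phantom
        with pytest.raises(ValueError):
            inject_motion(img, [RigidTransform()] * 3)
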