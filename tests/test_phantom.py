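"""Phantom rendering, count calibration, noise, thinning, bootstrap."""

import numpy as np
import pytest

from dynapet.frames import CountsCalibration, DynamicImage, FrameSchedule, ValidationError
from dynapet.kinetics import KineticParams, model_tac_2tcm_irr
from dynapet.phantom import (
    DoseLevel,
    IFParams,
    PhantomSpec,
    Region,
    add_poisson_noise,
    bootstrap_counts,
    counts_to_image,
    default_phantom,
    expected_counts,
    feng_if,
    region_masks,
    render_dynamic,
    spawn_seeds,
    thin_counts,
)


class TestInputFunction:
    def test_zero_before_appearance(self):
        p = IFParams(t0_s=20.0)
        t = np.arange(0.0, 100.0)
        c = feng_if(p, t)
        assert np.all(c[t < 20.0] == 0)
        assert np.all(c >= 0)

    def test_single_early_peak_then_decay(self):
        p = IFParams()
        t = np.arange(0.0, 3601.0)
        c = feng_if(p, t)
        peak = c.argmax()
        assert t[peak] < 120.0
        # monotone decay once the slowest exponential dominates
        late = c[1200:]
        assert np.all(np.diff(late) <= 1e-9)

    def test_peak_location_stable_under_grid_refinement(self):
        """Brute-force fine-grid peak search agrees with the coarse grid."""
        p = IFParams()
        coarse = np.arange(0.0, 300.0, 1.0)
        fine = np.arange(0.0, 300.0, 0.01)
        t_coarse = coarse[feng_if(p, coarse).argmax()]
        t_fine = fine[feng_if(p, fine).argmax()]
        assert abs(t_coarse - t_fine) <= 1.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            IFParams(l1=0.1, l2=0.2, l3=0.01)  # l1 must exceed l2


class TestRenderDynamic:
    def _one_region_phantom(self, model, params):
        return PhantomSpec(
            grid=(8, 8, 8), voxel_size_mm=(4.0, 4.0, 4.0),
            regions=(Region("r", (16.0, 16.0, 16.0), (20.0, 20.0, 20.0),
                            model, params),),
        )

    def test_blood_region_frame_average_of_linear_ramp_is_exact(self):
        # blood region carries the IF itself: a linear ramp a*t averages to
        # a*(start+end)/2 exactly under trapezoid frame averaging
        phantom = self._one_region_phantom("blood", None)
        sched = FrameSchedule(((0.0, 10.0), (10.0, 40.0)))
        a = 0.25
        curve = a * np.arange(0.0, 41.0)
        img = render_dynamic(phantom, curve, sched)
        mask = region_masks(phantom)["r"]
        assert np.allclose(img.voxels[mask][0], [a * 5.0, a * 25.0])

    def test_constant_curve_renders_constant(self):
        phantom = self._one_region_phantom("blood", None)
        sched = FrameSchedule(((0.0, 30.0), (30.0, 60.0)))
        img = render_dynamic(phantom, np.full(61, 7.0), sched)
        mask = region_masks(phantom)["r"]
        assert np.allclose(img.voxels[mask], 7.0)
        assert np.allclose(img.voxels[~mask], 0.0)

    def test_2tcm_frame_average_matches_dense_quadrature(self, if_curve, fdg_schedule):
        p = KineticParams(K1=0.5, k2=0.7, k3=0.08, vB=0.05)
        phantom = self._one_region_phantom("2tcm_irr", p)
        img = render_dynamic(phantom, if_curve, fdg_schedule)
        mask = region_masks(phantom)["r"]
        got = img.voxels[mask][0]
        curve = model_tac_2tcm_irr(p, if_curve)
        t = np.arange(len(curve), dtype=float)
        for i, (s, e) in enumerate(fdg_schedule.frames):
            fine = np.linspace(s, e, 2001)
            ref = np.trapezoid(np.interp(fine, t, curve), fine) / (e - s)
            assert got[i] == pytest.approx(ref, rel=1e-3)

    def test_linear_in_input_amplitude(self, if_curve, fdg_schedule):
        p = KineticParams(K1=0.5, k2=0.7, k3=0.08, vB=0.05)
        phantom = self._one_region_phantom("2tcm_irr", p)
        img1 = render_dynamic(phantom, if_curve, fdg_schedule)
        img3 = render_dynamic(phantom, 3.0 * if_curve, fdg_schedule)
        assert np.allclose(img3.voxels, 3.0 * img1.voxels, rtol=1e-12)


class TestCounts:
    def _small_image(self):
        sched = FrameSchedule(((0.0, 5.0), (5.0, 15.0)))
        vox = np.ones((4, 4, 4, 2)) * 2.0
        return DynamicImage(vox, (4.0, 4.0, 4.0), sched,
                            CountsCalibration(sensitivity=60.0, dose_fraction=1.0))

    def test_expected_counts_formula_and_linearity(self):
        img = self._small_image()
        c = expected_counts(img)
        # conc * voxel ml * duration * sensitivity
        assert c[0, 0, 0, 0] == pytest.approx(2.0 * 0.064 * 5.0 * 60.0)
        assert c[0, 0, 0, 1] == pytest.approx(2.0 * c[0, 0, 0, 0])  # 2x duration
        img2 = DynamicImage(img.voxels, img.voxel_size_mm, img.schedule,
                            CountsCalibration(60.0, 0.5))
        assert np.allclose(expected_counts(img2), 0.5 * c)

    def test_poisson_zero_expectation_gives_zero(self):
        img = self._small_image()
        img.voxels[:] = 0.0
        noisy = add_poisson_noise(img, seed=3)
        assert np.all(noisy.voxels == 0)

    def test_poisson_determinism_and_mean(self):
        img = self._small_image()
        a = add_poisson_noise(img, seed=9)
        b = add_poisson_noise(img, seed=9)
        assert np.array_equal(a.voxels, b.voxels)
        # Monte-Carlo moment check on a fixed expectation of ~38.4
        lam = expected_counts(img)[0, 0, 0, 0]
        draws = np.array([
            np.random.default_rng(s).poisson(lam)
            for s in spawn_seeds(123, 10_000)
        ])
        se = np.sqrt(lam / len(draws))
        assert abs(draws.mean() - lam) < 3 * se

    def test_counts_round_trip(self):
        img = self._small_image()
        c = expected_counts(img)
        back = counts_to_image(c, img)
        assert np.allclose(back.voxels, img.voxels)


class TestThinning:
    def test_factor_one_identity(self):
        counts = np.arange(24).reshape(2, 3, 2, 2)
        assert np.array_equal(thin_counts(counts, 1.0, seed=0), counts)

    def test_conservation_with_complement(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(80.0, (6, 6, 6, 4))
        thinned, comp = thin_counts(counts, 0.3, seed=7, complementary=True)
        assert np.array_equal(thinned + comp, counts)
        assert thinned.min() >= 0 and comp.min() >= 0

    def test_binomial_moments(self):
        counts = np.full(10_000, 1000, dtype=np.int64)
        thinned = thin_counts(counts, 0.5, seed=1)
        se = np.sqrt(1000 * 0.25 / len(counts))
        assert abs(thinned.mean() - 500.0) < 3 * se

    def test_composition_of_thinnings(self):
        """Thinning by f1 then f2 has Binomial(n, f1*f2) moments."""
        n, f1, f2 = 400, 0.5, 0.4
        counts = np.full(20_000, n, dtype=np.int64)
        stage1 = thin_counts(counts, f1, seed=2)
        stage2 = thin_counts(stage1, f2, seed=3)
        p = f1 * f2
        se = np.sqrt(n * p * (1 - p) / len(counts))
        assert abs(stage2.mean() - n * p) < 3 * se

    def test_invalid_factor(self):
        with pytest.raises(ValidationError):
            thin_counts(np.ones(3), 0.0, seed=0)
        with pytest.raises(ValidationError):
            DoseLevel(1.5)


class TestBootstrap:
    def test_replicate_count_and_determinism(self):
        counts = np.random.default_rng(0).poisson(30, (4, 4, 4, 2))
        reps = bootstrap_counts(counts, B=10, seed=4)
        assert reps.shape == (10, 4, 4, 4, 2)
        assert np.array_equal(reps, bootstrap_counts(counts, B=10, seed=4))
        # replicates are not all identical
        assert not np.array_equal(reps[0], reps[1])

    def test_poisson_moment(self):
        counts = np.array([50])
        reps = bootstrap_counts(counts, B=5000, seed=8)
        se = np.sqrt(50 / 5000)
        assert abs(reps.mean() - 50.0) < 3 * se


class TestDefaultPhantom:
    def test_small_contract(self, small_phantom, small_masks):
        assert small_phantom.grid == (32, 32, 32)
        assert len(small_phantom.regions) >= 8
        for name, mask in small_masks.items():
            assert mask.any(), f"region {name} is empty on the grid"

    def test_ground_truth_ki_consistency(self, small_phantom):
        for r in small_phantom.regions:
            if r.model == "2tcm_irr":
                k = r.kinetics
                assert k.ki == pytest.approx(k.K1 * k.k3 / (k.k2 + k.k3))

    def test_lesion_core_colder_than_shell_late(self, small_phantom, small_masks,
                                                if_curve, fgln_schedule):
        img = render_dynamic(small_phantom, if_curve, fgln_schedule)
        last = img.voxels[..., -1]
        assert last[small_masks["lesion_core"]].mean() < last[small_masks["lesion"]].mean()

    def test_unknown_size_rejected(self):
        with pytest.raises(ValidationError):
            default_phantom("huge")


class TestNoiseScaling:
    def test_roi_noise_scales_with_inverse_sqrt_counts(self, static_frame, small_masks):
        """Relative SD of the ROI mean follows 1/sqrt(ROI counts) within 20 %
        across a 100x dose range."""
        mask = small_masks["liver"]
        counts = expected_counts(static_frame)
        roi_counts_full = counts[mask].sum()
        rels = {}
        for dose in (1.0, 0.1, 0.01):
            means = []
            for s in spawn_seeds(31, 80):
                lam = counts * dose
                noisy = np.random.default_rng(s).poisson(lam)
                conc = counts_to_image(noisy, static_frame,
                                       static_frame.calibration.scaled(dose))
                means.append(conc.voxels[mask].mean())
            rels[dose] = np.std(means) / np.mean(means)
        for dose, rel in rels.items():
            predicted = 1.0 / np.sqrt(roi_counts_full * dose)
            assert rel == pytest.approx(predicted, rel=0.2)
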