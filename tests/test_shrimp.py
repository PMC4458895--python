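"""SHRImP pipeline: trace filtering, step detection, PSF fitting,
difference-image localization and distance histograms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rodfold.psf import (PSFFit, eccentricity, fit_psf, model_image,
                         render_isotropic)
from rodfold.shrimp import (LocalizationPair, Region, analyze_movie,
                            distance_histogram, extract_region_trace,
                            freedman_diaconis_width, level_images,
                            shrimp_localize)
from rodfold.simulate import TIRFSimConfig, simulate_tirf_movie
from rodfold.steps import (Rejection, StepModel, chung_kennedy_filter,
                           detect_two_steps)


class TestChungKennedyFilter:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(min_value=-1e5, max_value=1e5,
                     allow_nan=False), st.integers(20, 80))
    def test_constant_trace_is_invariant(self, level, n):
        out = chung_kennedy_filter(np.full(n, level))
        np.testing.assert_allclose(out, level, rtol=0, atol=1e-9)

    def test_noiseless_step_preserved_exactly(self):
        # each one-sided window is zero-variance on its own side, so the
        # filter reproduces the step sample by sample
        x = np.concatenate([np.full(25, 100.0), np.full(25, 50.0)])
        np.testing.assert_array_equal(chung_kennedy_filter(x), x)

    def test_reduces_mse_on_noisy_two_level_trace(self):
        truth = np.concatenate([np.full(40, 100.0), np.full(40, 50.0)])
        rng = np.random.default_rng(0)
        mse_raw, mse_filt = 0.0, 0.0
        for _ in range(200):
            noisy = truth + rng.normal(0, 10, truth.size)
            filt = chung_kennedy_filter(noisy)
            mse_raw += np.mean((noisy - truth) ** 2)
            mse_filt += np.mean((filt - truth) ** 2)
        assert mse_filt < mse_raw

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            chung_kennedy_filter(np.ones(4), window=5)


class TestStepDetection:
    def test_constant_trace_rejected_no_steps(self):
        out = detect_two_steps(np.full(60, 500.0))
        assert isinstance(out, Rejection) and out.reason == "no steps"

    def test_single_step_rejected_as_one_fluorophore(self):
        x = np.concatenate([np.full(30, 1000.0), np.full(30, 30.0)])
        out = detect_two_steps(chung_kennedy_filter(x), raw=x)
        assert isinstance(out, Rejection)
        assert out.reason == "one fluorophore"

    def test_noisy_two_step_recovery_within_one_frame(self):
        # steps at frames 40 and 90, levels 1000/520/30, noise sd 15
        truth = np.concatenate([np.full(40, 1000.0), np.full(50, 520.0),
                                np.full(40, 30.0)])
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(200):
            noisy = truth + rng.normal(0, 15, truth.size)
            out = detect_two_steps(chung_kennedy_filter(noisy), raw=noisy)
            if isinstance(out, StepModel):
                s1, s2 = out.step_frames
                if abs(s1 - 40) <= 1 and abs(s2 - 90) <= 1:
                    hits += 1
        assert hits >= 190

    def test_level_ordering_required(self):
        x = np.concatenate([np.full(20, 100.0), np.full(20, 500.0),
                            np.full(20, 30.0)])
        out = detect_two_steps(x)
        assert isinstance(out, Rejection)


class TestLevelImages:
    def test_constant_stack(self):
        stack = np.ones((30, 12, 12)) * 7.0
        i1, i2 = level_images(stack, Region(0, 0), step1=10)
        np.testing.assert_array_equal(i1, stack[0, :10, :10])
        np.testing.assert_array_equal(i2, stack[0, :10, :10])

    def test_exact_means_of_identical_frames(self):
        p = np.arange(100).reshape(10, 10).astype(float)
        q = p[::-1]
        stack = np.concatenate([np.tile(p, (7, 1, 1)),
                                np.tile(q, (7, 1, 1))])
        i1, i2 = level_images(stack, Region(0, 0), step1=7)
        np.testing.assert_array_equal(i1, p)
        np.testing.assert_array_equal(i2, q)

    def test_averaging_reduces_pixel_noise_like_sqrt7(self):
        rng = np.random.default_rng(2)
        sds = []
        for _ in range(100):
            stack = rng.normal(100.0, 9.0, (20, 10, 10))
            _, i2 = level_images(stack, Region(0, 0), step1=8)
            sds.append(i2.std())
        assert np.mean(sds) == pytest.approx(9.0 / np.sqrt(7), rel=0.2)

    def test_insufficient_frames_named(self):
        stack = np.ones((10, 10, 10))
        with pytest.raises(ValueError, match="before the first step"):
            level_images(stack, Region(0, 0), step1=3)


class TestPSFFit:
    def test_noiseless_render_and_refit_recovers_centre(self):
        img = render_isotropic((10, 10), 4.30, 5.70, 0.80, 5000.0) + 2.0
        fit = fit_psf(img)
        assert fit.converged
        assert fit.x0 == pytest.approx(4.30, abs=1e-3)
        assert fit.y0 == pytest.approx(5.70, abs=1e-3)
        assert fit.sigma_x == pytest.approx(0.80, abs=1e-3)

    def test_circular_spot_residual_invariant_to_theta(self):
        img = render_isotropic((10, 10), 5.0, 5.0, 0.8, 3000.0)
        base = model_image((10, 10), 100.0, 5.0, 5.0, 0.8, 0.8, 0.0, 0.0)
        for theta in (0.3, 1.1, 2.5):
            rotated = model_image((10, 10), 100.0, 5.0, 5.0, 0.8, 0.8,
                                  theta, 0.0)
            np.testing.assert_allclose(rotated, base, atol=1e-12)
        fit = fit_psf(img)
        assert eccentricity(fit) == pytest.approx(0.0, abs=1e-4)

    def test_flat_image_reports_failed_fit(self):
        fit = fit_psf(np.zeros((10, 10)))
        assert not fit.converged

    def test_localization_precision_scales_with_photon_count(self):
        # centre scatter ~ sigma/sqrt(N) within a factor of two
        rng = np.random.default_rng(3)
        for photons in (200, 1000, 5000):
            errs = []
            for _ in range(40):
                img = rng.poisson(
                    render_isotropic((10, 10), 4.6, 5.2, 0.7, photons)
                ).astype(float)
                fit = fit_psf(img)
                if fit.converged:
                    errs.append(fit.x0 - 4.6)
            scatter = np.std(errs)
            predicted = 0.7 / np.sqrt(photons)
            assert predicted / 2 < scatter < predicted * 2


class TestEccentricity:
    @pytest.mark.parametrize("ratio, expected", [
        (1.0, 0.0),
        (0.6, 0.8),
        (0.999, 0.0447),
    ])
    def test_formula(self, ratio, expected):
        fit = PSFFit(1.0, 5, 5, 1.0 * ratio, 1.0, 0.0, 0.0, True, 0.0)
        assert eccentricity(fit) == pytest.approx(expected, abs=5e-4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.05, 5.0), st.floats(0.05, 5.0))
    def test_bounded_and_symmetric(self, sx, sy):
        f1 = PSFFit(1.0, 5, 5, sx, sy, 0.0, 0.0, True, 0.0)
        f2 = PSFFit(1.0, 5, 5, sy, sx, 0.0, 0.0, True, 0.0)
        e = eccentricity(f1)
        assert 0.0 <= e < 1.0
        assert e == pytest.approx(eccentricity(f2), abs=1e-12)

    def test_undefined_for_failed_fit(self):
        fit = PSFFit(1.0, 5, 5, 1.0, 1.0, 0.0, 0.0, False, 0.0)
        with pytest.raises(ValueError):
            eccentricity(fit)


class TestLocalization:
    def test_noiseless_pair_recovered_to_sub_angstrom(
            self, noiseless_movie):
        _, stack, truth = noiseless_movie
        res = [r for r in analyze_movie(stack)
               if isinstance(r, LocalizationPair)]
        assert len(res) == 1
        assert res[0].distance == pytest.approx(59.0, abs=0.5)

    @pytest.mark.parametrize("sep", [20.0, 40.0, 80.0, 100.0])
    def test_noiseless_end_to_end_exact_over_separations(self, sep):
        cfg = TIRFSimConfig(separation=sep, shot_noise=False,
                            read_noise_sd=0.0, seed=7)
        stack, _ = simulate_tirf_movie(cfg)
        res = [r for r in analyze_movie(stack)
               if isinstance(r, LocalizationPair)]
        assert res and res[0].distance == pytest.approx(sep, abs=1e-2)

    def test_distance_is_exact_euclidean_norm(self, noiseless_movie):
        _, stack, _ = noiseless_movie
        pair = [r for r in analyze_movie(stack)
                if isinstance(r, LocalizationPair)][0]
        d = np.hypot(pair.pos1[0] - pair.pos2[0],
                     pair.pos1[1] - pair.pos2[1])
        assert pair.distance == d

    def test_zero_separation_distances_biased_positive(self):
        # the norm of a noisy 2-vector is non-negative, so recovered
        # distances at zero true separation have a positive mean; this
        # is a documented property, not an error
        dists = []
        for i in range(25):
            cfg = TIRFSimConfig(separation=0.0, seed=400 + i)
            stack, _ = simulate_tirf_movie(cfg)
            for r in analyze_movie(stack):
                if isinstance(r, LocalizationPair) and r.passed_qc:
                    dists.append(r.distance)
        assert len(dists) >= 5
        assert np.mean(dists) > 0

    def test_qc_monotone_in_eccentricity_threshold(self):
        pairs = []
        for i in range(20):
            stack, _ = simulate_tirf_movie(TIRFSimConfig(seed=500 + i))
            pairs += [r for r in analyze_movie(stack, ecc_max=np.inf)
                      if isinstance(r, LocalizationPair)
                      and np.all(np.isfinite(r.eccentricities))]
        counts = []
        for thr in (0.05, 0.1, 0.2, 0.35, 0.6, 1.0):
            counts.append(sum(max(p.eccentricities) < thr for p in pairs))
        assert counts == sorted(counts)

    def test_too_short_movie_rejected(self):
        with pytest.raises(ValueError, match="15 frames"):
            analyze_movie(np.zeros((5, 16, 16)))

    def test_overlapping_second_step_rejected(self, noiseless_movie):
        _, stack, _ = noiseless_movie
        model = StepModel((20, 24), (3000.0, 1500.0, 0.0))
        with pytest.raises(ValueError):
            shrimp_localize(stack, Region(3, 3), model)


class TestDistanceHistogram:
    def test_fd_width_rounds_to_nearest_5nm(self):
        values = np.arange(100) * (34.0 / 49.5)   # IQR exactly 34 nm
        # 2 * 34 * 100^(-1/3) = 14.65 -> 15 nm
        assert freedman_diaconis_width(values) == pytest.approx(15.0)

    def test_gaussian_recovery_at_54nm(self):
        rng = np.random.default_rng(6)
        d = rng.normal(54.0, 15.0, 100)
        hist = distance_histogram(d, bin_width=25.0)
        assert hist.gauss_mean == pytest.approx(54.0, abs=4.0)
        assert hist.counts.sum() == 100

    def test_identical_distances_flagged_degenerate(self):
        hist = distance_histogram(np.full(20, 42.0), bin_width=25.0)
        assert hist.degenerate
        assert hist.counts.sum() == 20

    def test_counts_conserve_pairs(self):
        rng = np.random.default_rng(7)
        d = rng.normal(60, 5, 57)
        for bw in (25.0, 5.0, None):
            hist = distance_histogram(d, bin_width=bw)
            assert hist.counts.sum() == 57 == hist.n_pairs

    def test_too_few_distances_rejected(self):
        with pytest.raises(ValueError):
            distance_histogram(np.arange(5.0))


def test_region_trace_sums_the_region():
    stack = np.arange(2 * 12 * 12, dtype=float).reshape(2, 12, 12)
    tr = extract_region_trace(stack, Region(1, 2))
    assert tr[0] == stack[0, 1:11, 2:12].sum()
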