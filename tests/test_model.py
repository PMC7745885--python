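"""Background fitting, noise estimation and peak detection."""

import dataclasses

import numpy as np
import pytest

import fourc
from fourc.model import FoldedProfile, LAMBDA_MIN
from conftest import simulate_profile


def make_profile(x, signal, vp):
    """NormalizedProfile straight from arrays (already filtered/normalized)."""
    x = np.asarray(x, dtype=np.int64)
    return fourc.NormalizedProfile(
        viewpoint=vp,
        chroms=np.full(len(x), vp.chrom),
        starts=x - 50,
        ends=x + 50,
        x=x,
        signal=np.asarray(signal, dtype=float),
        norm_constant=1.0,
        window_weight=float(np.sum(signal)),
        target_total=float(np.sum(signal)),
        retained_mask=np.ones(len(x), dtype=bool),
    )


class TestFoldProfile:
    def test_left_right_averaging(self):
        vp = fourc.Viewpoint("c", 99_950, 100_050)
        prof = make_profile([90_000, 110_000], [2.0, 6.0], vp)
        folded = fourc.fold_profile(prof, bin_width=5_000)
        assert len(folded.d) == 1
        assert folded.a[0] == pytest.approx(4.0)  # mean of the two sides
        assert folded.support[0] == 2

    def test_symmetric_signal_is_unchanged(self):
        vp = fourc.Viewpoint("c", 99_950, 100_050)
        prof = make_profile([90_000, 110_000], [4.0, 4.0], vp)
        folded = fourc.fold_profile(prof, bin_width=5_000)
        assert folded.a[0] == pytest.approx(4.0)

    def test_one_sided_profile_warns(self):
        vp = fourc.Viewpoint("c", 99_950, 100_050)
        prof = make_profile([110_000, 120_000], [1.0, 2.0], vp)
        with pytest.warns(UserWarning, match="one-sided"):
            folded = fourc.fold_profile(prof, bin_width=5_000)
        assert len(folded.d) == 2


class TestFitBackground:
    def test_noiseless_recovery_to_1e6(self):
        d = (np.arange(100) + 0.5) * 5_000.0
        a = 2.0 + 8.0 * np.exp(-d / 50_000.0)
        folded = FoldedProfile(d=d, a=a, support=np.full(100, 25), bin_width=5_000.0)
        bg, diag = fourc.fit_background(folded)
        assert diag["converged"]
        assert bg.B == pytest.approx(2.0, rel=1e-6)
        assert bg.I_v == pytest.approx(8.0, rel=1e-6)
        assert bg.lam == pytest.approx(50_000.0, rel=1e-6)

    def test_flat_profile_degenerates_to_mean(self):
        d = (np.arange(50) + 0.5) * 5_000.0
        folded = FoldedProfile(d=d, a=np.full(50, 3.0), support=np.full(50, 10), bin_width=5_000.0)
        bg, diag = fourc.fit_background(folded)
        assert diag["degenerate"]
        assert bg.B == pytest.approx(3.0)
        assert bg.I_v == 0.0 and bg.lam == LAMBDA_MIN

    def test_contaminated_bins_are_trimmed(self):
        rng = np.random.default_rng(5)
        d = (np.arange(100) + 0.5) * 5_000.0
        a = 2.0 + 8.0 * np.exp(-d / 50_000.0)
        a[rng.choice(100, 20, replace=False)] *= 10  # peak-like contamination
        folded = FoldedProfile(d=d, a=a, support=np.full(100, 25), bin_width=5_000.0)
        bg, _ = fourc.fit_background(folded)
        assert abs(bg.lam - 50_000.0) / 50_000.0 < 0.15

    def test_too_few_bins(self):
        folded = FoldedProfile(d=np.array([1e3, 2e3]), a=np.array([1.0, 2.0]),
                               support=np.array([5, 5]), bin_width=1e3)
        with pytest.raises(ValueError):
            fourc.fit_background(folded)

    def test_monotone_background(self):
        d = (np.arange(80) + 0.5) * 5_000.0
        a = 1.0 + 5.0 * np.exp(-d / 30_000.0) + np.random.default_rng(0).normal(0, 0.05, 80)
        folded = FoldedProfile(d=d, a=np.maximum(a, 0), support=np.full(80, 20), bin_width=5_000.0)
        bg, _ = fourc.fit_background(folded)
        grid = np.linspace(0, 4e6, 500)
        pred = bg.predict(grid)
        assert (np.diff(pred) <= 1e-12).all()


class TestSubtractBackground:
    def test_exact_background_gives_zero_residuals(self):
        vp = fourc.Viewpoint("c", 995_000, 1_005_000, norm_radius=2_000_000)
        x = np.arange(1_020_000, 2_000_000, 1_000)
        bg = fourc.BackgroundModel(B=1.0, I_v=5.0, lam=50_000.0)
        prof = make_profile(x, bg.predict(np.abs(x - vp.centre)), vp)
        r = fourc.subtract_background(prof, bg)
        np.testing.assert_allclose(r, 0.0, atol=1e-12)

    def test_zero_background_is_identity(self):
        vp = fourc.Viewpoint("c", 995_000, 1_005_000)
        x = np.arange(1_020_000, 1_100_000, 1_000)
        s = np.linspace(1, 3, len(x))
        prof = make_profile(x, s, vp)
        bg = fourc.BackgroundModel(B=0.0, I_v=0.0, lam=1.0e3)
        np.testing.assert_allclose(fourc.subtract_background(prof, bg), s)


class TestEstimateNoise:
    def test_gaussian_consistency(self):
        r = np.random.default_rng(7).standard_normal(10_000)
        assert fourc.estimate_noise(r) == pytest.approx(1.0, abs=0.05)

    def test_constant_residuals_error(self):
        with pytest.raises(ValueError, match="zero noise"):
            fourc.estimate_noise(np.full(100, 2.5))

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            fourc.estimate_noise(np.arange(5, dtype=float))

    def test_outlier_robustness(self):
        rng = np.random.default_rng(11)
        clean = rng.standard_normal(5_000)
        dirty = clean.copy()
        dirty[rng.choice(5_000, 250, replace=False)] += 50.0  # 5% gross outliers
        assert abs(fourc.estimate_noise(dirty) - fourc.estimate_noise(clean)) < 0.1


class TestDetectPeaks:
    def _grid(self, n=3_000, spacing=350, seed=0):
        rng = np.random.default_rng(seed)
        x = np.cumsum(rng.integers(spacing - 150, spacing + 150, size=n)).astype(float)
        return x, rng

    def test_flat_zero_residuals_give_no_calls(self):
        x, _ = self._grid(800)
        calls = fourc.detect_peaks(np.zeros(len(x)), 1.0, x, sigma=20_000.0)
        assert calls == []

    def test_single_injected_peak_found_once(self):
        x, rng = self._grid(3_000, seed=3)
        centre = x[len(x) // 2]
        r = rng.standard_normal(len(x)) + 10.0 * np.exp(-0.5 * ((x - centre) / 20_000.0) ** 2)
        calls = fourc.detect_peaks(r, 1.0, x, sigma=20_000.0, alpha=0.0005)
        assert len(calls) == 1
        assert abs(calls[0].centre - centre) < 20_000.0
        assert calls[0].significant and calls[0].p_value < 0.0005
        assert calls[0].amplitude == pytest.approx(10.0, rel=0.3)

    def test_null_calibration_on_gaussian_noise(self):
        # fraction of fragments covered by significant calls at the
        # default alpha stays below 0.002 across 200 profiles
        x, _ = self._grid(2_000, seed=9)
        rng = np.random.default_rng(123)
        flagged = tot = 0
        for _ in range(200):
            r = rng.standard_normal(len(x))
            calls = fourc.detect_peaks(r, 1.0, x, sigma=20_000.0, alpha=0.0005)
            cov = np.zeros(len(x), dtype=bool)
            for pk in calls:
                s, e = pk.interval
                cov |= (x >= s) & (x <= e)
            flagged += cov.sum()
            tot += len(x)
        assert flagged / tot <= 0.002

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            fourc.detect_peaks(np.zeros(10), 1.0, np.arange(10.0), sigma=0.0)

    def test_empty_series(self):
        assert fourc.detect_peaks(np.array([]), 1.0, np.array([]), sigma=1e4) == []


class TestEvaluateModel:
    @pytest.fixture
    def fitted(self, map5m, vp5m):
        truth = fourc.default_truth(vp5m, seed=77)
        prof, _ = simulate_profile(map5m, truth)
        return prof, fourc.call_interactions(prof)

    def test_forward_model_components(self, fitted):
        _, fit = fitted
        vp = fit.viewpoint
        no_peak_model = dataclasses.replace(fit, peaks=[])
        at_vp = float(no_peak_model.predict([vp.centre])[0])
        assert at_vp == pytest.approx(fit.background.B + fit.background.I_v, rel=1e-9)
        far = float(no_peak_model.predict([vp.centre + 5e8])[0])
        assert far == pytest.approx(fit.background.B, rel=1e-9)

    def test_forward_inverse_consistency(self, fitted):
        prof, fit = fitted
        x, s = prof.cis()
        np.testing.assert_allclose(fit.predict_background(x) + fit.resid, s, atol=1e-9)

    def test_peak_recovered_near_truth(self, fitted):
        _, fit = fitted
        vp = fit.viewpoint
        offsets = sorted((pk.centre - vp.centre) / 1000 for pk in fit.peaks)
        assert len(offsets) == 2
        assert abs(offsets[0] - 350.0) < 10 and abs(offsets[1] - 430.0) < 15

    def test_summary_mentions_key_quantities(self, fitted):
        _, fit = fitted
        text = fit.summary()
        assert "lambda" in text and "significant peaks" in text
        assert f"{len(fit.peaks)}" in text


class TestCallInteractions:
    def test_determinism(self, map5m, vp5m):
        truth = fourc.default_truth(vp5m, seed=88)
        prof, _ = simulate_profile(map5m, truth)
        fit1 = fourc.call_interactions(prof)
        fit2 = fourc.call_interactions(prof)
        assert fit1.background == fit2.background
        assert fit1.peaks == fit2.peaks
        assert fit1.residual_scale == fit2.residual_scale

    def test_translation_equivariance(self, map5m, vp5m):
        shift = 7_654_321
        truth = fourc.default_truth(vp5m, seed=55)
        prof, _ = simulate_profile(map5m, truth)
        vp2 = fourc.Viewpoint(vp5m.chrom, vp5m.start + shift, vp5m.end + shift)
        prof2 = dataclasses.replace(
            prof,
            viewpoint=vp2,
            starts=prof.starts + shift,
            ends=prof.ends + shift,
            x=prof.x + shift,
        )
        fit1 = fourc.call_interactions(prof)
        fit2 = fourc.call_interactions(prof2)
        assert fit2.background.B == pytest.approx(fit1.background.B, rel=1e-9)
        assert fit2.background.lam == pytest.approx(fit1.background.lam, rel=1e-9)
        assert len(fit1.peaks) == len(fit2.peaks)
        for p1, p2 in zip(fit1.peaks, fit2.peaks):
            assert p2.centre - p1.centre == pytest.approx(shift, abs=1.0)
            assert p2.p_value == pytest.approx(p1.p_value, rel=1e-6)

    def test_alpha_validation(self, map5m, vp5m):
        truth = fourc.default_truth(vp5m, seed=88)
        prof, _ = simulate_profile(map5m, truth)
        with pytest.raises(ValueError):
            fourc.ViewpointModel(prof, alpha=1.5)
        with pytest.raises(ValueError):
            fourc.ViewpointModel(prof, sigma=-1.0)
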