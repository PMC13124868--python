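import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ramanscreen.dataset import SpectralDataset, WavenumberAxis
from ramanscreen.filters import (
    MSC,
    SNV,
    AsLSBaseline,
    AsLSSmoother,
    DegenerateSpectrumError,
    EWMASmoother,
    FilterCombination,
    FilterParams,
    LinearBaseline,
    MovingMedianSmoother,
    OffsetBaseline,
    PeakAreaNormalizer,
    PeakHeightNormalizer,
    RowCenter,
    SavitzkyGolayDerivative,
    SavitzkyGolaySmoother,
    WaveletDenoiser,
    all_combinations,
    apply_combination,
    asls_fit,
)
from ramanscreen.screen import _iter_preprocessed

NU = np.arange(100.0, 400.0)  # 300-channel axis for operator tests


def _peaky(rng=None, n=500):
    x = np.arange(float(n))
    y = 10.0 + 8 * np.exp(-0.5 * ((x - 150) / 8) ** 2) \
        + 12 * np.exp(-0.5 * ((x - 300) / 10) ** 2) \
        + 6 * np.exp(-0.5 * ((x - 420) / 6) ** 2)
    if rng is not None:
        y = y + rng.normal(0, 0.2, n)
    return x, y


class TestSavitzkyGolay:
    def test_constant_preserved(self):
        y = np.full_like(NU, 7.0)
        np.testing.assert_allclose(SavitzkyGolaySmoother().transform(y), y)

    def test_quadratic_reproduced_exactly(self):
        y = 0.01 * NU**2 - 3 * NU + 5
        np.testing.assert_allclose(SavitzkyGolaySmoother().transform(y), y,
                                   atol=1e-8)

    def test_impulse_response_matches_normal_equations(self):
        # centre output = centre SG coefficient from the local quadratic fit
        w, order = 15, 2
        y = np.zeros(w)
        y[w // 2] = 1.0
        A = np.vander(np.arange(w) - w // 2, order + 1, increasing=True)
        H = A @ np.linalg.solve(A.T @ A, A.T)
        expected = H[w // 2, w // 2]
        out = SavitzkyGolaySmoother(w, order).transform(np.r_[np.zeros(20), y,
                                                              np.zeros(20)])
        assert out[20 + w // 2] == pytest.approx(expected, abs=1e-10)

    def test_window_longer_than_spectrum_rejected(self):
        with pytest.raises(ValueError):
            SavitzkyGolaySmoother(15).transform(np.ones(10))


class TestEWMA:
    def test_alpha_one_is_identity(self):
        y = np.sin(NU / 10)
        np.testing.assert_allclose(EWMASmoother(alpha=1.0).transform(y), y)

    def test_constant_preserved(self):
        y = np.full(100, 3.0)
        np.testing.assert_allclose(EWMASmoother(0.3).transform(y), y)

    def test_linear_ramp_preserved_in_interior(self):
        # symmetric two-pass cancels the lag of each directional pass
        y = np.linspace(0, 10, 50)
        out = EWMASmoother(0.3).transform(y)
        a = 0.3
        fwd = np.empty(50)
        fwd[0] = y[0]
        for i in range(1, 50):
            fwd[i] = a * y[i] + (1 - a) * fwd[i - 1]
        bwd = np.empty(50)
        bwd[-1] = y[-1]
        for i in range(48, -1, -1):
            bwd[i] = a * y[i] + (1 - a) * bwd[i + 1]
        np.testing.assert_allclose(out, 0.5 * (fwd + bwd), atol=1e-12)
        np.testing.assert_allclose(out[10:40], y[10:40], atol=0.15)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            EWMASmoother(0.0).transform(np.ones(10))


class TestWaveletDenoise:
    def test_zero_and_constant_fixed_points(self):
        wds = WaveletDenoiser()
        np.testing.assert_allclose(wds.transform(np.zeros(256)), 0.0,
                                   atol=1e-12)
        np.testing.assert_allclose(wds.transform(np.full(256, 5.0)), 5.0,
                                   atol=1e-10)

    def test_denoising_reduces_rmse_on_noisy_sinusoid(self):
        x = np.linspace(0, 4 * np.pi, 512)
        truth = 10 * np.sin(x)
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = truth + rng.normal(0, 1.0, x.size)
            den = WaveletDenoiser().transform(noisy)
            if np.sqrt(np.mean((den - truth) ** 2)) < np.sqrt(
                    np.mean((noisy - truth) ** 2)):
                wins += 1
        assert wins == 20

    def test_output_length_preserved_for_odd_lengths(self):
        y = np.random.default_rng(0).normal(size=333)
        assert WaveletDenoiser().transform(y).shape == y.shape


class TestMovingMedian:
    def test_constant_and_monotone_preserved(self):
        mm = MovingMedianSmoother(15)
        np.testing.assert_allclose(mm.transform(np.full(60, 2.0)), 2.0)
        y = np.linspace(0, 1, 60)
        out = mm.transform(y)
        assert np.all(np.diff(out) >= -1e-12)

    def test_single_spike_removed_completely(self):
        y = np.ones(100)
        y[50] = 100.0
        out = MovingMedianSmoother(15).transform(y)
        assert out.max() == pytest.approx(1.0)


class TestAsLS:
    def test_line_reproduced(self):
        y = np.linspace(1, 5, 200)
        np.testing.assert_allclose(asls_fit(y, 1e4, 0.5), y, atol=1e-6)

    def test_lambda_to_zero_p_half_returns_input(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=100)
        np.testing.assert_allclose(asls_fit(y, 1e-8, 0.5), y, atol=1e-5)

    def test_baseline_tracked_within_2pct_away_from_peaks(self):
        x, y = _peaky()
        z = asls_fit(y, 1e4, 1e-3)
        away = (np.abs(x - 150) > 40) & (np.abs(x - 300) > 50) \
            & (np.abs(x - 420) > 30)
        assert np.all(np.abs(z[away] - 10.0) / 10.0 < 0.02)

    def test_baseline_subtraction_recovers_peak_heights_within_5pct(self):
        x, y = _peaky()
        corr = AsLSBaseline().transform(y)
        for pos, h in ((150, 8.0), (300, 12.0), (420, 6.0)):
            assert abs(corr[pos] - h) / h < 0.05

    def test_baseline_subtraction_nearly_idempotent(self):
        # the second pass removes at most ~1 % of the tallest peak
        _, y = _peaky()
        once = AsLSBaseline().transform(y)
        twice = AsLSBaseline().transform(once)
        assert np.max(np.abs(twice - once)) < 1e-2 * 12.0


class TestBaselines:
    def test_row_center_examples(self):
        rc = RowCenter()
        np.testing.assert_allclose(rc.transform(np.array([1.0, 2, 3])),
                                   [-1, 0, 1])
        out = rc.transform(np.random.default_rng(0).normal(5, 2, 100))
        assert out.mean() == pytest.approx(0.0, abs=1e-12)

    def test_offset_examples(self):
        ob = OffsetBaseline()
        np.testing.assert_allclose(ob.transform(np.array([3.0, 1, 2])),
                                   [2, 0, 1])
        y = np.array([0.0, 1, 2])
        np.testing.assert_allclose(ob.transform(y), y)

    def test_linear_residual_orthogonal_to_line(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=NU.size) + 0.05 * NU
        out = LinearBaseline(NU).transform(y)
        assert abs(out.sum()) < 1e-8
        assert abs(out @ (NU - NU.mean())) < 1e-6

    def test_exact_line_removed(self):
        y = 2.0 * NU + 3.0
        np.testing.assert_allclose(LinearBaseline(NU).transform(y), 0.0,
                                   atol=1e-9)


class TestNormalizers:
    def test_snv_mean_zero_unit_sd(self):
        rng = np.random.default_rng(2)
        out = SNV().transform(rng.normal(10, 3, 200))
        assert out.mean() == pytest.approx(0.0, abs=1e-10)
        assert out.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_snv_affine_invariance_and_degenerate(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=100)
        np.testing.assert_allclose(SNV().transform(y),
                                   SNV().transform(2.5 * y + 7), atol=1e-10)
        with pytest.raises(DegenerateSpectrumError):
            SNV().transform(np.full(50, 3.0))

    def test_peak_height(self):
        ph = PeakHeightNormalizer()
        np.testing.assert_allclose(ph.transform(np.array([1.0, 4, 2])),
                                   [0.25, 1, 0.5])
        y = np.random.default_rng(4).uniform(0.1, 5, 100)
        np.testing.assert_allclose(ph.transform(y), ph.transform(2 * y))
        with pytest.raises(DegenerateSpectrumError):
            ph.transform(-np.ones(10))

    def test_peak_area_unit_rectangle(self):
        nu = np.arange(0.0, 11.0)
        y = np.ones(11)  # trapezoid area = 10
        out = PeakAreaNormalizer(nu).transform(y)
        np.testing.assert_allclose(out, 0.1)
        assert np.trapezoid(np.abs(out), nu) == pytest.approx(1.0)


class TestMSC:
    def test_reference_maps_to_itself(self):
        rng = np.random.default_rng(5)
        cal = rng.uniform(1, 5, size=(6, 120))
        msc = MSC().fit(cal)
        np.testing.assert_allclose(msc.transform(msc.reference_[None, :])[0],
                                   msc.reference_, atol=1e-10)

    def test_affine_distortion_collapsed(self):
        rng = np.random.default_rng(6)
        cal = rng.uniform(1, 5, size=(6, 120))
        msc = MSC().fit(cal)
        ref = msc.reference_
        np.testing.assert_allclose(msc.transform(2 * ref + 3)[0], ref,
                                   atol=1e-9)
        for a, b in ((0.5, -1.0), (3.0, 10.0)):
            np.testing.assert_allclose(msc.transform(b + a * ref)[0], ref,
                                       atol=1e-9)

    def test_nonpositive_gain_leaves_spectrum_uncorrected(self):
        msc = MSC().fit(np.vstack([np.linspace(0, 1, 50)] * 3))
        y = np.linspace(1, 0, 50)  # anti-correlated with reference
        with pytest.warns(UserWarning):
            out = msc.transform(y)
        np.testing.assert_allclose(out[0], y)


class TestDerivatives:
    def test_first_derivative_exact_on_quadratic(self):
        step = NU[1] - NU[0]
        y = 0.02 * NU**2 - 1.5 * NU + 4
        out = SavitzkyGolayDerivative(1, 15, step).transform(y)
        np.testing.assert_allclose(out[7:-7], 0.04 * NU[7:-7] - 1.5, atol=1e-8)

    def test_second_derivative_exact_on_cubic(self):
        step = NU[1] - NU[0]
        y = 1e-4 * NU**3 - 0.02 * NU**2 + NU
        out = SavitzkyGolayDerivative(2, 15, step).transform(y)
        np.testing.assert_allclose(out[7:-7], 6e-4 * NU[7:-7] - 0.04,
                                   atol=1e-7)

    def test_first_derivative_of_constant_is_zero(self):
        out = SavitzkyGolayDerivative(1, 15, 1.0).transform(np.full(100, 9.0))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)


class TestCombinations:
    def test_grid_has_480_unique_members(self):
        combos = all_combinations()
        assert len(combos) == len(set(combos)) == 480

    def test_label_round_trip(self):
        for combo in all_combinations()[::37]:
            assert FilterCombination.from_label(combo.label()) == combo

    def test_all_none_is_identity(self):
        rng = np.random.default_rng(7)
        ds = SpectralDataset(
            axis=WavenumberAxis(NU), intensities=rng.uniform(1, 5, (4, NU.size)),
            sample_ids=list("abcd"))
        out = apply_combination(ds, FilterCombination.raw())
        np.testing.assert_array_equal(out.intensities, ds.intensities)

    def test_composition_matches_manual_oracle(self):
        rng = np.random.default_rng(8)
        ds = SpectralDataset(
            axis=WavenumberAxis(NU), intensities=rng.uniform(1, 5, (4, NU.size)),
            sample_ids=list("abcd"))
        combo = FilterCombination("MW", "offset", "none", "none")
        out = apply_combination(ds, combo)
        manual = OffsetBaseline().transform(
            MovingMedianSmoother(15).transform(ds.intensities))
        np.testing.assert_allclose(out.intensities, manual, atol=1e-12)

    def test_every_combination_preserves_shape(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(1, 5, (5, 200))
        axis = np.arange(200.0)
        cal = np.ones(5, dtype=bool)
        seen = 0
        for combo, res in _iter_preprocessed(X, axis, cal, FilterParams()):
            assert not isinstance(res, Exception), combo.label()
            assert res.shape == X.shape
            seen += 1
        assert seen == 480

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_scaling_invariance_of_normalizers(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.uniform(0.5, 5.0, 150)
        scale = rng.uniform(0.1, 10.0)
        for tr in (SNV(), PeakHeightNormalizer(), PeakAreaNormalizer()):
            np.testing.assert_allclose(tr.transform(y),
                                       tr.transform(scale * y), atol=1e-8)
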