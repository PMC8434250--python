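import numpy as np
import pytest

from ramandecomp import (
    Spectrum,
    average_replicates,
    baseline_correct,
    crop,
    normalize_to_band,
    resample_uniform,
    second_derivative,
)
from ramandecomp.preprocess import ReplicateSDWarning


def _gauss(x, c, h, w):
    return h * np.exp(-4 * np.log(2) * ((x - c) / w) ** 2)


class TestAverageReplicates:
    def test_identical_replicates_zero_sd(self, gaussian_spectrum):
        mean, sd = average_replicates([gaussian_spectrum] * 3)
        np.testing.assert_allclose(mean.intensity, gaussian_spectrum.intensity, atol=1e-12)
        np.testing.assert_allclose(sd, 0.0, atol=1e-12)

    def test_sample_sd_of_1_2_3(self):
        x = np.arange(10.0)
        reps = [Spectrum(x, np.full(10, v)) for v in (1.0, 2.0, 3.0)]
        with pytest.warns(ReplicateSDWarning):  # SD = 50% of mean
            mean, sd = average_replicates(reps)
        np.testing.assert_allclose(mean.intensity, 2.0)
        np.testing.assert_allclose(sd, 1.0)  # (n-1) sample SD

    def test_low_noise_replicates_no_warning(self):
        import warnings

        from ramandecomp import generate_replicates, random_truth

        truth = random_truth("gliadin_liquid", seed=7, noise_sigma=0.0)
        reps = generate_replicates(truth, 3)  # 2% multiplicative jitter
        with warnings.catch_warnings():
            warnings.simplefilter("error", ReplicateSDWarning)
            mean, sd = average_replicates(reps)
        scale = np.maximum(np.abs(mean.intensity), 1e-9)
        assert np.all(sd / scale < 0.05)

    def test_disjoint_axes_rejected(self):
        a = Spectrum(np.arange(0.0, 10.0), np.ones(10))
        b = Spectrum(np.arange(20.0, 30.0), np.ones(10))
        with pytest.raises(ValueError):
            average_replicates([a, b])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_replicates([])


class TestCrop:
    def test_kernel_analysis_range(self):
        x = np.arange(300.0, 4000.0, 1.0)
        s = Spectrum(x, np.ones_like(x))
        out = crop(s, (300.0, 2000.0))
        assert out.wavenumber.max() <= 2000.0
        assert out.wavenumber.min() >= 300.0

    def test_full_range_identity(self, gaussian_spectrum):
        out = crop(gaussian_spectrum, (0.0, 1e4))
        np.testing.assert_array_equal(out.intensity, gaussian_spectrum.intensity)

    def test_idempotent(self, gaussian_spectrum):
        once = crop(gaussian_spectrum, (650.0, 750.0))
        twice = crop(once, (650.0, 750.0))
        np.testing.assert_array_equal(once.wavenumber, twice.wavenumber)
        np.testing.assert_array_equal(once.intensity, twice.intensity)

    def test_empty_result_rejected(self, gaussian_spectrum):
        with pytest.raises(ValueError):
            crop(gaussian_spectrum, (100.0, 200.0))


class TestBaseline:
    def test_pure_line_cancels_exactly(self):
        x = np.arange(300.0, 2000.0, 1.0)
        s = Spectrum(x, 0.01 * x + 3.0)
        out, model = baseline_correct(s, "linear", [(300, 320), (1980, 2000)])
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-9)
        assert model.kind == "linear"

    def test_gaussian_on_ramp_recovers_height(self):
        x = np.arange(500.0, 900.0, 0.5)
        y = _gauss(x, 700.0, 2.0, 12.0) + 0.002 * x + 1.0
        s = Spectrum(x, y)
        # anchors beyond 4 FWHM of the band center
        out, _ = baseline_correct(s, "linear", [(500, 520), (880, 900)])
        height = out.intensity[np.argmin(np.abs(out.wavenumber - 700.0))]
        assert abs(height - 2.0) / 2.0 < 0.005

    def test_idempotent_on_corrected_spectrum(self):
        x = np.arange(500.0, 900.0, 0.5)
        s = Spectrum(x, _gauss(x, 700.0, 2.0, 12.0) + 0.002 * x)
        once, _ = baseline_correct(s, "linear", [(500, 520), (880, 900)])
        twice, _ = baseline_correct(once, "linear", [(500, 520), (880, 900)])
        assert np.max(np.abs(twice.intensity - once.intensity)) < 1e-6 * np.max(once.intensity)

    def test_degenerate_anchors_rejected(self, gaussian_spectrum):
        with pytest.raises(ValueError):
            baseline_correct(gaussian_spectrum, "linear", [(700, 700.4), (700, 700.4)])


class TestNormalize:
    def _ref_spectrum(self, height=2.0):
        x = np.arange(1300.0, 1600.0, 1.0)
        return Spectrum(x, _gauss(x, 1457.0, height, 15.0) + 0.1)

    def test_divides_by_reference_height(self):
        s = self._ref_spectrum(2.0)
        out, rec = normalize_to_band(s)
        assert rec.divisor == pytest.approx(2.1)  # peak + offset
        np.testing.assert_allclose(out.intensity, s.intensity / rec.divisor)
        win = (out.wavenumber >= 1450) & (out.wavenumber <= 1470)
        assert out.intensity[win].max() == pytest.approx(1.0)

    def test_scale_invariance(self):
        s = self._ref_spectrum()
        out1, _ = normalize_to_band(s)
        out2, _ = normalize_to_band(s.replace(s.intensity * 37.5))
        np.testing.assert_allclose(out1.intensity, out2.intensity, atol=1e-12)

    def test_missing_reference_band_rejected(self):
        x = np.arange(1300.0, 1600.0, 1.0)
        s = Spectrum(x, np.full_like(x, -1.0))
        with pytest.raises(ValueError):
            normalize_to_band(s)


class TestSecondDerivative:
    def test_parabola_gives_constant(self):
        x = np.arange(0.0, 50.0, 0.5)
        a = 0.3
        s = Spectrum(x, a * x**2)
        d2 = second_derivative(s, smooth_window=11, poly_order=3)
        np.testing.assert_allclose(d2.intensity[10:-10], 2 * a, atol=1e-6)

    def test_single_gaussian_minimum_at_center(self, gaussian_spectrum):
        d2 = second_derivative(gaussian_spectrum, smooth_window=11, poly_order=3)
        interior = slice(10, -10)
        i = np.argmin(d2.intensity[interior])
        center = d2.wavenumber[interior][i]
        assert abs(center - 700.0) <= gaussian_spectrum.step

    def test_two_gaussians_two_minima(self):
        x = np.arange(600.0, 800.0, 0.5)
        y = _gauss(x, 690.0, 1.0, 12.0) + _gauss(x, 715.0, 0.8, 12.0)
        d2 = second_derivative(Spectrum(x, y), smooth_window=11, poly_order=3)
        from scipy.signal import argrelmin

        (mins,) = argrelmin(d2.intensity, order=5)
        centers = d2.wavenumber[mins]
        assert any(abs(c - 690.0) < 2 for c in centers)
        assert any(abs(c - 715.0) < 2 for c in centers)

    def test_window_larger_than_spectrum_rejected(self):
        s = Spectrum(np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValueError):
            second_derivative(s, smooth_window=11)

    def test_nonuniform_grid_rejected(self):
        x = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 17.0, 18.0, 19.0, 20.0, 21.0, 22.0, 23.0])
        with pytest.raises(ValueError, match="uniform"):
            second_derivative(Spectrum(x, np.ones_like(x)), smooth_window=5)


class TestChainInvariance:
    @pytest.mark.parametrize("scale", [0.5, 3.0, 1e4])
    def test_preprocessing_chain_scale_invariant(self, scale):
        from ramandecomp import generate_spectrum, random_truth

        truth = random_truth("endosperm", seed=3)
        s, _ = generate_spectrum(truth)
        from ramandecomp.pipeline import ENDOSPERM_BASELINE_ANCHORS

        def chain(spec):
            out = crop(spec, (300.0, 2000.0))
            out, _ = baseline_correct(out, "polynomial", ENDOSPERM_BASELINE_ANCHORS)
            out, _ = normalize_to_band(out)
            return out

        a = chain(s)
        b = chain(s.replace(s.intensity * scale))
        np.testing.assert_allclose(b.intensity, a.intensity, rtol=1e-9, atol=1e-12)

    def test_baseline_normalize_commute_with_crop(self):
        x = np.arange(400.0, 1700.0, 0.5)
        y = _gauss(x, 1457.0, 1.0, 15.0) + _gauss(x, 700.0, 0.4, 12.0) + 0.001 * x
        s = Spectrum(x, y)
        anchors = [(400, 430), (1650, 1700)]

        def process(spec):
            out, _ = baseline_correct(spec, "linear", anchors)
            out, _ = normalize_to_band(out)
            return out

        region = (400.0, 1700.0)  # contains anchors and reference window
        a = crop(process(s), region)
        b = process(crop(s, region))
        np.testing.assert_allclose(a.intensity, b.intensity, atol=1e-10)
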