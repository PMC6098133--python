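import numpy as np
import pytest

from ftirsurv.io import Spectrum
from ftirsurv.preprocess import (
    PreprocessConfig,
    correct_baseline,
    extract_window,
    normalize,
    preprocess,
    smooth,
)

GRID = 800.0 + 2.0 * np.arange(1351)


def _spec(y):
    return Spectrum(GRID, np.asarray(y, dtype=float))


class TestRubberband:
    def test_linear_spectrum_maps_to_zero(self):
        s = _spec(0.1 + 1e-4 * GRID)
        out = correct_baseline(s, PreprocessConfig())
        assert np.allclose(out.absorbance, 0.0, atol=1e-12)

    def test_constant_offset_invariance(self):
        rng = np.random.default_rng(0)
        y = np.abs(rng.normal(size=GRID.size))
        cfg = PreprocessConfig()
        a = correct_baseline(_spec(y), cfg)
        b = correct_baseline(_spec(y + 3.7), cfg)
        assert np.allclose(a.absorbance, b.absorbance, atol=1e-10)

    def test_endpoints_zero_and_hull_nonnegative_envelope(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=GRID.size) ** 2
        out = correct_baseline(_spec(y), PreprocessConfig())
        assert out.absorbance[0] == pytest.approx(0.0, abs=1e-12)
        assert out.absorbance[-1] == pytest.approx(0.0, abs=1e-12)
        # the hull is a lower envelope: corrected values never dip below it
        assert out.absorbance.min() >= -1e-10

    def test_band_apex_survives_sloped_baseline(self):
        band = np.exp(-((GRID - 1030.0) ** 2) / (2 * 8.0**2))
        sloped = band + 1e-4 * GRID
        out = correct_baseline(_spec(sloped), PreprocessConfig())
        i_pure = np.argmax(band)
        i_corr = np.argmax(out.absorbance)
        assert abs(GRID[i_corr] - GRID[i_pure]) <= 2.0  # within one grid step

    def test_grid_unchanged(self):
        s = _spec(np.exp(-((GRID - 1030.0) ** 2) / 128.0))
        out = correct_baseline(s, PreprocessConfig())
        assert np.array_equal(out.wavenumbers, s.wavenumbers)


class TestPolynomialBaseline:
    def test_recovers_planted_quadratic_background(self):
        bg = 0.2 + 1e-4 * GRID + 2e-8 * GRID**2
        band = np.exp(-((GRID - 1030.0) ** 2) / (2 * 8.0**2))
        cfg = PreprocessConfig(baseline_method="polynomial", polynomial_degree=2)
        out = correct_baseline(_spec(bg + band), cfg)
        # the band region should survive, the background be mostly removed
        assert out.absorbance.max() == pytest.approx(1.0, abs=0.05)

    def test_too_few_points_rejected(self):
        s = Spectrum(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        cfg = PreprocessConfig(baseline_method="polynomial", polynomial_degree=3)
        with pytest.raises(ValueError, match="degree"):
            correct_baseline(s, cfg)


class TestNormalize:
    def test_vector_norm_is_one(self):
        rng = np.random.default_rng(2)
        out = normalize(_spec(rng.normal(size=GRID.size)), PreprocessConfig())
        assert np.linalg.norm(out.absorbance) == pytest.approx(1.0, abs=1e-12)

    def test_vector_scale_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=GRID.size)
        cfg = PreprocessConfig()
        a = normalize(_spec(y), cfg)
        b = normalize(_spec(7.0 * y), cfg)
        assert np.allclose(a.absorbance, b.absorbance, atol=1e-14)

    def test_minmax_range(self):
        rng = np.random.default_rng(4)
        cfg = PreprocessConfig(normalization="minmax")
        out = normalize(_spec(rng.normal(size=GRID.size)), cfg)
        assert out.absorbance.min() == pytest.approx(0.0)
        assert out.absorbance.max() == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize(_spec(np.zeros(GRID.size)), PreprocessConfig())
        with pytest.raises(ValueError, match="constant"):
            normalize(_spec(np.ones(GRID.size)), PreprocessConfig(normalization="minmax"))


class TestSmooth:
    def test_constant_unchanged(self):
        cfg = PreprocessConfig(smoothing="savitzky_golay")
        out = smooth(_spec(np.full(GRID.size, 2.5)), cfg)
        assert np.allclose(out.absorbance, 2.5, atol=1e-12)

    def test_disabled_is_identity(self, gaussian_spectrum):
        out = smooth(gaussian_spectrum, PreprocessConfig())
        assert out is gaussian_spectrum

    def test_quadratic_reproduced_exactly(self):
        # a Savitzky-Golay filter of order 2 reproduces quadratics exactly
        x = (GRID - GRID.mean()) / 1000.0
        y = 1.0 + 0.5 * x + 0.25 * x**2
        cfg = PreprocessConfig(
            smoothing="savitzky_golay", smoothing_window=7, smoothing_order=2
        )
        out = smooth(_spec(y), cfg)
        assert np.allclose(out.absorbance, y, atol=1e-9)

    def test_nonuniform_grid_rejected(self):
        s = Spectrum(np.array([1.0, 2.0, 4.0, 8.0, 16.0, 17.0, 18.0]), np.ones(7))
        cfg = PreprocessConfig(smoothing="savitzky_golay")
        with pytest.raises(ValueError, match="resample_to_grid"):
            smooth(s, cfg)

    def test_invalid_window_config_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            PreprocessConfig(smoothing="savitzky_golay", smoothing_window=6)
        with pytest.raises(ValueError, match="order"):
            PreprocessConfig(
                smoothing="savitzky_golay", smoothing_window=5, smoothing_order=5
            )


class TestWindow:
    def test_default_band_has_76_points(self, gaussian_spectrum):
        out = extract_window(gaussian_spectrum, (950.0, 1100.0))
        assert len(out) == 76
        assert out.wavenumbers[0] == 950.0 and out.wavenumbers[-1] == 1100.0

    def test_full_support_is_identity(self, gaussian_spectrum):
        out = extract_window(gaussian_spectrum, (800.0, 3500.0))
        assert np.array_equal(out.absorbance, gaussian_spectrum.absorbance)

    def test_empty_intersection_rejected(self, gaussian_spectrum):
        with pytest.raises(ValueError, match="intersect"):
            extract_window(gaussian_spectrum, (4000.0, 4100.0))


def test_pipeline_second_pass_is_identity():
    """rubberband + vector on a nonnegative spectrum: reapplying changes nothing.

    After hull subtraction the spectrum touches zero at its hull points, so a
    second hull subtraction removes ~nothing, and the norm is already 1.
    """
    rng = np.random.default_rng(5)
    y = np.exp(-((GRID - 1030.0) ** 2) / 128.0) + 0.01 * rng.random(GRID.size)
    cfg = PreprocessConfig()
    once = preprocess(_spec(y), cfg)
    twice = preprocess(once, cfg)
    assert np.allclose(once.absorbance, twice.absorbance, atol=1e-10)


def test_windowing_does_not_commute_with_normalization():
    """Regression: normalize over the full range first, then window.

    Windowing first drops out-of-band intensity from the norm and changes the
    scaled values, so the two orders must not be treated as interchangeable.
    """
    # carbohydrate band inside the window plus an amide band well outside it
    y = (
        np.exp(-((GRID - 1030.0) ** 2) / (2 * 8.0**2))
        + 0.9 * np.exp(-((GRID - 1655.0) ** 2) / (2 * 14.0**2))
    )
    s = _spec(y)
    cfg = PreprocessConfig()
    band = cfg.analysis_band
    norm_then_window = extract_window(normalize(s, cfg), band)
    window_then_norm = normalize(extract_window(s, band), cfg)
    assert not np.allclose(
        norm_then_window.absorbance, window_then_norm.absorbance, atol=1e-6
    )
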