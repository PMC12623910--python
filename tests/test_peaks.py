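"""Lamellar peak detection/fitting, d-spacings and the offset intensity model."""

import numpy as np
import pytest

from mesokit.peaks import (
    classify_pattern,
    d_spacing,
    detect_peaks,
    fit_peaks,
    label_harmonics,
    lamellar_intensity_ratio,
    pseudo_voigt,
    scherrer_length,
    two_component_decompose,
)


class TestDSpacing:
    @pytest.mark.parametrize(
        "q,order,expected,tol",
        [
            (1.35, 1, 4.65, 0.01),  # intermolecular distance from the halo
            (0.43, 2, 29.0, 0.5),  # solvent-evaporated interlayer repeat
            (0.45, 2, 28.0, 0.5),  # vitrified interlayer repeat
            (0.21, 1, 30.0, 0.5),  # lamellar periodicity from the (001)
            (2 * np.pi, 1, 1.0, 1e-12),
        ],
    )
    def test_values(self, q, order, expected, tol):
        assert d_spacing(q, order) == pytest.approx(expected, abs=tol)

    def test_harmonic_linearity_exact(self):
        for l in (1, 2, 3, 5):
            assert d_spacing(0.43, l) == l * d_spacing(0.43, 1)

    @pytest.mark.parametrize("q,order", [(0.0, 1), (-1.0, 1), (0.4, 0)])
    def test_rejects_invalid(self, q, order):
        with pytest.raises(ValueError):
            d_spacing(q, order)


class TestPseudoVoigt:
    @pytest.mark.parametrize("eta", [0.0, 0.3, 1.0])
    def test_height_and_fwhm_exact(self, eta):
        c, h, w = 0.43, 2.0, 0.05
        assert pseudo_voigt(c, c, h, w, eta) == pytest.approx(h)
        # at +/- fwhm/2 the profile is exactly half height for any eta
        assert pseudo_voigt(c + w / 2, c, h, w, eta) == pytest.approx(h / 2, rel=1e-12)
        assert pseudo_voigt(c - w / 2, c, h, w, eta) == pytest.approx(h / 2, rel=1e-12)


def _three_peak_curve(q, noise_rng=None, heights=(1.0, 2.0, 0.5)):
    y = 1.0 + sum(
        pseudo_voigt(q, c, h, 0.03, 0.5)
        for c, h in zip((0.21, 0.43, 0.65), heights)
    )
    if noise_rng is not None:
        y = y * (1 + 0.01 * noise_rng.standard_normal(len(q)))
    return y


class TestDetectPeaks:
    def test_three_peaks_within_grid_step(self):
        q = np.arange(0.15, 1.0, 0.002)
        centers = detect_peaks(q, _three_peak_curve(q), min_prominence=0.1)
        assert len(centers) == 3
        for found, true in zip(centers, (0.21, 0.43, 0.65)):
            assert abs(found - true) <= 0.002

    def test_flat_curve_yields_nothing(self):
        q = np.linspace(0.1, 1.0, 200)
        assert detect_peaks(q, np.ones_like(q), min_prominence=0.01) == []

    def test_overlapping_identical_peaks_merge(self):
        q = np.arange(0.2, 0.7, 0.002)
        y = pseudo_voigt(q, 0.42, 1.0, 0.05, 0.5) + pseudo_voigt(q, 0.44, 1.0, 0.05, 0.5)
        centers = detect_peaks(q, y, min_prominence=0.1)
        assert len(centers) == 1
        assert abs(centers[0] - 0.43) < 0.01


class TestFitPeaks:
    def test_noiseless_self_consistency(self):
        q = np.arange(0.3, 0.6, 0.001)
        true = dict(center=0.435, height=1.7, fwhm=0.041, eta=0.37)
        y = 0.2 + pseudo_voigt(q, true["center"], true["height"], true["fwhm"], true["eta"])
        fit = fit_peaks(q, y, [0.44])
        assert fit.converged
        p = fit.peaks[0]
        assert p.center == pytest.approx(true["center"], rel=1e-6)
        assert p.amplitude == pytest.approx(true["height"], rel=1e-6)
        assert p.fwhm == pytest.approx(true["fwhm"], rel=1e-6)
        assert p.eta == pytest.approx(true["eta"], abs=1e-5)
        assert fit.residual_rms < 1e-9

    def test_scale_equivariance(self):
        q = np.arange(0.15, 1.0, 0.002)
        y = _three_peak_curve(q)
        k = 37.5
        f1 = fit_peaks(q, y, [0.21, 0.43, 0.65])
        f2 = fit_peaks(q, k * y, [0.21, 0.43, 0.65])
        for p1, p2 in zip(f1.peaks, f2.peaks):
            assert p2.center == pytest.approx(p1.center, rel=1e-9)
            assert p2.fwhm == pytest.approx(p1.fwhm, rel=1e-9)
            assert p2.amplitude == pytest.approx(k * p1.amplitude, rel=1e-9)
        assert f2.residual_rms == pytest.approx(k * f1.residual_rms, rel=1e-6, abs=1e-12)

    def test_center_accuracy_under_noise(self):
        # two-peak pattern, 1% multiplicative noise, many replicates
        q = np.arange(0.3, 0.8, 0.002)
        errors = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = (
                1.0
                + pseudo_voigt(q, 0.43, 2.0, 0.03, 0.5)
                + pseudo_voigt(q, 0.65, 0.6, 0.03, 0.5)
            ) * (1 + 0.01 * rng.standard_normal(len(q)))
            fit = fit_peaks(q, y, [0.43, 0.65])
            errors.append(abs(fit.peaks[0].center - 0.43))
        assert np.median(errors) < 0.002

    def test_harmonic_labels_and_relation(self, reduced_presets):
        sf = reduced_presets["SE-ITZ-20"]["sf"]
        centers = detect_peaks(sf.q, sf.s, q_window=(0.17, 0.85), min_prominence=0.02)
        fit = label_harmonics(fit_peaks(sf.q, sf.s, centers, q_window=(0.17, 0.85)))
        labels = [p.label for p in fit.peaks]
        assert labels == ["001", "002", "003"]
        fundamentals = [p.center / p.order for p in fit.peaks]
        assert max(fundamentals) / min(fundamentals) - 1 < 0.01

    def test_amplitude_ratio_between_presets(self, reduced_presets):
        heights = {}
        for name, data in reduced_presets.items():
            sf = data["sf"]
            centers = detect_peaks(sf.q, sf.s, q_window=(0.17, 0.85), min_prominence=0.02)
            fit = label_harmonics(fit_peaks(sf.q, sf.s, centers, q_window=(0.17, 0.85)))
            heights[name] = fit.peak("002").amplitude
        ratio = heights["SE-ITZ-20"] / heights["V-ITZ"]
        assert ratio == pytest.approx(3.0, rel=0.1)


class TestTwoComponentDecompose:
    def _blend(self, q, sharp_h=1.0, broad_h=0.6):
        return (
            0.1
            + pseudo_voigt(q, 0.42, sharp_h, 0.012, 0.5)
            + pseudo_voigt(q, 0.44, broad_h, 0.055, 0.5)
        )

    def test_recovers_components_with_width_ordering(self):
        q = np.arange(0.36, 0.52, 0.0005)
        fit = two_component_decompose(q, self._blend(q))
        sharp, broad = fit.peak("sharp"), fit.peak("broad")
        assert sharp.fwhm < broad.fwhm
        assert sharp.center == pytest.approx(0.42, abs=0.002)
        assert broad.center == pytest.approx(0.44, abs=0.005)
        assert sharp.fwhm == pytest.approx(0.012, rel=0.05)
        assert broad.fwhm == pytest.approx(0.055, rel=0.05)

    def test_single_component_degenerates(self):
        q = np.arange(0.36, 0.52, 0.0005)
        y = 0.1 + pseudo_voigt(q, 0.43, 1.0, 0.015, 0.5)
        fit = two_component_decompose(q, y, centers_init=(0.42, 0.44))
        broad = fit.peak("broad")
        # the broad component collapses to (near) zero amplitude
        assert broad.amplitude < 0.05 * fit.peak("sharp").amplitude or fit.residual_rms < 1e-6

    def test_swapped_initialization_converges_to_same_answer(self):
        q = np.arange(0.36, 0.52, 0.0005)
        y = self._blend(q)
        f1 = two_component_decompose(q, y, centers_init=(0.42, 0.44))
        f2 = two_component_decompose(q, y, centers_init=(0.44, 0.42))
        assert f1.peak("sharp").center == pytest.approx(f2.peak("sharp").center, abs=1e-4)
        assert f1.peak("sharp").fwhm == pytest.approx(f2.peak("sharp").fwhm, rel=1e-2)


class TestLamellarIntensityRatio:
    def test_zero_offset_is_profile_limit(self):
        assert lamellar_intensity_ratio(0.0, 29.0, 1.0, 0.5) == pytest.approx(0.25)

    def test_strictly_decreasing_in_offset(self):
        sigmas = np.linspace(0, 3, 20)
        vals = [lamellar_intensity_ratio(s, 29.0, 1.0, 0.5) for s in sigmas]
        assert np.all(np.diff(vals) < 0)

    def test_half_value_offset_closed_form(self):
        d = 29.0
        q1, q2 = 2 * np.pi / d, 4 * np.pi / d
        sigma_half = np.sqrt(np.log(2) / (q2**2 - q1**2))
        full = lamellar_intensity_ratio(0.0, d, 1.0, 0.7)
        assert lamellar_intensity_ratio(sigma_half, d, 1.0, 0.7) == pytest.approx(
            0.5 * full, rel=1e-12
        )

    def test_rejects_zero_first_amplitude(self):
        with pytest.raises(ValueError):
            lamellar_intensity_ratio(0.1, 29.0, 0.0, 0.5)


class TestScherrer:
    def test_reciprocal_width(self):
        assert scherrer_length(0.0286) == pytest.approx(2 * np.pi / 0.0286)
        with pytest.raises(ValueError):
            scherrer_length(0.0)


class TestClassifier:
    def test_sharp_vs_broad_peaks(self):
        q = np.arange(0.2, 1.2, 0.002)
        sharp = 0.1 + pseudo_voigt(q, 0.7, 2.0, 0.010, 0.5)
        broad = 0.1 + pseudo_voigt(q, 0.7, 2.0, 0.040, 0.5)
        assert classify_pattern(q, sharp, q_window=(0.3, 1.1)) == "crystalline"
        assert classify_pattern(q, broad, q_window=(0.3, 1.1)) == "liquid_crystal"
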