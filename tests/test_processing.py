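"""Integration, noise estimation and baseline correction."""

import numpy as np
import pytest

from qnmr import (
    AcquisitionParams,
    IntegrationRegion,
    InvalidParameterError,
    MixtureSpec,
    Spectrum,
    area_ratio,
    baseline_correct,
    estimate_noise,
    integrate_region,
    synthesize_spectrum,
)
from qnmr.errors import QnmrError
from qnmr.processing import DEFAULT_NOISE_REGION


def flat_spectrum(value=0.0, n=4096, high=12.0, low=-2.0):
    ppm = np.linspace(high, low, n)
    return Spectrum(ppm=ppm, intensity=np.full(n, value))


def lorentzian_spectrum(center=5.0, fwhm_ppm=0.01, height=1.0, n=65536):
    ppm = np.linspace(12.0, -2.0, n)
    half = fwhm_ppm / 2
    y = height * half**2 / ((ppm - center) ** 2 + half**2)
    return Spectrum(ppm=ppm, intensity=y)


class TestEstimateNoise:
    def test_constant_spectrum_zero(self):
        assert estimate_noise(flat_spectrum(3.0), DEFAULT_NOISE_REGION) == pytest.approx(0.0)

    def test_linear_ramp_removed_by_detrending(self):
        sp = flat_spectrum()
        sp.intensity = 2.5 * sp.ppm + 1.0
        assert estimate_noise(sp, DEFAULT_NOISE_REGION) == pytest.approx(0.0, abs=1e-9)

    def test_recovers_generator_sigma(self):
        rng = np.random.default_rng(42)
        n = 20000
        ppm = np.linspace(11.0, 9.0, n)
        sp = Spectrum(ppm=ppm, intensity=rng.normal(0, 0.05, n))
        est = estimate_noise(sp, IntegrationRegion("w", high_ppm=10.9, low_ppm=9.1))
        assert est == pytest.approx(0.05, rel=0.05)

    def test_refuses_overlap_with_analytical_region(self):
        sp = flat_spectrum()
        analytical = IntegrationRegion("5.91", high_ppm=10.2, low_ppm=10.1)
        with pytest.raises(InvalidParameterError, match="overlap"):
            estimate_noise(sp, DEFAULT_NOISE_REGION, exclude_regions=(analytical,))

    def test_too_few_points_rejected(self):
        sp = flat_spectrum(n=64)  # ~2 points land in a 0.5 ppm window
        with pytest.raises(InvalidParameterError, match="16"):
            estimate_noise(sp, DEFAULT_NOISE_REGION)


class TestBaselineCorrect:
    anchors = (
        IntegrationRegion("a1", high_ppm=11.5, low_ppm=10.5),
        IntegrationRegion("a2", high_ppm=0.5, low_ppm=-0.5),
        IntegrationRegion("a3", high_ppm=4.6, low_ppm=4.4),
    )

    def test_zero_baseline_unchanged(self):
        sp = lorentzian_spectrum(n=8192)
        out = baseline_correct(sp, self.anchors, poly_degree=2)
        # tails of the unit-height line reach the anchors at the 1e-5 level
        assert np.allclose(out.intensity, sp.intensity, atol=1e-4)

    def test_degree_zero_removes_constant_offset(self):
        sp = flat_spectrum(7.0)
        out = baseline_correct(sp, self.anchors, poly_degree=0)
        assert np.allclose(out.intensity, 0.0, atol=1e-9)

    def test_quadratic_baseline_recovered_areas(self, system, regions):
        analyte, standard = system
        spec = MixtureSpec(
            components=((analyte, 5.0), (standard, 5.0)),
            baseline_coeffs=(0.05, -0.4, 2.0),  # 0.05 x^2 − 0.4 x + 2
        )
        raw = synthesize_spectrum(spec)
        clean = synthesize_spectrum(
            MixtureSpec(components=((analyte, 5.0), (standard, 5.0)))
        )
        corrected = baseline_correct(
            raw,
            (
                IntegrationRegion("a1", high_ppm=11.5, low_ppm=10.0),
                IntegrationRegion("a2", high_ppm=0.5, low_ppm=-0.5),
                IntegrationRegion("a3", high_ppm=4.7, low_ppm=4.3),
            ),
            poly_degree=2,
        )
        for label in ("5.91", "8.72"):
            a_clean = integrate_region(clean, regions[label], noise_region=None).area
            a_corr = integrate_region(corrected, regions[label], noise_region=None).area
            assert a_corr == pytest.approx(a_clean, rel=0.005)

    def test_insufficient_anchor_points_rejected(self):
        sp = flat_spectrum(n=512)
        anchor = IntegrationRegion("a", high_ppm=10.2, low_ppm=10.1)  # ~4 points
        with pytest.raises(InvalidParameterError):
            baseline_correct(sp, (anchor,), poly_degree=5)


class TestIntegrateRegion:
    def test_lorentzian_closed_form(self):
        # unit-height Lorentzian: integral = (pi/2) * FWHM * height
        fwhm = 0.01
        sp = lorentzian_spectrum(fwhm_ppm=fwhm, height=1.0)
        reg = IntegrationRegion("L", high_ppm=5.0 + 60 * fwhm, low_ppm=5.0 - 60 * fwhm)
        res = integrate_region(sp, reg, noise_region=None)
        assert res.area == pytest.approx(np.pi / 2 * fwhm, rel=0.006)
        assert res.peak_height == pytest.approx(1.0, rel=1e-3)

    def test_all_zero_spectrum(self):
        res = integrate_region(
            flat_spectrum(), IntegrationRegion("z", high_ppm=6.0, low_ppm=5.0)
        )
        assert res.area == 0.0
        assert res.snr == 0.0

    def test_additive_over_partition(self):
        sp = lorentzian_spectrum()
        # split exactly on grid points so the partition shares one sample
        hi, mid, lo = (float(sp.ppm[i]) for i in (20000, 32768, 40000))
        whole = integrate_region(
            sp, IntegrationRegion("w", high_ppm=hi, low_ppm=lo), noise_region=None
        ).area
        left = integrate_region(
            sp, IntegrationRegion("l", high_ppm=mid, low_ppm=lo), noise_region=None
        ).area
        right = integrate_region(
            sp, IntegrationRegion("r", high_ppm=hi, low_ppm=mid), noise_region=None
        ).area
        assert left + right == pytest.approx(whole, rel=1e-9)

    def test_widening_region_monotone_toward_closed_form(self):
        fwhm = 0.01
        sp = lorentzian_spectrum(fwhm_ppm=fwhm)
        closed = np.pi / 2 * fwhm
        areas = [
            integrate_region(
                sp,
                IntegrationRegion("w", high_ppm=5.0 + k * fwhm, low_ppm=5.0 - k * fwhm),
                noise_region=None,
            ).area
            for k in (10, 30, 100, 300)
        ]
        assert all(a < b for a, b in zip(areas, areas[1:]))
        assert all(a < closed for a in areas)

    def test_region_outside_axis_rejected(self):
        sp = flat_spectrum()
        with pytest.raises(QnmrError):
            integrate_region(sp, IntegrationRegion("out", high_ppm=15.0, low_ppm=14.0))

    def test_zero_width_region_rejected(self):
        with pytest.raises(InvalidParameterError):
            IntegrationRegion("bad", high_ppm=5.0, low_ppm=5.0)

    def test_snr_scales_inversely_with_sigma(self, system):
        analyte, standard = system
        reg = IntegrationRegion("5.91", high_ppm=5.99, low_ppm=5.83)
        products = []
        for sigma in (0.05, 0.1, 0.2):
            sp = synthesize_spectrum(
                MixtureSpec(
                    components=((analyte, 5.0), (standard, 5.0)),
                    noise_sigma=sigma,
                    seed=99,
                )
            )
            res = integrate_region(sp, reg)
            products.append(res.snr * sigma)
        assert max(products) / min(products) == pytest.approx(1.0, rel=0.02)


class TestAreaRatio:
    def test_simple_and_equal(self):
        reg = IntegrationRegion("r", high_ppm=1.0, low_ppm=0.0)
        from qnmr import IntegralResult

        a = IntegralResult(region=reg, area=3.64, peak_height=1.0, snr=0.0)
        b = IntegralResult(region=reg, area=1.0, peak_height=1.0, snr=0.0)
        assert area_ratio(a, b) == pytest.approx(3.64)
        assert area_ratio(b, b) == 1.0

    def test_zero_standard_area_guarded(self):
        reg = IntegrationRegion("r", high_ppm=1.0, low_ppm=0.0)
        from qnmr import IntegralResult

        a = IntegralResult(region=reg, area=1.0, peak_height=1.0, snr=0.0)
        z = IntegralResult(region=reg, area=0.0, peak_height=0.0, snr=0.0)
        with pytest.raises(QnmrError):
            area_ratio(a, z)
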