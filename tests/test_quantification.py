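"""Internal-standard and external-standard quantification arithmetic."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qnmr import (
    DivisionGuardError,
    GravimetricRecord,
    InvalidParameterError,
    MixtureSpec,
    amount_hplc,
    amount_per_dose,
    make_tablet_spectrum,
    purity_hplc,
    purity_internal_standard,
    quantify_spectrum,
    summarize_signals,
    synthesize_spectrum,
)


@pytest.fixture
def sites(system):
    analyte, standard = system
    return analyte.site("H-12"), standard.site("H-3")


class TestPurityInternalStandard:
    def test_calibration_level_six_hand_oracle(self, system, sites):
        # A_x/A_std = 3.64 at m_std/m_x = 5.00/19.40:
        # 3.64 · (1/2) · (389.4/182.14) · (5.00/19.40) · 100 = 100.2837…
        analyte, standard = system
        x_site, std_site = sites
        grav = GravimetricRecord(m_std=5.00, m_x=19.40, p_std=1.0)
        p = purity_internal_standard(3.64, 1.0, x_site, std_site, analyte, standard, grav)
        assert p == pytest.approx(100.2837, abs=0.005)

    def test_inverted_ratio_gives_exactly_100(self, system, sites):
        analyte, standard = system
        x_site, std_site = sites
        m_std, m_x = 4.2, 7.7
        ratio = (
            (x_site.n_protons / std_site.n_protons)
            * (standard.mol_weight / analyte.mol_weight)
            * (m_x / m_std)
        )
        grav = GravimetricRecord(m_std=m_std, m_x=m_x, p_std=1.0)
        p = purity_internal_standard(ratio, 1.0, x_site, std_site, analyte, standard, grav)
        assert p == pytest.approx(100.0, rel=1e-12)

    def test_zero_mass_guarded(self, system, sites):
        with pytest.raises(DivisionGuardError):
            GravimetricRecord(m_std=5.0, m_x=0.0)

    def test_zero_standard_area_guarded(self, system, sites):
        analyte, standard = system
        x_site, std_site = sites
        grav = GravimetricRecord(m_std=5.0, m_x=5.0)
        with pytest.raises(DivisionGuardError):
            purity_internal_standard(1.0, 0.0, x_site, std_site, analyte, standard, grav)

    def test_bad_standard_purity_rejected(self):
        with pytest.raises(InvalidParameterError):
            GravimetricRecord(m_std=5.0, m_x=5.0, p_std=1.5)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(0.1, 100.0))
    def test_area_scale_invariance(self, system, scale):
        analyte, standard = system
        x_site, std_site = analyte.site("H-12"), standard.site("H-3")
        grav = GravimetricRecord(m_std=5.0, m_x=5.0)
        base = purity_internal_standard(
            0.9, 1.0, x_site, std_site, analyte, standard, grav
        )
        scaled = purity_internal_standard(
            0.9 * scale, 1.0 * scale, x_site, std_site, analyte, standard, grav
        )
        assert scaled == pytest.approx(base, rel=1e-9)


class TestAmountPerDose:
    def test_noiseless_tablet_fixture_recovers_content(self, system, regions):
        spec, spectrum = make_tablet_spectrum(
            system,
            tablet_content_mg=5.0,
            powder_mass_mg=100.0,
            avg_tablet_weight_mg=100.0,
            is_mass_mg=5.0,
        )
        grav = GravimetricRecord(m_std=5.0, m_powder=100.0, avg_tablet_weight=100.0)
        outcome = quantify_spectrum(
            spectrum, system, grav, mode="content", regions=regions, noise_region=None
        )
        assert outcome.result.mean == pytest.approx(5.0, rel=0.01)
        assert outcome.result.units == "mg/dose"

    def test_zero_area_zero_content(self, system, sites):
        analyte, standard = system
        x_site, std_site = sites
        grav = GravimetricRecord(m_std=5.0, m_powder=100.0, avg_tablet_weight=100.0)
        assert amount_per_dose(0.0, 1.0, x_site, std_site, analyte, standard, grav) == 0.0

    def test_doubling_powder_mass_halves_content(self, system, sites):
        analyte, standard = system
        x_site, std_site = sites
        g1 = GravimetricRecord(m_std=5.0, m_powder=100.0, avg_tablet_weight=100.0)
        g2 = GravimetricRecord(m_std=5.0, m_powder=200.0, avg_tablet_weight=100.0)
        a1 = amount_per_dose(0.9, 1.0, x_site, std_site, analyte, standard, g1)
        a2 = amount_per_dose(0.9, 1.0, x_site, std_site, analyte, standard, g2)
        assert a2 == pytest.approx(a1 / 2)

    def test_unit_bridge_with_purity_equation(self, system, sites):
        # m_powder = m_x and T = 100 mg make the content numerically the purity
        analyte, standard = system
        x_site, std_site = sites
        grav_p = GravimetricRecord(m_std=5.0, m_x=7.3)
        grav_c = GravimetricRecord(m_std=5.0, m_powder=7.3, avg_tablet_weight=100.0)
        p = purity_internal_standard(0.8, 1.0, x_site, std_site, analyte, standard, grav_p)
        c = amount_per_dose(0.8, 1.0, x_site, std_site, analyte, standard, grav_c)
        assert c == pytest.approx(p, rel=1e-12)


class TestHplcArithmetic:
    def test_identity_case(self):
        grav = GravimetricRecord(m_s=5.0, m_x=5.0, p_s=0.999)
        assert purity_hplc(1.0, 1.0, grav) == pytest.approx(99.9)

    def test_product_case(self):
        grav = GravimetricRecord(m_s=0.99, m_x=1.0, p_s=1.0)
        assert purity_hplc(1.01, 1.0, grav) == pytest.approx(99.99)

    def test_zero_standard_peak_guarded(self):
        grav = GravimetricRecord(m_s=5.0, m_x=5.0, p_s=0.999)
        with pytest.raises(DivisionGuardError):
            purity_hplc(1.0, 0.0, grav)

    def test_content_trivial_and_t_proportionality(self):
        grav = GravimetricRecord(m_s=5.0, m_powder=100.0, p_s=1.0, avg_tablet_weight=100.0)
        assert amount_hplc(1.0, 1.0, grav) == pytest.approx(5.0)
        half_t = GravimetricRecord(m_s=5.0, m_powder=100.0, p_s=1.0, avg_tablet_weight=50.0)
        assert amount_hplc(1.0, 1.0, half_t) == pytest.approx(2.5)

    def test_agrees_with_internal_standard_content_on_same_fixture(
        self, system, regions
    ):
        # both routes reduce to the true tablet content on a noiseless sample
        spec, spectrum = make_tablet_spectrum(system, tablet_content_mg=5.0)
        grav = GravimetricRecord(m_std=5.0, m_powder=100.0, avg_tablet_weight=100.0)
        qnmr_content = quantify_spectrum(
            spectrum, system, grav, mode="content", regions=regions, noise_region=None
        ).result.mean
        # external-standard route: a reference injection of known mass
        grav_h = GravimetricRecord(
            m_s=5.0, m_powder=100.0, p_s=1.0, avg_tablet_weight=100.0
        )
        hplc_content = amount_hplc(ax_peak=5.0, as_peak=5.0, grav=grav_h)
        assert qnmr_content == pytest.approx(hplc_content, rel=0.01)


class TestSummarizeSignals:
    def test_three_signal_mean_from_published_row(self):
        res = summarize_signals({"8.72": 99.87, "8.45": 100.04, "7.82": 100.21})
        assert res.mean == pytest.approx(100.04, abs=0.005)
        assert res.n == 3

    def test_single_signal_rsd_zero_with_n_flag(self):
        res = summarize_signals({"8.72": 99.5})
        assert res.mean == 99.5
        assert res.rsd_percent == 0.0
        assert res.n == 1

    def test_equal_values_zero_rsd(self):
        res = summarize_signals({"a": 100.0, "b": 100.0, "c": 100.0})
        assert res.rsd_percent == 0.0

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            summarize_signals({})
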