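"""Deconvolution and Nernst equilibration-plot analysis."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from flavochar import redox_potentiometry as rp
from flavochar import synthetic_data as sd


@pytest.fixture
def eps():
    return rp.ExtinctionMatrix.two_wavelength()


@pytest.fixture
def truth():
    return sd.EquilibrationTruth(e_enzyme_mV=-138.0, e_dye_mV=-125.0)


def make_fractions(truth, times=None):
    times = np.linspace(1.0, 40.0, 40) if times is None else times
    f_red_e, f_red_d = sd.equilibrate_fractions(truth, times)
    return rp.FractionSeries(
        times_min=times, f_ox_enzyme=1.0 - f_red_e, f_ox_dye=1.0 - f_red_d,
        clipped=np.zeros(times.size, bool),
    )


class TestDeconvolve:
    def test_diagonal_eps_fully_oxidized(self):
        """No spectral overlap, oxidized sample: both fractions are 1."""
        eps = rp.ExtinctionMatrix(
            wavelengths_nm=(450.0, 610.0),
            eps=np.array([[10.0, 0.0], [0.0, 0.0], [0.0, 20.0], [0.0, 0.0]]),
        )
        series = rp.AbsorbanceSeries(
            times_min=np.array([0.0]),
            absorbance=np.array([[10.0 * 65 / 1000, 20.0 * 40 / 1000]]),
            flavin_total_uM=65.0, dye_total_uM=40.0,
        )
        fr = rp.deconvolve(series, eps)
        assert fr.f_ox_enzyme[0] == pytest.approx(1.0)
        assert fr.f_ox_dye[0] == pytest.approx(1.0)

    def test_zero_absorbance_means_fully_reduced(self, eps):
        series = rp.AbsorbanceSeries(
            times_min=np.array([0.0]), absorbance=np.zeros((1, 2)),
            flavin_total_uM=65.0, dye_total_uM=40.0,
        )
        fr = rp.deconvolve(series, eps)
        assert fr.f_ox_enzyme[0] == 0.0 and fr.f_ox_dye[0] == 0.0

    def test_round_trip_overlapping_eps(self, truth, eps, noiseless):
        """Noiseless deconvolution recovers generator fractions to 1e-9."""
        times = np.linspace(1.0, 40.0, 25)
        series = sd.gen_equilibration(truth, eps, times, noiseless)
        fr = rp.deconvolve(series, eps)
        f_red_e, f_red_d = sd.equilibrate_fractions(truth, times)
        np.testing.assert_allclose(fr.f_ox_enzyme, 1.0 - f_red_e, atol=1e-9)
        np.testing.assert_allclose(fr.f_ox_dye, 1.0 - f_red_d, atol=1e-9)

    def test_reprojection_reproduces_absorbance(self, truth, eps, noiseless):
        """Fractions projected back through eps give the input matrix."""
        times = np.linspace(1.0, 40.0, 25)
        series = sd.gen_equilibration(truth, eps, times, noiseless)
        fr = rp.deconvolve(series, eps)
        conc = np.column_stack([
            truth.flavin_total_uM * fr.f_ox_enzyme,
            truth.flavin_total_uM * (1 - fr.f_ox_enzyme),
            truth.dye_total_uM * fr.f_ox_dye,
            truth.dye_total_uM * (1 - fr.f_ox_dye),
        ])
        back = conc @ (eps.eps / 1000.0)
        np.testing.assert_allclose(back, series.absorbance, atol=1e-12)

    def test_singular_eps_rejected(self):
        eps = rp.ExtinctionMatrix(
            wavelengths_nm=(450.0, 610.0),
            eps=np.array([[10.0, 5.0], [0.0, 0.0], [10.0, 5.0], [0.0, 0.0]]),
        )
        series = rp.AbsorbanceSeries(
            times_min=np.array([0.0]), absorbance=np.array([[0.5, 0.25]]),
            flavin_total_uM=65.0, dye_total_uM=40.0,
        )
        with pytest.raises(ValueError, match="condition"):
            rp.deconvolve(series, eps)


class TestEquilibrationFit:
    def test_slope_unity_for_equal_electron_couples(self, truth):
        fit = rp.equilibration_fit(make_fractions(truth), truth.e_dye_mV)
        assert fit.slope == pytest.approx(1.000, abs=1e-6)

    def test_slope_two_for_two_vs_one_electron(self):
        truth = sd.EquilibrationTruth(e_enzyme_mV=-225.0, e_dye_mV=-225.0,
                                      n_F=2, n_D=1)
        fit = rp.equilibration_fit(make_fractions(truth), truth.e_dye_mV,
                                   n_F=2, n_D=1)
        assert fit.slope == pytest.approx(2.000, abs=1e-6)

    def test_intercept_matches_nernst_prediction(self, truth):
        """Intercept = n_F (E_enz - E_dye) / nu = -0.44 for this pair."""
        fit = rp.equilibration_fit(make_fractions(truth), truth.e_dye_mV)
        assert fit.intercept == pytest.approx(2 * (-138 + 125) / 59.0, abs=1e-6)
        assert fit.intercept == pytest.approx(-0.45, abs=0.01)

    def test_recovers_enzyme_midpoint(self, truth):
        fit = rp.equilibration_fit(make_fractions(truth), truth.e_dye_mV)
        assert fit.e_m_mV == pytest.approx(-138.0, abs=0.1)

    @pytest.mark.parametrize("e_enz,e_dye", [
        (-138.0, -125.0), (-212.0, -225.0), (-100.0, -240.0), (-250.0, -110.0),
    ])
    def test_midpoint_exact_for_any_separation(self, e_enz, e_dye):
        """Recovery < 0.1 mV for separations up to 150 mV either way.

        Two n=2 couples only co-occupy the default 0.1-0.9 window when
        their midpoints lie within ~56 mV, so widely separated pairs are
        fit with a wider window - harmless on noiseless data, where the
        log ratios stay exact out to the ends.
        """
        truth = sd.EquilibrationTruth(e_enzyme_mV=e_enz, e_dye_mV=e_dye)
        window = (0.1, 0.9) if abs(e_enz - e_dye) < 50 else (1e-4, 1 - 1e-4)
        fr = make_fractions(truth, np.linspace(0.25, 41.0, 800))
        fit = rp.equilibration_fit(fr, e_dye, window=window)
        assert abs(fit.e_m_mV - e_enz) < 0.1

    def test_free_flavin_control_with_anthraquinone(self):
        """A free-FMN-style run against AQS recovers the set midpoint."""
        aqs = rp.get_dye("anthraquinone_2_sulfonate")
        truth = sd.EquilibrationTruth(e_enzyme_mV=-212.0, e_dye_mV=aqs.e0_mV,
                                      flavin_total_uM=50.0)
        fit = rp.equilibration_fit(make_fractions(truth), aqs.e0_mV,
                                   n_F=2, n_D=aqs.n)
        assert fit.e_m_mV == pytest.approx(-212.0, abs=0.1)

    def test_too_few_window_points_rejected(self, truth):
        fr = make_fractions(truth, np.array([0.1, 39.0, 41.0]))
        with pytest.raises(ValueError, match="usable points"):
            rp.equilibration_fit(fr, truth.e_dye_mV)


class TestPotentialFromIntercept:
    def test_worked_calculation(self):
        """-125 + (59/2)(-0.45) = -138.275 mV."""
        assert rp.potential_from_intercept(-125.0, -0.45, 2) == pytest.approx(
            -138.275, abs=1e-12)

    def test_zero_intercept_returns_dye_potential(self):
        assert rp.potential_from_intercept(-310.0, 0.0, 1) == -310.0

    def test_phenosafranin_inversion(self):
        """Inverting the formula at E_m = -225 against phenosafranin."""
        assert rp.potential_from_intercept(-252.0, 0.915, 2) == pytest.approx(
            -225.0, abs=0.01)

    @given(st.floats(-400, 0), st.floats(-3, 3), st.floats(-3, 3),
           st.floats(0.1, 0.9))
    def test_affine_in_intercept(self, e_dye, i1, i2, lam):
        """E(convex mix of intercepts) = convex mix of E's."""
        mix = rp.potential_from_intercept(e_dye, lam * i1 + (1 - lam) * i2, 2)
        parts = (lam * rp.potential_from_intercept(e_dye, i1, 2)
                 + (1 - lam) * rp.potential_from_intercept(e_dye, i2, 2))
        assert mix == pytest.approx(parts, rel=1e-9, abs=1e-9)


class TestDyeLibrary:
    def test_default_midpoints(self):
        lib = rp.dye_library()
        assert lib["indigo_carmine"].e0_mV == -125.0
        assert lib["phenosafranin"].e0_mV == -252.0
        assert lib["anthraquinone_2_sulfonate"].e0_mV == -225.0

    def test_unknown_dye_raises(self):
        with pytest.raises(KeyError, match="unknown reference dye"):
            rp.get_dye("methylene_blue")

    def test_user_override_wins(self):
        custom = {"indigo_carmine": rp.DyeRef("indigo_carmine", -120.0, 2)}
        assert rp.get_dye("indigo_carmine", custom).e0_mV == -120.0
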