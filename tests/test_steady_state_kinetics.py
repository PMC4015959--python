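"""Michaelis–Menten / ping-pong fitting and derived kinetic quantities."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from flavochar import steady_state_kinetics as ssk
from flavochar import synthetic_data as sd

from oracles import grid_mm

#: printed kinetic table used for the internal-consistency check:
#: variant -> (Km µM, kcat s^-1, kcat/Km mM^-1 s^-1)
KINETIC_TABLE = {
    "wild_type": (22, 258, 11727),
    "E77A": (180, 17.9, 99),
    "E77K": (30, 0.75, 25),
    "E77L": (250, 0.072, 0.29),
    "E77M": (420, 2.5, 6.0),
    "Y78A": (40, 196, 4900),
    "R80E": (30, 0.275, 9.2),
    "R80K": (350, 9.5, 27),
    "R80M": (780, 0.302, 0.39),
    "R80L": (580, 0.142, 0.24),
    "R95A": (20, 146, 7292),
    "R95E": (70, 21.1, 302),
    "S113A": (60, 76.7, 1278),
    "G115F": (410, 2.2, 5.4),
    "G115I": (630, 1.7, 2.7),
    "G118F": (85, 77, 906),
    "G118I": (38, 12, 316),
}


def _ulp(x: float) -> float:
    """Magnitude of the least significant printed digit of x."""
    s = f"{x:g}"
    if "." in s:
        return 10.0 ** -len(s.split(".")[1])
    return 1.0


class TestRateFromA340:
    def test_zero_slope(self):
        assert ssk.rate_from_a340(0.0) == 0.0

    def test_unit_conversion(self):
        """0.373 A/min over 1 cm is 1.0 µM NADH per second."""
        assert ssk.rate_from_a340(0.373, 1.0) == pytest.approx(1.0, abs=1e-3)

    def test_doubling_path_halves_velocity(self):
        assert ssk.rate_from_a340(0.373, 2.0) == pytest.approx(
            ssk.rate_from_a340(0.373, 1.0) / 2.0)


class TestFitMM:
    def test_noiseless_round_trip(self, noiseless):
        data = sd.gen_rates_mm(22.0, 258.0, 0.01,
                               np.array([2.0, 5, 10, 20, 50, 100, 200, 500]),
                               noiseless)
        fit = ssk.fit_mm(data)
        assert fit.km_uM == pytest.approx(22.0, rel=1e-6)
        assert fit.kcat_s == pytest.approx(258.0, rel=1e-6)

    def test_agrees_with_grid_oracle(self, noiseless):
        data = sd.gen_rates_mm(22.0, 258.0, 0.01,
                               np.array([2.0, 5, 10, 20, 50, 100, 200, 500]),
                               noiseless)
        fit = ssk.fit_mm(data)
        km_grid, vmax_grid = grid_mm(data.substrate_uM, data.velocity,
                                     data.enzyme_total_uM,
                                     np.arange(18.0, 26.0, 0.05))
        assert abs(fit.km_uM - km_grid) <= 0.05

    def test_exact_half_saturation_point_consistent(self, noiseless):
        """Data containing v(S=Km) = Vmax/2 fits back to the same Km."""
        data = sd.gen_rates_mm(22.0, 258.0, 0.01,
                               np.array([22.0, 5.0, 50.0, 200.0, 1000.0]),
                               noiseless)
        fit = ssk.fit_mm(data)
        vmax = fit.kcat_s * data.enzyme_total_uM
        v_at_km = vmax * fit.km_uM / (fit.km_uM + fit.km_uM)
        assert v_at_km == pytest.approx(vmax / 2.0)

    def test_recovery_median_km_error_under_10pct_at_5pct_noise(self):
        errs = []
        s = np.array([2.0, 5, 10, 20, 50, 100, 200, 500])
        for seed in range(100):
            data = sd.gen_rates_mm(22.0, 258.0, 0.01, s,
                                   sd.SimConfig(seed=seed, noise_rel=0.05))
            errs.append(abs(ssk.fit_mm(data).km_uM - 22.0) / 22.0)
        assert np.median(errs) < 0.10


class TestSpecificity:
    @pytest.mark.parametrize("km,kcat,expect", [
        (22.0, 258.0, 11727), (40.0, 196.0, 4900), (1000.0, 1.0, 1.0),
    ])
    def test_printed_values(self, km, kcat, expect):
        assert ssk.specificity(km, kcat) == pytest.approx(expect, abs=0.5)

    @given(st.floats(0.1, 1000), st.floats(0.01, 1000), st.floats(0.1, 100))
    def test_homogeneous_in_kcat(self, km, kcat, c):
        assert ssk.specificity(km, c * kcat) == pytest.approx(
            c * ssk.specificity(km, kcat), rel=1e-9)

    def test_table_internal_consistency(self):
        """Every printed kcat/Km cell is consistent with its Km and kcat.

        The quotient of printed (rounded) inputs must land within the
        printed cell's rounding, allowing for the inputs' own half-ulp
        rounding intervals (some cells were evidently computed from
        unrounded fit values).
        """
        for variant, (km, kcat, spec) in KINETIC_TABLE.items():
            km_h, kcat_h = _ulp(km) / 2, _ulp(kcat) / 2
            lo = ssk.specificity(km + km_h, kcat - kcat_h)
            hi = ssk.specificity(km - km_h, kcat + kcat_h)
            tol = _ulp(spec)
            assert lo - tol <= spec <= hi + tol, variant


class TestFitPingPong:
    def test_noiseless_round_trip(self, noiseless, fig6_design):
        a, b = fig6_design
        data = sd.gen_rates_pingpong(50.0, 33.0, 111.0, 0.061, a, b, noiseless)
        fit = ssk.fit_pingpong(data)
        assert fit.kcat_s == pytest.approx(50.0, rel=1e-6)
        assert fit.ka_uM == pytest.approx(33.0, rel=1e-6)
        assert fit.kb_uM == pytest.approx(111.0, rel=1e-6)

    def test_parallelism_zero_for_pingpong(self, noiseless, fig6_design):
        a, b = fig6_design
        data = sd.gen_rates_pingpong(50.0, 33.0, 111.0, 0.061, a, b, noiseless)
        assert ssk.fit_pingpong(data).parallelism_stat == pytest.approx(0.0,
                                                                        abs=1e-9)

    def test_ternary_law_detected_as_non_parallel(self, noiseless, fig6_design):
        """Sequential-mechanism data triggers the mechanism warning."""
        a, b = fig6_design
        data = sd.gen_rates_ternary(50.0, 33.0, 111.0, 0.061, a, b, noiseless,
                                    kia_uM=100.0)
        with pytest.warns(UserWarning, match="ping-pong mechanism"):
            fit = ssk.fit_pingpong(data)
        assert fit.parallelism_stat > 0.15

    def test_reduces_to_mm_at_saturating_b(self, noiseless):
        """B = 100*Kb: per-level MM fit agrees with ping-pong Ka within 1%."""
        a = np.array([3.0, 8, 15, 33, 70, 150, 400, 900])
        b_sat = np.array([111.0 * 100])
        pp = sd.gen_rates_pingpong(50.0, 33.0, 111.0, 0.061, a,
                                   np.array([111.0 * 100, 111.0 * 200,
                                             111.0 * 400]), noiseless)
        m = pp.b_uM == b_sat[0]
        mm = ssk.fit_mm(ssk.RateDataset(substrate_uM=pp.a_uM[m],
                                        velocity=pp.velocity[m],
                                        enzyme_total_uM=0.061))
        assert mm.km_uM == pytest.approx(33.0, rel=0.01)
        assert mm.kcat_s == pytest.approx(50.0, rel=0.01)

    def test_requires_enough_levels(self, noiseless):
        data = sd.gen_rates_pingpong(50.0, 33.0, 111.0, 0.061,
                                     np.array([5.0, 20, 80, 300]),
                                     np.array([10.0, 50.0]), noiseless)
        with pytest.raises(ValueError, match="levels of substrate B"):
            ssk.fit_pingpong(data)


class TestDerivedQuantities:
    def test_kcat_from_specific_activity(self):
        """1111 µmol/min/mg at 21412 Da per subunit is 396.5 -> 397 s^-1."""
        k = ssk.kcat_from_specific_activity(1111.0, 21412.0)
        assert k == pytest.approx(396.5, abs=0.05)
        assert ssk.kcat_from_specific_activity(0.0, 21412.0) == 0.0
        assert ssk.kcat_from_specific_activity(60.0, 60000.0) == pytest.approx(60.0)

    def test_kie_values(self):
        assert ssk.kie(258.0, 258.0).value == 1.0
        assert ssk.kie(258.0, 47.3).value == pytest.approx(5.45, abs=0.01)
        assert ssk.kie(147.0, 77.4).value == pytest.approx(1.9, abs=0.01)

    def test_kie_se_propagation(self):
        r = ssk.kie(100.0, 50.0, se_h=2.0, se_d=1.0)
        assert r.se == pytest.approx(2.0 * np.sqrt(0.02**2 + 0.02**2))

    def test_activity_ratios(self):
        assert ssk.activity_ratio(50.0, 50.0).value == 1.0
        assert ssk.activity_ratio(50.0, 146.0).value == pytest.approx(0.34,
                                                                      abs=0.005)
        assert ssk.activity_ratio(1.5, 258.0).value == pytest.approx(0.006,
                                                                     abs=0.0005)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            ssk.kie(100.0, 0.0)
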