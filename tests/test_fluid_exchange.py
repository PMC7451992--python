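"""Starling-exchange closed forms, interstitial compliance and mass balance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cardiorenal.fluid_exchange as fx
from cardiorenal.parameters import ParameterSet

P = ParameterSet()
MMHG_PA = 133.322387415


class TestColloidOsmoticPressure:
    def test_zero_concentration(self):
        assert fx.colloid_osmotic_pressure(0.0) == 0.0

    def test_hand_evaluated_polynomial(self):
        # 1.629*7 + 0.2935*49, evaluated by hand
        assert fx.colloid_osmotic_pressure(7.0) == pytest.approx(
            25.7845, abs=1e-12)

    @given(st.floats(0.1, 15.0), st.floats(0.1, 15.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_increasing_and_convex(self, a, b):
        lo, hi = sorted((a, b))
        if hi - lo < 1e-6:
            return
        f = fx.colloid_osmotic_pressure
        assert f(hi) > f(lo)
        mid = 0.5 * (lo + hi)
        assert f(mid) < 0.5 * (f(lo) + f(hi)) + 1e-12

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            fx.colloid_osmotic_pressure(-1.0)


class TestSodiumOsmoticPressure:
    def test_zero(self):
        assert fx.sodium_osmotic_pressure(0.0) == 0.0

    def test_vant_hoff_unit_conversion_oracle(self):
        # independent oracle: pi = C*R*T Pa, 1 mmHg = 133.322... Pa
        expected_pa = 140.0 * 8.314 * 310.0
        assert fx.sodium_osmotic_pressure(140.0) == pytest.approx(
            expected_pa / MMHG_PA, rel=1e-12)

    def test_equal_concentrations_cancel_in_filtration(self):
        phi = fx.filtration_rate(10.0, 10.0, 5.0, 5.0,
                                 fx.sodium_osmotic_pressure(140.0),
                                 fx.sodium_osmotic_pressure(140.0))
        assert phi == pytest.approx(0.0, abs=1e-12)


class TestInterstitialPressure:
    def test_branch_point_continuity_after_refit(self):
        eps = 1e-9
        above = fx.interstitial_pressure(15.0 + eps)
        below = fx.interstitial_pressure(15.0 - eps)
        assert above == pytest.approx(below, abs=1e-6)

    def test_branch_point_slope_continuity(self):
        h = 1e-6
        s_above = (fx.interstitial_pressure(15.0 + 2 * h)
                   - fx.interstitial_pressure(15.0 + h)) / h
        s_below = (fx.interstitial_pressure(15.0 - h)
                   - fx.interstitial_pressure(15.0 - 2 * h)) / h
        assert s_above == pytest.approx(s_below, rel=1e-3)

    def test_expansion_branch_printed_form(self):
        # A*exp(B*V) - C with printed constants, by hand at V=20
        assert fx.interstitial_pressure(20.0) == pytest.approx(
            0.01 * math.exp(0.25 * 20.0) + 0.72, rel=1e-12)

    def test_monotone_nondecreasing(self):
        v = np.linspace(6.0, 35.0, 400)
        pvals = [fx.interstitial_pressure(x) for x in v]
        assert np.all(np.diff(pvals) >= -1e-12)

    def test_strain_stiffening_on_expansion_branch(self):
        # d2P/dV2 > 0 for V >= 15
        v = np.linspace(15.0, 35.0, 100)
        pvals = np.array([fx.interstitial_pressure(x) for x in v])
        assert np.all(np.diff(pvals, 2) > 0)

    def test_congestion_raises_pressure(self):
        assert (fx.interstitial_pressure(23.47)
                > fx.interstitial_pressure(15.0))

    def test_out_of_range_warns(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="cardiorenal.fluid_exchange"):
            fx.interstitial_pressure(4.0)
        assert any("extrapolating" in r.message for r in caplog.records)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            fx.interstitial_pressure(0.0)


class TestFiltrationRate:
    def test_balanced_terms_give_zero(self):
        # P_c - P_if exactly offsets the osmotic differences
        assert fx.filtration_rate(10.0, 2.0, 20.0, 12.0, 2700.0, 2700.0) \
            == pytest.approx(0.0, abs=1e-12)

    def test_unit_driving_pressure_gives_kf(self):
        assert fx.filtration_rate(1.0, 0, 0, 0, 0, 0) == pytest.approx(6.67)

    def test_antisymmetry(self):
        f = fx.filtration_rate(12, 3, 25, 14, 2710, 2700)
        g = fx.filtration_rate(3, 12, 14, 25, 2700, 2710)
        assert f == pytest.approx(-g, rel=1e-12)


class TestAdvanceFluids:
    def _state(self):
        return fx.CompartmentFluids(bv=4.9, ifv=15.0, na_blood=397.9,
                                    na_if=2100.0, protein_blood=198.9,
                                    protein_if=706.4)

    def test_equilibrium_is_fixed_point(self):
        s = self._state()
        s2 = fx.advance_fluids(s, phi_fr=0.0, urine_flow=1e-3,
                               intake=1e-3, dt=10.0)
        assert s2.bv == s.bv and s2.ifv == s.ifv

    def test_water_conservation_over_many_random_steps(self):
        # telescoping-sum oracle: Delta(BV+IFV) == sum (intake-urine)*dt
        rng = np.random.default_rng(12345)
        s = self._state()
        total0 = s.bv + s.ifv
        net = 0.0
        for _ in range(10_000):
            phi = rng.uniform(-5e-4, 5e-4)
            urine = rng.uniform(0.5e-3, 1.5e-3)
            intake = rng.uniform(0.5e-3, 1.5e-3)
            dt = rng.uniform(0.1, 10.0)
            s = fx.advance_fluids(s, phi, urine, intake, dt)
            net += (intake - urine) * dt
        assert (s.bv + s.ifv) - total0 == pytest.approx(net, abs=1e-9)

    def test_step_rejection_names_diagnostics(self):
        s = self._state()
        with pytest.raises(ValueError, match="rejected"):
            fx.advance_fluids(s, phi_fr=0.0, urine_flow=1.0, intake=0.0,
                              dt=1e5)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            fx.advance_fluids(self._state(), 0.0, 0.0, 0.0, 0.0)


def test_refit_constants_continuous_with_printed_expansion():
    a_con, c_con = fx.refit_contraction_constants(P)
    v0 = P.ifv_branch
    expansion = P.a_if_ex * math.exp(P.b_if_ex * v0) - P.c_if_ex
    contraction = -a_con * math.exp(P.b_if_con * (v0 - 12.0)) + c_con
    assert contraction == pytest.approx(expansion, rel=1e-12)
    assert a_con < 0  # matches the printed sign convention
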