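"""Renal hemodynamics, tubular handling and SGLT2 pharmacology."""

import numpy as np
import pytest

import cardiorenal as cr
from cardiorenal.fluid_exchange import colloid_osmotic_pressure
from cardiorenal.kidney import (gfr, proximal_glucose_reabsorption,
                                renal_steady, sodium_water_excretion)
from cardiorenal.neurohormonal import NeurohormonalState, effector_outputs

P = cr.default_parameters()
EFF = effector_outputs(NeurohormonalState(), P)
PI_C = colloid_osmotic_pressure(7.0)


class TestGFR:
    def test_healthy_setpoint(self):
        g, rbf, pgc = gfr(P.map_ref, P, EFF, PI_C)
        assert g == pytest.approx(95.8, rel=0.01)
        assert 800 < rbf < 1300
        assert 45 < pgc < 65

    def test_nephron_loss_equivalent_to_kf_scaling(self):
        # halving the nephron fraction at fixed single-nephron function is
        # exactly halving the whole-kidney ultrafiltration coefficient
        g_n, _, _ = gfr(P.map_ref, P.copy(nephron_frac=0.5), EFF, PI_C)
        g_k, _, _ = gfr(P.map_ref, P.copy(kf_glom=P.kf_glom / 2), EFF, PI_C)
        assert g_n == pytest.approx(g_k, rel=1e-10)
        assert g_n < 95.8

    def test_preafferent_resistance_lowers_gfr(self):
        g_hi, _, _ = gfr(P.map_ref, P.copy(r_preaff=25.5), EFF, PI_C)
        g_lo, _, _ = gfr(P.map_ref, P, EFF, PI_C)
        assert g_hi < g_lo

    def test_afferent_narrowing_lowers_gfr(self):
        g_hi, _, _ = gfr(P.map_ref, P.copy(d_aa=1.55e-5), EFF, PI_C)
        g_lo, _, _ = gfr(P.map_ref, P, EFF, PI_C)
        assert g_hi < g_lo

    def test_unphysiological_map_rejected(self):
        with pytest.raises(ValueError):
            gfr(30.0, P, EFF, PI_C)

    def test_zero_filtration_pressure_returns_zero(self):
        g, _, _ = gfr(45.0, P, EFF, pi_plasma=60.0)
        assert g == 0.0


class TestGlucoseHandling:
    def test_subthreshold_spill_negligible(self):
        filtered = 95.8 * 5.5 / 1000.0
        reab, spill = proximal_glucose_reabsorption(filtered, P)
        assert spill < 1e-3
        assert reab == pytest.approx(filtered, rel=1e-2)

    def test_full_blockade_spills_filtered_load(self):
        p = P.copy(tm_sglt1=0.0)
        reab, spill = proximal_glucose_reabsorption(0.5, p,
                                                    sglt2_inhibition=1.0)
        assert spill == pytest.approx(0.5, abs=0.02)
        assert reab >= 0.0

    def test_mass_balance(self):
        for load in (0.1, 0.5, 1.0, 3.0):
            reab, spill = proximal_glucose_reabsorption(load, P,
                                                        sglt2_inhibition=0.5)
            assert reab + spill == pytest.approx(load, rel=1e-12)
            assert reab >= 0 and spill >= 0

    def test_diabetic_load_spills_more_under_inhibition(self):
        p = P.copy(sglt2_inhibition=0.95)
        _, uge_h = proximal_glucose_reabsorption(95.8 * 5.5 / 1000, p)
        _, uge_d = proximal_glucose_reabsorption(95.8 * 8.0 / 1000, p)
        assert uge_d > 1.5 * uge_h


class TestSodiumWaterExcretion:
    def test_setpoint_closure(self):
        urine_na, urine_flow, md = sodium_water_excretion(
            95.8, 140.0, P.map_ref, EFF, uge=0.0, p=P)
        assert urine_na == pytest.approx(P.na_intake, rel=2e-3)
        assert urine_flow == pytest.approx(P.water_intake0, rel=2e-2)
        assert md == pytest.approx(P.md_ref, rel=2e-3)

    def test_pressure_natriuresis_slope_positive(self):
        lo, _, _ = sodium_water_excretion(95.8, 140.0, P.map_ref - 5, EFF,
                                          0.0, P)
        hi, _, _ = sodium_water_excretion(95.8, 140.0, P.map_ref + 5, EFF,
                                          0.0, P)
        assert hi > lo

    def test_excretion_bounded_by_filtration(self):
        urine_na, _, _ = sodium_water_excretion(95.8, 140.0, 150.0, EFF,
                                                0.0, P)
        assert 0.0 <= urine_na <= 95.8 * 140.0 / 1000.0

    def test_glucose_osmotic_drag_raises_excretion(self):
        dry, flow_dry, _ = sodium_water_excretion(95.8, 140.0, P.map_ref,
                                                  EFF, 0.0, P)
        wet, flow_wet, _ = sodium_water_excretion(95.8, 140.0, P.map_ref,
                                                  EFF, 0.3, P)
        assert wet > dry
        assert flow_wet > flow_dry


class TestRenalSteady:
    def test_setpoint_self_consistency(self):
        ro = renal_steady(P.map_ref, 140.0, PI_C, EFF, P)
        assert ro.gfr == pytest.approx(95.8, rel=0.01)
        assert ro.urine_na == pytest.approx(P.na_intake, rel=5e-3)
        assert ro.uge * 1440 < 0.5   # essentially aglucosuric

    def test_sglt2i_is_natriuretic_diuretic_and_dips_gfr(self):
        base = renal_steady(P.map_ref, 140.0, PI_C, EFF, P)
        drug = renal_steady(P.map_ref, 140.0, PI_C, EFF,
                            P.copy(sglt2_inhibition=0.95))
        assert drug.urine_na > base.urine_na
        assert drug.urine_flow > base.urine_flow
        assert drug.uge > base.uge + 0.1
        assert drug.gfr < base.gfr   # TGF-mediated acute dip

    def test_sglt2i_gfr_dip_larger_in_diabetic(self):
        h0 = renal_steady(P.map_ref, 140.0, PI_C, EFF, P)
        h1 = renal_steady(P.map_ref, 140.0, PI_C, EFF,
                          P.copy(sglt2_inhibition=0.95))
        d = P.copy(c_glu=8.0)
        d0 = renal_steady(P.map_ref, 140.0, PI_C, EFF, d)
        d1 = renal_steady(P.map_ref, 140.0, PI_C, EFF,
                          d.copy(sglt2_inhibition=0.95))
        assert (d0.gfr - d1.gfr) > (h0.gfr - h1.gfr)
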