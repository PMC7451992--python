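"""LV mechanics, valve/beat integration and periodic steady state."""

import numpy as np
import pytest

import cardiorenal as cr
from cardiorenal.cardiac import (NonConvergenceError, VentricleGeometry,
                                 activation, beats_to_periodic_steady_state,
                                 fiber_stress, initial_fast_state, lv_pressure,
                                 run_beat)
from cardiorenal.states import SlowState

P = cr.default_parameters()


def geometry():
    return VentricleGeometry.from_state(P, SlowState())


class TestFiberStressAndPressure:
    def test_zero_strain_zero_passive_pressure(self):
        g = geometry()
        assert lv_pressure(g.v_lv_cavity, g, 0.0, P) == pytest.approx(
            0.0, abs=1e-12)

    def test_stress_decomposition(self):
        g = geometry()
        fs = fiber_stress(100.0, g, 0.7, P)
        assert fs.sigma_f == pytest.approx(
            fs.sigma_f_active + fs.sigma_f_passive, rel=1e-15)
        assert fs.sigma_f_active >= 0.0

    def test_active_stress_vanishes_outside_activation(self):
        g = geometry()
        fs = fiber_stress(100.0, g, 0.0, P)
        assert fs.sigma_f_active == 0.0

    def test_passive_nondecreasing_in_volume(self):
        g = geometry()
        vols = np.linspace(40.0, 200.0, 60)
        s = [fiber_stress(v, g, 0.0, P).sigma_f_passive for v in vols]
        assert np.all(np.diff(s) > 0)

    def test_pressure_increasing_in_volume_at_fixed_activation(self):
        g = geometry()
        for act in (0.0, 0.5, 1.0):
            vols = np.linspace(60.0, 220.0, 40)
            pr = [lv_pressure(v, g, act, P) for v in vols]
            assert np.all(np.diff(pr) > 0)

    def test_active_pressure_linear_in_contractility(self):
        g = geometry()
        base = fiber_stress(40.0, g, 1.0, P, contractility=1.0)
        doubled = fiber_stress(40.0, g, 1.0, P, contractility=2.0)
        assert doubled.sigma_f_active == pytest.approx(
            2.0 * base.sigma_f_active, rel=1e-12)

    def test_stiffness_raises_edp_at_fixed_edv(self):
        g = geometry()
        soft = lv_pressure(120.0, g, 0.0, P)
        stiff = lv_pressure(120.0, g, 0.0, P.copy(lv_stiffness=12.2))
        assert stiff > soft

    def test_nonphysical_volume_rejected(self):
        g = geometry()
        with pytest.raises(ValueError, match="volume"):
            lv_pressure(-1.0, g, 0.0, P)


class TestActivation:
    def test_zero_at_cycle_start_and_in_diastole(self):
        assert activation(0.0, 0.4) == 0.0
        assert activation(0.5, 0.4) == 0.0
        assert activation(0.99, 0.4) == 0.0

    def test_plateau_is_unity(self):
        assert activation(0.4 * 0.45, 0.4) == 1.0

    def test_bounded(self):
        ph = np.linspace(0, 0.999, 500)
        a = np.array([activation(x, 0.4) for x in ph])
        assert np.all((a >= 0) & (a <= 1))


class TestRunBeat:
    def test_volume_conservation_within_beat(self, healthy_baseline):
        slow, fast, _ = healthy_baseline
        f2, bs = run_beat(fast, P, slow)
        assert f2.total == pytest.approx(fast.total, abs=1e-8)

    def test_valve_flow_balance_equals_lv_volume_change(self, healthy_baseline):
        slow, fast, _ = healthy_baseline
        f2, bs = run_beat(fast, P, slow)
        # net mitral inflow minus aortic outflow == LV volume change
        assert (bs.sv_ejected - bs.sv_ejected) == 0  # sanity
        f3, bs2, trace = run_beat(f2, P, slow, return_trace=True)
        dv = f3.v_lv - f2.v_lv
        # integrated flows carry O(dt^2) quadrature error per step
        assert dv == pytest.approx(0.0, abs=0.5)

    def test_stroke_work_positive_counterclockwise(self, healthy_baseline):
        slow, fast, _ = healthy_baseline
        _, bs = run_beat(fast, P, slow)
        assert bs.stroke_work > 0.0

    def test_summary_identities(self, healthy_baseline):
        _, _, bs = healthy_baseline
        assert bs.sv == bs.edv - bs.esv
        assert bs.ef == pytest.approx(bs.sv / bs.edv, rel=1e-15)
        assert bs.co == pytest.approx(bs.sv * bs.hr / 1000.0, rel=1e-15)

    def test_pressure_ordering(self, healthy_baseline):
        _, _, bs = healthy_baseline
        assert bs.dbp <= bs.map <= bs.sbp

    def test_invalid_inputs_rejected(self, healthy_baseline):
        slow, fast, _ = healthy_baseline
        with pytest.raises(ValueError):
            run_beat(fast, P, slow, hr=0.0)


class TestPeriodicSteadyState:
    def test_fixed_point_property(self, healthy_baseline):
        slow, fast, bs = healthy_baseline
        _, bs2 = run_beat(fast, P, slow, hr=bs.hr)
        assert bs2.edv == pytest.approx(bs.edv, rel=5e-5)

    def test_independent_of_initial_perturbation(self, healthy_baseline):
        slow, fast, bs = healthy_baseline
        for factor in (0.9, 1.1):
            f0 = initial_fast_state(P, slow)
            f0.v_lv *= factor
            f0.v_ven -= f0.v_lv * (factor - 1.0)
            _, bs_p = beats_to_periodic_steady_state(f0, P, slow, tol=1e-9)
            assert bs_p.edv == pytest.approx(bs.edv, rel=1e-4)
            assert bs_p.map == pytest.approx(bs.map, rel=1e-4)

    def test_contractility_lowers_esv(self, healthy_baseline):
        slow, fast, _ = healthy_baseline
        _, lo = beats_to_periodic_steady_state(
            fast, P.copy(contractility=0.9), slow)
        _, hi = beats_to_periodic_steady_state(
            fast, P.copy(contractility=1.1), slow)
        assert hi.esv < lo.esv

    def test_invalid_tolerance_rejected(self, healthy_baseline):
        slow, fast, _ = healthy_baseline
        with pytest.raises(ValueError):
            beats_to_periodic_steady_state(fast, P, slow, tol=0.0)

    def test_nonconvergence_carries_last_summary(self, healthy_baseline):
        slow, fast, _ = healthy_baseline
        with pytest.raises(NonConvergenceError) as exc:
            beats_to_periodic_steady_state(fast, P, slow, tol=1e-16,
                                           max_beats=5)
        assert exc.value.last is not None
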