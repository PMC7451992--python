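"""Growth-law hand evaluations, caps and remodeling patterns."""

import math

import numpy as np
import pytest

from cardiorenal.parameters import ParameterSet
from cardiorenal.remodeling import (MyocytePopulation, WallComposition,
                                    cavity_volume, d_dD_dt, d_dL_dt,
                                    myocyte_volume, wall_volume)

P = ParameterSet()


def pop(dd=0.0, dl=0.0):
    return MyocytePopulation.from_params(P, dd=dd, dl=dl)


class TestDiameterGrowth:
    def test_setpoint_rate_is_zero(self):
        assert d_dD_dt(P.sigma_peak_ref, pop(), P) == 0.0

    def test_doubled_stress_at_zero_offset_gives_kd0(self):
        # hand evaluation: K_d = K_d0*(max-0)/max, ratio term = 1
        assert d_dD_dt(2 * P.sigma_peak_ref, pop(), P) == pytest.approx(
            P.k_d0, rel=1e-12)

    def test_growth_saturates_at_cap(self):
        full = pop(dd=P.d_myo0)   # dD = dD_max = D_myo0
        assert d_dD_dt(2 * P.sigma_peak_ref, full, P) == 0.0

    def test_regression_branch_uses_uncapped_rate(self):
        r = d_dD_dt(0.5 * P.sigma_peak_ref, pop(dd=0.5 * P.d_myo0), P)
        assert r == pytest.approx(P.k_d0 * (0.5 - 1.0), rel=1e-12)

    def test_atrophy_floor(self):
        floored = pop(dd=-P.dd_floor_frac * P.d_myo0)
        assert d_dD_dt(0.5 * P.sigma_peak_ref, floored, P) == 0.0

    def test_invalid_reference_rejected(self):
        with pytest.raises(ValueError):
            d_dD_dt(1.0, pop(), P.copy(sigma_peak_ref=0.0))


class TestLengthGrowth:
    def test_below_reference_rate_exactly_zero(self):
        # asymmetric law: no length regression
        assert d_dL_dt(0.999 * P.sigma_ed_ref, pop(dl=0.3 * P.l_myo0), P) == 0.0

    def test_setpoint_rate_is_zero(self):
        assert d_dL_dt(P.sigma_ed_ref, pop(), P) == 0.0

    def test_hand_evaluated_half_capacity(self):
        # sigma = 1.5 ref, dL = dL_max/2: K_l = K_l0/2, ratio-1 = 0.5
        r = d_dL_dt(1.5 * P.sigma_ed_ref, pop(dl=0.5 * P.l_myo0), P)
        assert r == pytest.approx(0.25 * P.k_l0, rel=1e-12)

    def test_growth_saturates_at_cap(self):
        assert d_dL_dt(3 * P.sigma_ed_ref, pop(dl=P.l_myo0), P) == 0.0


class TestGeometry:
    def test_cavity_volume_identity_at_zero_offset(self):
        assert cavity_volume(pop(), 60.0) == 60.0

    def test_cavity_volume_doubled_length_is_eightfold(self):
        assert cavity_volume(pop(dl=P.l_myo0), 60.0, 1.0) == pytest.approx(
            480.0, rel=1e-12)

    def test_cavity_volume_cube_law(self):
        # (1.26)^3 = 2.000376
        assert cavity_volume(pop(dl=0.26 * P.l_myo0), 1.0, 1.0) == pytest.approx(
            1.26 ** 3, rel=1e-12)

    def test_cylinder_formula(self):
        q = MyocytePopulation(n_myo=1.0, d_myo0=2.0, l_myo0=4.0)
        # V = pi D^2 L / 4 = 4*pi (in m^3) -> mL conversion factor 1e6
        assert myocyte_volume(q) == pytest.approx(4 * math.pi * 1e6, rel=1e-12)

    def test_diameter_doubling_quadruples_myocyte_volume(self):
        assert myocyte_volume(pop(dd=P.d_myo0)) == pytest.approx(
            4 * myocyte_volume(pop()), rel=1e-12)

    def test_wall_volume_composition_identity(self):
        comp = WallComposition(v_myo=0.0, v_is=0.0, v_f=0.0)
        bare = wall_volume(pop(), comp)
        assert bare == pytest.approx(myocyte_volume(pop()), rel=1e-12)
        assert comp.v_wall == comp.v_myo + comp.v_is + comp.v_f


class TestForwardIntegration:
    @pytest.mark.parametrize("sig_peak_ratio,sig_ed_ratio",
                             [(5.0, 5.0), (50.0, 50.0), (0.0, 0.0)])
    def test_offsets_respect_caps_under_extreme_stress(self, sig_peak_ratio,
                                                       sig_ed_ratio):
        dd, dl = 0.0, 0.0
        dt = 1440.0  # one day in slow-time minutes
        for _ in range(2000):
            q = pop(dd=dd, dl=dl)
            dd += dt * d_dD_dt(sig_peak_ratio * P.sigma_peak_ref, q, P)
            dl += dt * d_dL_dt(sig_ed_ratio * P.sigma_ed_ref, q, P)
            dd = min(max(dd, -P.dd_floor_frac * P.d_myo0), q.dd_max)
            dl = min(dl, q.dl_max)  # explicit-Euler overshoot guard
        assert -P.dd_floor_frac * P.d_myo0 - 1e-12 <= dd <= P.d_myo0 + 1e-12
        assert 0.0 <= dl <= P.l_myo0 + 1e-12

    def test_pure_patterns(self):
        # volume overload only -> eccentric (length grows, diameter at rest)
        assert d_dL_dt(2 * P.sigma_ed_ref, pop(), P) > 0
        assert d_dD_dt(P.sigma_peak_ref, pop(), P) == 0.0
        # pressure overload only -> concentric
        assert d_dD_dt(2 * P.sigma_peak_ref, pop(), P) > 0
        assert d_dL_dt(P.sigma_ed_ref, pop(), P) == 0.0
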