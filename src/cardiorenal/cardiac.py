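"""Beat-resolved left-ventricle and closed-loop circulation model.

The LV is a thick-walled spherical chamber whose cavity pressure follows from
the total myofiber Cauchy stress via the one-fiber relation

    P_lv = sigma_f/3 · ln(1 + V_w/V_cavity),

with sigma_f = sigma_active + sigma_passive.  The fiber stretch
lambda = ((V + V_w/3)/(V_ref + V_w/3))^(1/3) is measured from the (remodeled)
unloaded cavity volume V_ref.  Passive stress is exponential in stretch with
stiffness parameter C_f; active stress is the product of a contractility
scale kappa_C, a sin² activation pulse over the systolic interval, and a
linear length-dependence factor.  Valves are ideal diodes smoothed over a
1e-6 mmHg band; the systemic loop has arterial, peripheral and venous
compartments plus a pulmonary-venous reservoir filled by a lumped right-side
pump whose output is sensitive to its pulmonary afterload.

One beat is integrated with fixed-step RK4 (numba-accelerated when
available), which preserves the circulating-volume invariant exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .neurohormonal import heart_rate
from .parameters import ParameterSet
from .remodeling import MyocytePopulation, cavity_volume, wall_volume
from .states import BeatSummary, FastState, SlowState

__all__ = [
    "VentricleGeometry", "FiberStressState", "ValveState",
    "lv_pressure", "fiber_stress", "activation",
    "run_beat", "beats_to_periodic_steady_state", "initial_fast_state",
    "NonConvergenceError",
]

VALVE_EPS = 1.0e-6   # mmHg, smoothing band of the ideal-diode valves

# kernel parameter vector layout
_NPK = 21
(_V_REF, _V_W, _SIG_P0, _C_F, _SIG_A, _S_L, _T_SYS, _R_AV, _R_MV, _R_PER,
 _C_A, _V_A0, _C_V, _V_V0, _C_PV, _V_PV0, _G_RH, _GAM_RH, _CAP_W, _PERIOD,
 _DT) = range(_NPK)

_NSUM = 14
(_S_EDV, _S_ESV, _S_EDP, _S_MAP, _S_SBP, _S_DBP, _S_PV, _S_PPV, _S_PC,
 _S_SPK, _S_SED, _S_QAV, _S_QMV, _S_WORK) = range(_NSUM)


def _ramp(x: float, eps: float) -> float:
    """Smoothed positive part: C¹ ideal-diode characteristic."""
    return 0.5 * (x + math.sqrt(x * x + eps * eps))


def _deriv(ts: float, a0: float, a1: float, a2: float, a3: float,
           pk: np.ndarray):
    """Instantaneous flows and pressures of the closed loop.

    Returns (dV_lv, dV_a, dV_v, dV_pv, P_lv, P_a, P_v, P_pv, sigma_total,
    sigma_passive, q_av, q_mv); volumes mL, flows mL/s, pressures mmHg.
    """
    if a0 < 1.0:
        a0 = 1.0
    t_sys = pk[_T_SYS]
    act = 0.0
    if 0.0 <= ts < t_sys:
        # rise / plateau / fall twitch (fractions 0.25 / 0.40 / 0.35)
        u = ts / t_sys
        if u < 0.25:
            s = math.sin(math.pi * u / 0.5)
            act = s * s
        elif u < 0.65:
            act = 1.0
        else:
            s = math.cos(math.pi * (u - 0.65) / 0.7)
            act = s * s
    third = pk[_V_W] / 3.0
    lam = ((a0 + third) / (pk[_V_REF] + third)) ** (1.0 / 3.0)
    sig_pas = pk[_SIG_P0] * (math.exp(pk[_C_F] * (lam - 1.0)) - 1.0)
    f_len = 1.0 + pk[_S_L] * (lam - 1.0)
    if f_len < 0.0:
        f_len = 0.0
    sig_act = pk[_SIG_A] * act * f_len
    sig_tot = sig_pas + sig_act
    p_lv = sig_tot * math.log(1.0 + pk[_V_W] / a0) / 3.0
    p_a = (a1 - pk[_V_A0]) / pk[_C_A]
    p_v = (a2 - pk[_V_V0]) / pk[_C_V]
    p_pv = (a3 - pk[_V_PV0]) / pk[_C_PV]

    q_mv = _ramp(p_pv - p_lv, VALVE_EPS) / pk[_R_MV]
    q_av = _ramp(p_lv - p_a, VALVE_EPS) / pk[_R_AV]
    q_per = (p_a - p_v) / pk[_R_PER]
    q_rh = pk[_G_RH] * _ramp(p_v - p_pv / pk[_GAM_RH], VALVE_EPS)

    return (q_mv - q_av, q_av - q_per, q_per - q_rh, q_rh - q_mv,
            p_lv, p_a, p_v, p_pv, sig_tot, sig_pas, q_av, q_mv)


def _beat_core(y: np.ndarray, pk: np.ndarray):
    """Integrate one cardiac cycle with fixed-step RK4.

    Returns (y_end, summary, trace); trace rows are (t_s, V_lv, P_lv, P_a).
    """
    period = pk[_PERIOD]
    n = int(period / pk[_DT] + 0.5)
    if n < 10:
        n = 10
    dt = period / n
    y0, y1, y2, y3 = y[0], y[1], y[2], y[3]

    summ = np.zeros(_NSUM)
    trace = np.empty((n + 1, 4))

    edv = -1.0e30
    esv = 1.0e30
    edp = 0.0
    sbp = -1.0e30
    dbp = 1.0e30
    spk = -1.0e30
    sed = 0.0
    acc_pa = 0.0
    acc_pv = 0.0
    acc_ppv = 0.0
    acc_pc = 0.0
    q_av_tot = 0.0
    q_mv_tot = 0.0
    work = 0.0
    prev_vlv = 0.0
    prev_plv = 0.0
    prev_qav = 0.0
    prev_qmv = 0.0

    for i in range(n + 1):
        t = i * dt
        (d0, d1, d2, d3, p_lv, p_a, p_v, p_pv, sig_tot, sig_pas,
         q_av, q_mv) = _deriv(t, y0, y1, y2, y3, pk)

        trace[i, 0] = t
        trace[i, 1] = y0
        trace[i, 2] = p_lv
        trace[i, 3] = p_a
        wgt = 0.5 if (i == 0 or i == n) else 1.0
        acc_pa += wgt * p_a
        acc_pv += wgt * p_v
        acc_ppv += wgt * p_pv
        acc_pc += wgt * (pk[_CAP_W] * p_a + (1.0 - pk[_CAP_W]) * p_v)
        if p_a > sbp:
            sbp = p_a
        if p_a < dbp:
            dbp = p_a
        if sig_tot > spk:
            spk = sig_tot
        if y0 > edv:
            edv = y0
        if y0 < esv:
            esv = y0
        if i == 0:
            edp = p_lv     # end diastole = activation onset
            sed = sig_pas
        else:
            work += -0.5 * (p_lv + prev_plv) * (y0 - prev_vlv)
            q_av_tot += 0.5 * dt * (q_av + prev_qav)
            q_mv_tot += 0.5 * dt * (q_mv + prev_qmv)
        prev_vlv = y0
        prev_plv = p_lv
        prev_qav = q_av
        prev_qmv = q_mv

        if i < n:
            b0 = y0 + 0.5 * dt * d0
            b1 = y1 + 0.5 * dt * d1
            b2 = y2 + 0.5 * dt * d2
            b3 = y3 + 0.5 * dt * d3
            (e0, e1, e2, e3, _, _, _, _, _, _, _, _) = _deriv(
                t + 0.5 * dt, b0, b1, b2, b3, pk)
            c0 = y0 + 0.5 * dt * e0
            c1 = y1 + 0.5 * dt * e1
            c2 = y2 + 0.5 * dt * e2
            c3 = y3 + 0.5 * dt * e3
            (f0, f1, f2, f3, _, _, _, _, _, _, _, _) = _deriv(
                t + 0.5 * dt, c0, c1, c2, c3, pk)
            g0v = y0 + dt * f0
            g1v = y1 + dt * f1
            g2v = y2 + dt * f2
            g3v = y3 + dt * f3
            (h0, h1, h2, h3, _, _, _, _, _, _, _, _) = _deriv(
                t + dt, g0v, g1v, g2v, g3v, pk)
            y0 += dt / 6.0 * (d0 + 2.0 * e0 + 2.0 * f0 + h0)
            y1 += dt / 6.0 * (d1 + 2.0 * e1 + 2.0 * f1 + h1)
            y2 += dt / 6.0 * (d2 + 2.0 * e2 + 2.0 * f2 + h2)
            y3 += dt / 6.0 * (d3 + 2.0 * e3 + 2.0 * f3 + h3)

    summ[_S_EDV] = edv
    summ[_S_ESV] = esv
    summ[_S_EDP] = edp
    summ[_S_MAP] = acc_pa / n
    summ[_S_SBP] = sbp
    summ[_S_DBP] = dbp
    summ[_S_PV] = acc_pv / n
    summ[_S_PPV] = acc_ppv / n
    summ[_S_PC] = acc_pc / n
    summ[_S_SPK] = spk
    summ[_S_SED] = sed
    summ[_S_QAV] = q_av_tot
    summ[_S_QMV] = q_mv_tot
    summ[_S_WORK] = work
    y_end = np.array([y0, y1, y2, y3])
    return y_end, summ, trace


try:  # optional numba acceleration (pure-Python fallback is identical code)
    from numba import njit as _njit

    _ramp = _njit(cache=True)(_ramp)            # type: ignore[assignment]
    _deriv = _njit(cache=True)(_deriv)          # type: ignore[assignment]
    _beat_core = _njit(cache=True)(_beat_core)  # type: ignore[assignment]
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False


@dataclass
class VentricleGeometry:
    """Spherical-chamber LV geometry (volumes in mL)."""

    v_w: float
    v_lv_cavity: float   # unloaded cavity volume (after remodeling)
    v_lv0: float         # pre-remodeling unloaded cavity volume
    spherical: bool = True

    def __post_init__(self):
        if self.v_w <= 0 or self.v_lv_cavity <= 0:
            raise ValueError("wall and cavity volumes must be positive")

    @classmethod
    def from_state(cls, p: ParameterSet, slow: SlowState) -> "VentricleGeometry":
        pop = MyocytePopulation.from_params(p, slow.dd, slow.dl)
        return cls(v_w=wall_volume(pop, p=p),
                   v_lv_cavity=cavity_volume(pop, p.v_lv0, p.l_scale),
                   v_lv0=p.v_lv0)


@dataclass
class FiberStressState:
    sigma_f: float
    sigma_f_active: float
    sigma_f_passive: float
    contractility_scale: float
    c_f: float


@dataclass
class ValveState:
    mitral_open: bool
    aortic_open: bool
    q_mitral: float   # mL/min
    q_aortic: float   # mL/min


def activation(phase: float, duty: float) -> float:
    """Rise/plateau/fall activation twitch.

    ``phase`` in [0,1) of the cycle, ``duty`` the systolic fraction; within
    systole the twitch rises over the first quarter, holds a plateau, and
    falls over the last 35%.
    """
    ph = phase % 1.0
    if ph >= duty:
        return 0.0
    u = ph / duty
    if u < 0.25:
        return math.sin(math.pi * u / 0.5) ** 2
    if u < 0.65:
        return 1.0
    return math.cos(math.pi * (u - 0.65) / 0.7) ** 2


def fiber_stress(v_cavity: float, geometry: VentricleGeometry, act: float,
                 p: ParameterSet, contractility: float | None = None
                 ) -> FiberStressState:
    """Total/active/passive fiber Cauchy stress (mmHg) at a cavity volume and
    activation level."""
    if v_cavity <= 0:
        raise ValueError(f"non-physical LV cavity volume {v_cavity} mL")
    kappa = p.contractility if contractility is None else contractility
    third = geometry.v_w / 3.0
    lam = ((v_cavity + third) / (geometry.v_lv_cavity + third)) ** (1.0 / 3.0)
    sig_pas = p.sigma_pas0 * (math.exp(p.lv_stiffness * (lam - 1.0)) - 1.0)
    f_len = max(0.0, 1.0 + p.act_len_slope * (lam - 1.0))
    sig_act = kappa * p.sigma_act0 * act * f_len
    return FiberStressState(
        sigma_f=sig_act + sig_pas, sigma_f_active=sig_act,
        sigma_f_passive=sig_pas, contractility_scale=kappa, c_f=p.lv_stiffness)


def lv_pressure(v_cavity: float, geometry: VentricleGeometry, act: float,
                p: ParameterSet, contractility: float | None = None) -> float:
    """Transmural LV pressure (mmHg) via the one-fiber spherical relation."""
    fs = fiber_stress(v_cavity, geometry, act, p, contractility)
    return fs.sigma_f * math.log(1.0 + geometry.v_w / v_cavity) / 3.0


def _kernel_params(p: ParameterSet, slow: SlowState, hr: float) -> np.ndarray:
    pop = MyocytePopulation.from_params(p, slow.dd, slow.dl)
    pk = np.empty(_NPK)
    pk[_V_REF] = cavity_volume(pop, p.v_lv0, p.l_scale)
    pk[_V_W] = wall_volume(pop, p=p)
    pk[_SIG_P0] = p.sigma_pas0
    pk[_C_F] = p.lv_stiffness
    pk[_SIG_A] = p.contractility * p.sigma_act0
    pk[_S_L] = p.act_len_slope
    period = 60.0 / hr
    pk[_T_SYS] = p.t_sys_coeff * math.sqrt(period)
    pk[_R_AV] = p.r_arterial
    pk[_R_MV] = p.r_mitral
    pk[_R_PER] = p.r_peripheral * slow.hormones.tone
    pk[_C_A] = p.c_arterial
    pk[_V_A0] = p.v_art_unstressed
    pk[_C_V] = p.c_venous_eff
    pk[_V_V0] = p.v_ven_unstressed
    pk[_C_PV] = p.c_pulm_ven
    pk[_V_PV0] = p.v_pulm_unstressed
    pk[_G_RH] = p.g_right_heart
    pk[_GAM_RH] = p.rh_backpressure_ratio
    pk[_CAP_W] = p.cap_pressure_weight
    pk[_PERIOD] = period
    pk[_DT] = p.beat_dt
    return pk


def initial_fast_state(p: ParameterSet, slow: SlowState) -> FastState:
    """Partition the circulating blood volume into compartments (cold start)."""
    total = slow.bv * 1000.0 - p.v_circ_fixed
    v_lv = 1.3 * p.v_lv0
    v_a = p.v_art_unstressed + 84.0 * p.c_arterial
    v_pv = p.v_pulm_unstressed + 7.0 * p.c_pulm_ven
    v_v = total - v_lv - v_a - v_pv
    if v_v <= 0:
        raise ValueError("blood volume too small to fill the circulation")
    return FastState(v_lv=v_lv, v_art=v_a, v_ven=v_v, v_pulm=v_pv)


def _enforce_volume(y: np.ndarray, target_total: float) -> np.ndarray:
    """Re-impose the circulating-volume constraint on the venous compartment."""
    y = y.copy()
    y[2] += target_total - y.sum()
    return y


def _summary_from_array(summ: np.ndarray, hr: float) -> BeatSummary:
    return BeatSummary(
        edv=float(summ[_S_EDV]), esv=float(summ[_S_ESV]),
        edp=float(summ[_S_EDP]), map=float(summ[_S_MAP]),
        sbp=float(summ[_S_SBP]), dbp=float(summ[_S_DBP]),
        p_ven=float(summ[_S_PV]), p_pulm_ven=float(summ[_S_PPV]),
        p_cap=float(summ[_S_PC]), sigma_peak=float(summ[_S_SPK]),
        sigma_ed=float(summ[_S_SED]), sv_ejected=float(summ[_S_QAV]),
        stroke_work=float(summ[_S_WORK]), hr=hr)


def run_beat(fast: FastState, p: ParameterSet, slow: SlowState,
             hr: float | None = None, return_trace: bool = False):
    """Integrate one cardiac cycle.

    Returns (FastState, BeatSummary) or, with ``return_trace``, additionally
    the (t_s, V_lv_mL, P_lv_mmHg, P_ao_mmHg) trace array.
    """
    if fast.v_lv <= 0:
        raise ValueError(f"non-physical LV volume {fast.v_lv} mL")
    if hr is None:
        hr = p.hr0
    if hr <= 0:
        raise ValueError("heart period must be positive")
    pk = _kernel_params(p, slow, hr)
    target = slow.bv * 1000.0 - p.v_circ_fixed
    y = _enforce_volume(fast.as_array(), target)
    y_end, summ, trace = _beat_core(y, pk)
    if not np.all(np.isfinite(y_end)):
        raise ArithmeticError(
            f"beat integration failed; state snapshot {y_end}, "
            f"period {pk[_PERIOD]:.3f}s")
    out = FastState.from_array(y_end)
    bs = _summary_from_array(summ, hr)
    if return_trace:
        return out, bs, trace
    return out, bs


class NonConvergenceError(RuntimeError):
    """Beat map failed to reach its periodic fixed point."""

    def __init__(self, msg, last=None, prev=None):
        super().__init__(msg)
        self.last = last
        self.prev = prev


def beats_to_periodic_steady_state(fast: FastState, p: ParameterSet,
                                   slow: SlowState, tol: float | None = None,
                                   max_beats: int | None = None):
    """Iterate the beat map to its periodic fixed point.

    Convergence is declared when EDV, ESV and MAP each change by less than
    ``tol`` (relative) between successive beats.  Heart rate is recomputed
    each beat from the pulmonary-venous congestion of the previous one, and
    the circulating-volume constraint is re-imposed after every beat.
    """
    if tol is None:
        tol = p.beat_tol
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_beats is None:
        max_beats = p.max_beats
    target = slow.bv * 1000.0 - p.v_circ_fixed
    y = _enforce_volume(fast.as_array(), target)
    p_pv0 = max((y[3] - p.v_pulm_unstressed) / p.c_pulm_ven, 0.0)
    hr = heart_rate(p_pv0, p)
    prev_summary = None
    prev_metrics = None
    prev_delta = None
    for _ in range(max_beats):
        pk = _kernel_params(p, slow, hr)
        y_new, summ, _ = _beat_core(y, pk)
        y_new = _enforce_volume(y_new, target)
        delta = y_new - y
        if prev_delta is not None and float(delta @ prev_delta) < 0.0:
            # oscillatory (period-2) mode: damp by averaging, which keeps
            # both the fixed point and the volume constraint
            y_new = 0.5 * (y_new + y)
            delta = y_new - y
        prev_delta = delta
        bs = _summary_from_array(summ, hr)
        hr = heart_rate(bs.p_pulm_ven, p)
        metrics = np.array([bs.edv, bs.esv, bs.map])
        if prev_metrics is not None:
            rel = np.max(np.abs(metrics - prev_metrics)
                         / np.maximum(np.abs(prev_metrics), 1e-9))
            if rel < tol:
                return FastState.from_array(y_new), bs
        prev_summary, prev_metrics = bs, metrics
        y = y_new
    raise NonConvergenceError(
        f"no periodic steady state within {max_beats} beats (tol={tol:g})",
        last=prev_summary, prev=prev_metrics)
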