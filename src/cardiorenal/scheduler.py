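"""Multi-timescale orchestrator.

The within-beat system (milliseconds–seconds) and the day-scale system
(volumes, sodium, hormones, remodeling) are coupled by timescale splitting:
at each macro step the beat map is iterated to its periodic fixed point, its
summary (MAP, capillary pressure, fiber stresses, cardiac output) is frozen
— with first-order sensitivities to blood volume — and the slow ODE system
is integrated across the step with an adaptive implicit method (LSODA).
Naive co-integration of ~37 million beats per simulated year is infeasible;
the split is validated against a per-beat-coupled reference integrator
(:func:`cointegrate_reference`) over a short horizon.

Everything is deterministic: no random numbers appear anywhere in the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import fluid_exchange as fx
from .cardiac import beats_to_periodic_steady_state, initial_fast_state, run_beat
from .interventions import Intervention, apply_intervention
from .kidney import renal_steady
from .neurohormonal import (NeurohormonalState, effector_outputs,
                            raas_derivatives)
from .parameters import ParameterSet
from .remodeling import MyocytePopulation, d_dD_dt, d_dL_dt
from .states import BeatSummary, FastState, SlowState

__all__ = ["Protocol", "RunResult", "run_protocol", "slow_derivatives",
           "pv_loop_snapshot", "cointegrate_reference", "BeatContext"]

MIN_PER_DAY = 1440.0

# absolute tolerances per slow-state component (BV, IFV, Na_b, Na_if,
# 4 hormones, tone, dD, dL)
_ATOL = np.array([1e-7, 1e-7, 1e-5, 1e-5,
                  1e-9, 1e-9, 1e-9, 1e-9, 1e-9, 1e-13, 1e-13])


@dataclass
class Protocol:
    """Simulation protocol: virtual patient, intervention, duration, cadence."""

    patient: str = "healthy"
    intervention: Intervention = field(default_factory=Intervention)
    duration_days: float = 365.0
    slow_step_days: float = 1.0
    output_every_days: float = 1.0
    beat_tol: Optional[float] = None
    slow_rtol: Optional[float] = None

    def __post_init__(self):
        if self.duration_days <= 0:
            raise ValueError("duration_days must be positive")
        if not 0 < self.slow_step_days <= 1.0:
            raise ValueError("slow_step_days must be in (0, 1] days")


@dataclass
class BeatContext:
    """Frozen converged-beat quantities plus first-order sensitivities to
    blood volume and autoregulation tone."""

    bv0: float
    tone0: float
    map0: float
    pc0: float
    co0: float
    sigma_peak: float
    sigma_ed: float
    dmap_dbv: float = 0.0
    dpc_dbv: float = 0.0
    dco_dbv: float = 0.0
    dmap_dtone: float = 0.0
    dpc_dtone: float = 0.0
    dco_dtone: float = 0.0

    @classmethod
    def from_summary(cls, bs: BeatSummary, slow: SlowState,
                     sens: tuple[float, ...] = (0.0,) * 6):
        return cls(bv0=slow.bv, tone0=slow.hormones.tone,
                   map0=bs.map, pc0=bs.p_cap, co0=bs.co,
                   sigma_peak=bs.sigma_peak, sigma_ed=bs.sigma_ed,
                   dmap_dbv=sens[0], dpc_dbv=sens[1], dco_dbv=sens[2],
                   dmap_dtone=sens[3], dpc_dtone=sens[4], dco_dtone=sens[5])


def slow_derivatives(y: np.ndarray, ctx: BeatContext, p: ParameterSet
                     ) -> np.ndarray:
    """Day-scale RHS (per minute) at frozen/linearized beat quantities.

    State layout: [BV, IFV, Na_b, Na_if, renin, angII, aldo, ADH, tone,
    dD, dL].
    """
    # guard against implicit-integrator trial states outside the domain
    bv = max(y[0], 0.5)
    ifv = max(y[1], 0.5)
    na_b = max(y[2], 1.0)
    na_if = max(y[3], 1.0)
    horm = NeurohormonalState(*[max(v, 1e-6) for v in y[4:9]])
    dd, dl = y[9], y[10]

    dbv = bv - ctx.bv0
    dtone = horm.tone - ctx.tone0
    # linearized beat quantities, clamped to the solver-safe range so that
    # implicit-integrator trial states cannot leave the model's domain
    map_ = min(max(ctx.map0 + ctx.dmap_dbv * dbv + ctx.dmap_dtone * dtone,
                   45.0), 215.0)
    p_c = max(ctx.pc0 + ctx.dpc_dbv * dbv + ctx.dpc_dtone * dtone, 0.0)
    co = max(ctx.co0 + ctx.dco_dbv * dbv + ctx.dco_dtone * dtone, 0.5)

    plasma = bv * (1.0 - p.hematocrit)
    c_na_b = na_b / plasma
    c_na_if = na_if / ifv
    pi_c = fx.colloid_osmotic_pressure(p.protein_blood_g / (plasma * 10.0))
    pi_if = fx.colloid_osmotic_pressure(p.protein_if_g / (ifv * 10.0))
    pi_na_c = fx.sodium_osmotic_pressure(c_na_b, p)
    pi_na_if = fx.sodium_osmotic_pressure(c_na_if, p)
    p_if = fx.interstitial_pressure(ifv, p)
    phi_ml = fx.filtration_rate(p_c, p_if, pi_c, pi_if, pi_na_c, pi_na_if, p)
    phi = phi_ml / 1000.0   # L/min

    eff = effector_outputs(horm, p)
    renal = renal_steady(map_, c_na_b, pi_c, eff, p)

    intake_w = p.water_intake0 * min(max(
        0.0, 1.0 + p.thirst_gain * (c_na_b / p.c_na_ref - 1.0)), 10.0)

    d_bv = intake_w - renal.urine_flow - phi
    d_ifv = phi
    c_mid = 0.5 * (c_na_b + c_na_if)
    j_na = phi * c_mid + p.ps_na * (c_na_b - c_na_if)
    d_nab = p.na_intake - renal.urine_na - j_na
    d_naif = j_na

    dr, da, dal, dadh, dtone = raas_derivatives(
        horm, renal.md_na, map_, c_na_b, bv, co, p)

    pop = MyocytePopulation.from_params(p, dd, dl)
    # slack fibers (stress below zero) cannot drive growth; the growth
    # laws are stated per slow-time unit, the clock converts to minutes
    ddd = d_dD_dt(max(ctx.sigma_peak, 0.0), pop, p) / p.remodel_time_unit_min
    ddl = d_dL_dt(max(ctx.sigma_ed, 0.0), pop, p) / p.remodel_time_unit_min

    return np.array([d_bv, d_ifv, d_nab, d_naif,
                     dr, da, dal, dadh, dtone, ddd, ddl])


def beat_sensitivities(fast: FastState, p: ParameterSet, slow: SlowState,
                       bs0: BeatSummary, bump: float = 0.02,
                       tone_bump: float = 0.005) -> tuple[float, ...]:
    """Central-difference sensitivities of (MAP, P_c, CO) to blood volume
    (per litre) and to autoregulation tone.

    Central differences matter: the heart-rate congestion map has strong
    local curvature near the healthy setpoint and a one-sided secant there
    destabilizes the equilibrium polish.
    """
    from dataclasses import replace as _replace

    tol = min(p.beat_tol, 1e-8)

    def at(dbv: float, dtone: float) -> BeatSummary:
        s = slow.copy(bv=slow.bv + dbv,
                      hormones=_replace(slow.hormones,
                                        tone=slow.hormones.tone + dtone))
        _, bs = beats_to_periodic_steady_state(fast, p, s, tol=tol)
        return bs

    b_hi, b_lo = at(bump, 0.0), at(-bump, 0.0)
    t_hi, t_lo = at(0.0, tone_bump), at(0.0, -tone_bump)
    return ((b_hi.map - b_lo.map) / (2 * bump),
            (b_hi.p_cap - b_lo.p_cap) / (2 * bump),
            (b_hi.co - b_lo.co) / (2 * bump),
            (t_hi.map - t_lo.map) / (2 * tone_bump),
            (t_hi.p_cap - t_lo.p_cap) / (2 * tone_bump),
            (t_hi.co - t_lo.co) / (2 * tone_bump))


def _diagnostics(slow: SlowState, bs: BeatSummary, p: ParameterSet) -> dict:
    plasma = slow.bv * (1.0 - p.hematocrit)
    c_na_b = slow.na_blood / plasma
    pi_c = fx.colloid_osmotic_pressure(p.protein_blood_g / (plasma * 10.0))
    pi_if = fx.colloid_osmotic_pressure(p.protein_if_g / (slow.ifv * 10.0))
    pi_na_c = fx.sodium_osmotic_pressure(c_na_b, p)
    pi_na_if = fx.sodium_osmotic_pressure(slow.na_if / slow.ifv, p)
    p_if = fx.interstitial_pressure(slow.ifv, p)
    phi = fx.filtration_rate(bs.p_cap, p_if, pi_c, pi_if, pi_na_c, pi_na_if, p)
    eff = effector_outputs(slow.hormones, p)
    renal = renal_steady(bs.map, c_na_b, pi_c, eff, p)
    return {
        "gfr_ml_min": renal.gfr,
        "urine_na_mmol_day": renal.urine_na * MIN_PER_DAY,
        "urine_flow_l_day": renal.urine_flow * MIN_PER_DAY,
        "uge_mmol_day": renal.uge * MIN_PER_DAY,
        "c_na_mmol_l": c_na_b,
        "p_if_mmhg": p_if,
        "pi_prot_c_mmhg": pi_c,
        "pi_prot_if_mmhg": pi_if,
        "phi_fr_ml_min": phi,
    }


def _record(rows: list, day: float, slow: SlowState, bs: BeatSummary,
            p: ParameterSet) -> None:
    row = {
        "day": day,
        "bv_l": slow.bv, "ifv_l": slow.ifv,
        "na_blood_mmol": slow.na_blood, "na_if_mmol": slow.na_if,
        "renin": slow.hormones.renin, "ang_ii": slow.hormones.ang_ii,
        "aldosterone": slow.hormones.aldosterone, "adh": slow.hormones.adh,
        "tone": slow.hormones.tone,
        "dd_um": slow.dd * 1e6, "dl_um": slow.dl * 1e6,
        "edv_ml": bs.edv, "esv_ml": bs.esv, "sv_ml": bs.sv, "ef": bs.ef,
        "edp_mmhg": bs.edp, "map_mmhg": bs.map, "sbp_mmhg": bs.sbp,
        "dbp_mmhg": bs.dbp, "hr_bpm": bs.hr, "co_l_min": bs.co,
        "p_ven_mmhg": bs.p_ven, "p_pulm_ven_mmhg": bs.p_pulm_ven,
        "p_cap_mmhg": bs.p_cap, "sigma_peak_mmhg": bs.sigma_peak,
        "sigma_ed_mmhg": bs.sigma_ed, "stroke_work_mmhg_ml": bs.stroke_work,
    }
    row.update(_diagnostics(slow, bs, p))
    rows.append(row)


@dataclass
class RunResult:
    """Trajectory plus final states of a protocol run."""

    frame: pd.DataFrame
    slow: SlowState
    fast: FastState
    params: ParameterSet
    protocol: Protocol

    def at_day(self, day: float) -> pd.Series:
        idx = (self.frame["day"] - day).abs().idxmin()
        return self.frame.loc[idx]


def advance(slow: SlowState, fast: FastState, params: ParameterSet,
            days: float, step_days: float = 1.0,
            intervention: Intervention | None = None,
            rows: list | None = None, output_every: float = 1.0,
            beat_tol: float | None = None, slow_rtol: float | None = None,
            sens_refresh_days: float = 14.0, sens_bv_window: float = 0.05,
            day0: float = 0.0) -> tuple[SlowState, FastState, BeatSummary]:
    """Advance the coupled system by ``days``; core macro-step loop.

    Appends output rows (at the requested cadence) to ``rows`` if given.
    Returns the final (slow, fast, converged beat summary).
    """
    rtol = slow_rtol if slow_rtol is not None else params.slow_rtol
    n_steps = max(1, int(round(days / step_days)))
    dt = days / n_steps
    sens = None
    sens_at = (-1e30, 0.0)
    next_out = day0
    bs = None
    for k in range(n_steps):
        day = day0 + k * dt
        p_day = apply_intervention(params, intervention, day)
        fast, bs = beats_to_periodic_steady_state(
            fast, p_day, slow, tol=beat_tol)
        if (sens is None or day - sens_at[0] >= sens_refresh_days
                or abs(slow.bv - sens_at[1]) > sens_bv_window):
            sens = beat_sensitivities(fast, p_day, slow, bs)
            sens_at = (day, slow.bv)
        if rows is not None and day >= next_out - 1e-9:
            _record(rows, day, slow, bs, p_day)
            next_out += output_every
        ctx = BeatContext.from_summary(bs, slow, sens)
        y0 = slow.as_vector()
        sol = solve_ivp(
            lambda t, y: slow_derivatives(y, ctx, p_day),
            (0.0, dt * MIN_PER_DAY), y0, method="LSODA",
            rtol=rtol, atol=_ATOL)
        if not sol.success:
            raise RuntimeError(
                f"slow integration failed at day {day:.2f}: {sol.message}")
        slow = SlowState.from_vector(sol.y[:, -1], day=day + dt)
    # final converged beat at the end state
    p_day = apply_intervention(params, intervention, day0 + days)
    fast, bs = beats_to_periodic_steady_state(fast, p_day, slow, tol=beat_tol)
    if rows is not None:
        _record(rows, day0 + days, slow, bs, p_day)
    return slow, fast, bs


def run_protocol(protocol: Protocol, params: ParameterSet | None = None,
                 initial: tuple[SlowState, FastState] | None = None
                 ) -> RunResult:
    """Run a full protocol from the patient's verified baseline state.

    The baseline (parameters, slow and fast state) is built by the
    virtual-patient module unless supplied explicitly.
    """
    from .virtual_patient import baseline_state, build_patient, get_preset

    if params is None:
        params = build_patient(get_preset(protocol.patient))
    if initial is None:
        slow, fast = baseline_state(protocol.patient)
    else:
        slow, fast = initial
    rows: list = []
    slow, fast, _ = advance(
        slow, fast, params, protocol.duration_days,
        step_days=protocol.slow_step_days,
        intervention=protocol.intervention, rows=rows,
        output_every=protocol.output_every_days,
        beat_tol=protocol.beat_tol, slow_rtol=protocol.slow_rtol)
    frame = pd.DataFrame(rows)
    return RunResult(frame=frame, slow=slow, fast=fast, params=params,
                     protocol=protocol)


def pv_loop_snapshot(result: RunResult, day: float) -> np.ndarray:
    """Converged-beat P-V trace at a recorded day of a finished run.

    Returns an array with columns (t_s, V_lv_mL, P_lv_mmHg, P_ao_mmHg).
    """
    f = result.frame
    if day < f["day"].min() - 1e-9 or day > f["day"].max() + 1e-9:
        raise ValueError(f"day {day} outside recorded trajectory")
    row = result.at_day(day)
    slow = SlowState(
        bv=row["bv_l"], ifv=row["ifv_l"], na_blood=row["na_blood_mmol"],
        na_if=row["na_if_mmol"],
        hormones=NeurohormonalState(row["renin"], row["ang_ii"],
                                    row["aldosterone"], row["adh"],
                                    row["tone"]),
        dd=row["dd_um"] * 1e-6, dl=row["dl_um"] * 1e-6, day=row["day"])
    p_day = apply_intervention(result.params, result.protocol.intervention,
                               row["day"])
    fast = initial_fast_state(p_day, slow)
    fast, bs = beats_to_periodic_steady_state(fast, p_day, slow)
    _, _, trace = run_beat(fast, p_day, slow, hr=bs.hr, return_trace=True)
    return trace


def cointegrate_reference(slow: SlowState, fast: FastState,
                          params: ParameterSet, days: float,
                          intervention: Intervention | None = None,
                          sample_every_beats: int = 200) -> pd.DataFrame:
    """Brute-force reference: fast and slow systems coupled at every beat.

    The slow state is advanced by one explicit step per cardiac cycle using
    that cycle's own summary (no freezing across a macro step, no blood-volume
    linearization).  The slow step (~0.014 min) is far below every slow time
    constant, so this is the near-continuous reference trajectory that the
    timescale-split scheduler is validated against.
    """
    from .neurohormonal import heart_rate

    rows = []
    t_min = 0.0
    beat = 0
    bs = None
    hr = params.hr0
    while t_min < days * MIN_PER_DAY:
        day = t_min / MIN_PER_DAY
        p_day = apply_intervention(params, intervention, day)
        fast, bs = run_beat(fast, p_day, slow, hr=hr)
        hr = heart_rate(bs.p_pulm_ven, p_day)
        dt = 60.0 / bs.hr / 60.0   # beat period in minutes
        ctx = BeatContext.from_summary(bs, slow)
        y = slow.as_vector()
        y = y + dt * slow_derivatives(y, ctx, p_day)
        slow = SlowState.from_vector(y, day=day)
        if beat % sample_every_beats == 0:
            rows.append({"day": day, "bv_l": slow.bv, "ifv_l": slow.ifv,
                         "map_mmhg": bs.map, "edv_ml": bs.edv,
                         "esv_ml": bs.esv, "co_l_min": bs.co})
        t_min += dt
        beat += 1
    rows.append({"day": t_min / MIN_PER_DAY, "bv_l": slow.bv,
                 "ifv_l": slow.ifv, "map_mmhg": bs.map, "edv_ml": bs.edv,
                 "esv_ml": bs.esv, "co_l_min": bs.co})
    return pd.DataFrame(rows)
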