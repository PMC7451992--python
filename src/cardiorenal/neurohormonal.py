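"""RAAS cascade and regulatory feedbacks.

All hormone levels are normalized to 1 at the healthy steady state.  Renin
secretion rises when macula-densa sodium delivery or renal perfusion pressure
falls and is restrained by ANG II short-loop feedback; ANG II formation is
scaled by (1 - ACE inhibition); aldosterone follows ANG II; ADH integrates
plasma osmolality and volume signals.  A slow whole-body autoregulation tone
state scales peripheral resistance toward the cardiac-output target, and a
sympathetic surrogate maps pulmonary-venous congestion to heart rate.
Effector outputs are multiplicative factors equal to 1 at setpoint, bounded
by saturation limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .parameters import ParameterSet

__all__ = ["NeurohormonalState", "update_raas", "effector_outputs", "heart_rate"]


@dataclass
class NeurohormonalState:
    renin: float = 1.0
    ang_ii: float = 1.0
    aldosterone: float = 1.0
    adh: float = 1.0
    tone: float = 1.0          # autoregulation resistance multiplier

    def clamped(self) -> "NeurohormonalState":
        return NeurohormonalState(
            renin=max(self.renin, 1e-6),
            ang_ii=max(self.ang_ii, 1e-6),
            aldosterone=max(self.aldosterone, 1e-6),
            adh=max(self.adh, 1e-6),
            tone=min(max(self.tone, 0.2), 5.0),
        )


def _clamp(x: float, lo: float, hi: float) -> float:
    return min(max(x, lo), hi)


def _bexp(x: float) -> float:
    """exp with a bounded argument (shields integrator trial states)."""
    return math.exp(_clamp(x, -30.0, 30.0))


def renin_secretion_target(state: NeurohormonalState, md_na: float, map_mmhg: float,
                           p: ParameterSet) -> float:
    """Normalized renin secretion: falls with MD Na delivery, perfusion pressure,
    and ANG II short-loop feedback."""
    md_dev = md_na / p.md_ref - 1.0
    rp_dev = map_mmhg / p.map_ref - 1.0
    target = _bexp(-p.md_gain * md_dev - p.renin_pressure_gain * rp_dev
                   - p.renin_shortloop_gain * (state.ang_ii - 1.0))
    return _clamp(target, 0.05, 20.0)


def hormone_targets(state: NeurohormonalState, md_na: float, map_mmhg: float,
                    c_na: float, bv: float, co_lmin: float,
                    p: ParameterSet) -> NeurohormonalState:
    """Instantaneous secretion equilibria the first-order kinetics relax toward."""
    renin_t = renin_secretion_target(state, md_na, map_mmhg, p)
    ang_t = _clamp(state.renin * (1.0 - p.ace_inhibition), 0.02, 20.0)
    aldo_t = _clamp(state.ang_ii ** p.aldo_ang_gain, 0.05, 10.0)
    adh_t = _clamp(
        _bexp(p.adh_osm_gain * (c_na / p.c_na_ref - 1.0)
              - p.adh_vol_gain * (bv / p.bv_ref - 1.0)),
        0.05, 10.0,
    )
    tone_t = _clamp((co_lmin / p.co_ref_lmin) ** p.autoreg_exp, 0.2, 5.0)
    return NeurohormonalState(renin_t, ang_t, aldo_t, adh_t, tone_t)


def update_raas(state: NeurohormonalState, md_na: float, map_mmhg: float,
                c_na: float, bv: float, co_lmin: float,
                p: ParameterSet, dt: float) -> NeurohormonalState:
    """First-order relaxation of hormone levels toward their targets over dt (min)."""
    if not 0.0 <= p.ace_inhibition <= 1.0:
        raise ValueError("ACE inhibition must be a fraction in [0, 1]")
    t = hormone_targets(state, md_na, map_mmhg, c_na, bv, co_lmin, p)

    def relax(x, xt, tau):
        return xt + (x - xt) * math.exp(-dt / tau)

    return NeurohormonalState(
        renin=relax(state.renin, t.renin, p.tau_renin),
        ang_ii=relax(state.ang_ii, t.ang_ii, p.tau_ang),
        aldosterone=relax(state.aldosterone, t.aldosterone, p.tau_aldo),
        adh=relax(state.adh, t.adh, p.tau_adh),
        tone=relax(state.tone, t.tone, p.tau_tone),
    ).clamped()


def raas_derivatives(state: NeurohormonalState, md_na: float, map_mmhg: float,
                     c_na: float, bv: float, co_lmin: float,
                     p: ParameterSet) -> tuple[float, float, float, float, float]:
    """Time derivatives (per min) of (renin, ang_ii, aldosterone, adh, tone)."""
    t = hormone_targets(state, md_na, map_mmhg, c_na, bv, co_lmin, p)
    return (
        (t.renin - state.renin) / p.tau_renin,
        (t.ang_ii - state.ang_ii) / p.tau_ang,
        (t.aldosterone - state.aldosterone) / p.tau_aldo,
        (t.adh - state.adh) / p.tau_adh,
        (t.tone - state.tone) / p.tau_tone,
    )


@dataclass
class EffectorOutputs:
    """Multiplicative effect factors; all equal 1 at setpoint."""

    r_efferent: float = 1.0     # ANG II efferent arteriolar constriction
    prox_reabs: float = 1.0     # ANG II proximal Na reabsorption
    dist_reabs: float = 1.0     # aldosterone distal Na reabsorption
    cd_reabs: float = 1.0       # aldosterone collecting-duct Na reabsorption
    urine_concentration: float = 1.0   # ADH urine-concentrating effect
    peripheral_tone: float = 1.0       # autoregulation resistance multiplier


def effector_outputs(state: NeurohormonalState, p: ParameterSet) -> EffectorOutputs:
    lo, hi = p.effect_min, p.effect_max
    reff_slope = (p.ang_reff_gain if state.ang_ii >= 1.0
                  else p.ang_reff_dilation_gain)
    return EffectorOutputs(
        r_efferent=_clamp(1.0 + reff_slope * (state.ang_ii - 1.0), lo, hi),
        prox_reabs=_clamp(1.0 + p.ang_prox_gain * (state.ang_ii - 1.0), lo, hi),
        dist_reabs=_clamp(1.0 + p.aldo_dist_gain * (state.aldosterone - 1.0), lo, hi),
        cd_reabs=_clamp(1.0 + p.aldo_cd_gain * (state.aldosterone - 1.0), lo, hi),
        urine_concentration=_clamp(state.adh ** p.uosm_adh_gain, lo, hi),
        peripheral_tone=state.tone,
    )


def heart_rate(p_pulm_ven: float, p: ParameterSet) -> float:
    """Heart rate (1/min) from pulmonary-venous congestion (sympathetic
    surrogate).  The positive part is smoothed (width 0.05) so the beat map
    stays contractive around the healthy setpoint."""
    x = p_pulm_ven / p.p_pulm_ref - 1.0
    w = 0.05
    congestion = 0.5 * (x + math.sqrt(x * x + w * w))
    return p.hr0 * (1.0 + p.hr_gain * congestion)
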