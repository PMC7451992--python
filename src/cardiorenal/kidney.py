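"""Renal hemodynamics and tubular sodium/glucose/water handling.

Whole-kidney glomerular filtration is computed from a pressure balance across
the glomerular capillary (preafferent + afferent resistance drop, efferent
resistance under ANG II control, plasma oncotic pressure amplified by the
filtration fraction) scaled by the ultrafiltration coefficient and the
functional-nephron fraction.  Tubular handling is segmental (proximal, loop,
distal, collecting duct) with fractional reabsorption setpoints modulated by
ANG II, aldosterone, ADH, pressure natriuresis, tubuloglomerular feedback,
SGLT2/NHE3 inhibition, and the osmotic drag of unreabsorbed glucose.

Glucose reabsorption is transport-maximum limited; SGLT2 inhibition removes a
fraction of SGLT2 capacity, with a smaller downstream (SGLT1) capacity intact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .neurohormonal import EffectorOutputs
from .parameters import ParameterSet

__all__ = ["RenalOutputs", "gfr", "proximal_glucose_reabsorption",
           "sodium_water_excretion", "renal_steady"]

P_RENAL_VENOUS = 4.0     # mmHg, renal venous back-pressure (fixed)
_FRAC_MIN, _FRAC_MAX = 0.02, 0.98


def _clamp(x, lo, hi):
    return min(max(x, lo), hi)


@dataclass
class RenalOutputs:
    gfr: float            # mL/min
    rbf: float            # mL/min
    p_glom: float         # mmHg
    filtered_na: float    # mmol/min
    filtered_glu: float   # mmol/min
    md_na: float          # mmol/min, macula densa Na delivery
    urine_na: float       # mmol/min
    urine_flow: float     # L/min
    uge: float            # mmol/min urinary glucose excretion


def afferent_resistance(p: ParameterSet, tgf_factor: float = 1.0) -> float:
    """Afferent arteriolar resistance (mmHg·min/mL), Poiseuille in D_aa."""
    return p.k_aff / p.d_aa ** 4 * tgf_factor


def gfr(map_mmhg: float, p: ParameterSet, eff: EffectorOutputs,
        pi_plasma: float, tgf_factor: float = 1.0) -> tuple[float, float, float]:
    """Whole-kidney GFR (mL/min) from the glomerular pressure balance.

    Returns (GFR, RBF, P_glom).  The mean glomerular oncotic pressure is
    pi_plasma·(1+FF); the filtration-fraction fixed point is solved by damped
    iteration.  Filtration pressure <= 0 yields GFR = 0.
    """
    if not 40.0 <= map_mmhg <= 220.0:
        raise ValueError(f"MAP {map_mmhg:.1f} mmHg outside physiological range")
    r_pre = p.r_preaff * p.r_preaff_scale
    r_aff = afferent_resistance(p, tgf_factor)
    r_eff = p.r_efferent * eff.r_efferent
    r_total = r_pre + r_aff + r_eff + p.r_renal_venous
    rbf = max(map_mmhg - P_RENAL_VENOUS, 0.0) / r_total
    p_glom = map_mmhg - rbf * (r_pre + r_aff)
    kf = p.kf_glom * p.kf_scale * p.nephron_frac
    rpf = rbf * (1.0 - p.hematocrit)
    g = 0.0
    for _ in range(200):
        ff = g / rpf if rpf > 0 else 0.0
        net = p_glom - p.p_bowman - pi_plasma * (1.0 + ff)
        g_new = max(kf * net, 0.0)
        if abs(g_new - g) < 1e-12 * max(g, 1.0):
            g = g_new
            break
        g = 0.5 * g + 0.5 * g_new
    return g, rbf, p_glom


def proximal_glucose_reabsorption(filtered_glu: float, p: ParameterSet,
                                  sglt2_inhibition: float | None = None
                                  ) -> tuple[float, float]:
    """Saturable proximal glucose reabsorption → (reabsorbed, spilled) mmol/min.

    Capacity = Tm_SGLT2·(1 - inhibition) + Tm_SGLT1, approached smoothly
    (hyperbolic smooth-min) so the flux is C¹ in the filtered load.
    """
    if filtered_glu < 0:
        raise ValueError("filtered glucose must be nonnegative")
    eps = p.sglt2_inhibition if sglt2_inhibition is None else sglt2_inhibition
    capacity = p.tm_sglt2 * (1.0 - eps) + p.tm_sglt1
    w = 0.02
    reab = 0.5 * (filtered_glu + capacity
                  - math.sqrt((filtered_glu - capacity) ** 2 + w * w))
    reab = min(max(reab, 0.0), filtered_glu)
    return reab, filtered_glu - reab


def sodium_water_excretion(gfr_ml_min: float, c_na: float, map_mmhg: float,
                           eff: EffectorOutputs, uge: float, p: ParameterSet
                           ) -> tuple[float, float, float]:
    """Segmental tubular handling → (urine_Na mmol/min, urine_flow L/min, md_Na).

    Proximal reabsorption is modulated by ANG II, NHE3 inhibition coupled to
    SGLT2 blockade, and pressure natriuresis; distal by aldosterone; the
    collecting duct by aldosterone, pressure natriuresis and glucose osmotic
    drag.  Urine flow follows from the excreted osmole load at an
    ADH-controlled urine osmolality.
    """
    filtered_na = gfr_ml_min * c_na / 1000.0
    map_ratio = map_mmhg / p.map_ref
    glu_drag = max(1.0 - p.glu_pt_coupling * uge, 0.5)
    f_pt = _clamp(p.f_prox0 * eff.prox_reabs * glu_drag
                  * (1.0 - p.nhe3_coupling * p.sglt2_inhibition)
                  * map_ratio ** (-p.pn_prox_exp), _FRAC_MIN, _FRAC_MAX)
    post_pt = filtered_na * (1.0 - f_pt)
    md_na = post_pt * (1.0 - p.f_loop0)
    f_dt = _clamp(p.f_dist0 * eff.dist_reabs, _FRAC_MIN, _FRAC_MAX)
    cd_in = md_na * (1.0 - f_dt)
    drag = 1.0 / (1.0 + p.osm_drag_gain * uge)
    f_cd = _clamp(p.f_cd0 * eff.cd_reabs * drag
                  * map_ratio ** (-p.pn_cd_exp), _FRAC_MIN, _FRAC_MAX)
    urine_na = cd_in * (1.0 - f_cd)
    osmoles = 2.0 * urine_na + uge + p.urea_osm_rate      # mosm/min
    u_osm = _clamp(p.u_osm0 * eff.urine_concentration, 60.0, 1200.0)
    urine_flow = osmoles / u_osm                          # L/min
    return urine_na, urine_flow, md_na


def renal_steady(map_mmhg: float, c_na: float, pi_plasma: float,
                 eff: EffectorOutputs, p: ParameterSet) -> RenalOutputs:
    """Self-consistent renal state at given pressure/hormone inputs.

    Solves the TGF loop (macula-densa delivery → afferent tone → GFR) by
    damped fixed-point iteration; deterministic.
    """
    tgf = 1.0
    g = rbf = p_gc = 0.0
    urine_na = urine_flow = md_na = uge = 0.0
    for _ in range(200):
        g, rbf, p_gc = gfr(map_mmhg, p, eff, pi_plasma, tgf_factor=tgf)
        filtered_glu = g * p.c_glu / 1000.0
        _, uge = proximal_glucose_reabsorption(filtered_glu, p)
        urine_na, urine_flow, md_na = sodium_water_excretion(
            g, c_na, map_mmhg, eff, uge, p)
        tgf_new = _clamp((md_na / p.md_ref) ** p.tgf_gain, 0.3, 3.0)
        if abs(tgf_new - tgf) < 1e-12:
            break
        tgf = 0.5 * tgf + 0.5 * tgf_new
    return RenalOutputs(
        gfr=g, rbf=rbf, p_glom=p_gc,
        filtered_na=g * c_na / 1000.0,
        filtered_glu=g * p.c_glu / 1000.0,
        md_na=md_na, urine_na=urine_na, urine_flow=urine_flow, uge=uge,
    )
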