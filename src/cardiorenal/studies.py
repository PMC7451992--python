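"""The package's standard simulation studies.

Each function runs one of the canonical experiments end to end — baseline
characterization, the hypertension/renal-injury step, chronic-HF disease
progression with placebo vs ACE inhibition, and the SGLT2-inhibitor response
studies — and returns plain dictionaries of the derived quantities.  All
studies are deterministic.
"""

from __future__ import annotations

import copy
from typing import Dict

from .cardiac import beats_to_periodic_steady_state
from .interventions import Intervention
from .parameters import default_parameters
from .scheduler import _diagnostics, advance
from .virtual_patient import baseline_state, build_patient, get_preset

__all__ = ["baseline_report", "hypertension_step", "solvd_trial",
           "sglt2i_two_week", "sglt2i_long_term",
           "ACEI_ARM_BASELINE_EDP"]

#: LV end-diastolic pressure at which the ACE-inhibitor arm of the chronic-HF
#: trial protocol begins (the treated arm's published baseline filling
#: pressure; reached by placebo progression from the anchor)
ACEI_ARM_BASELINE_EDP = 23.6


def baseline_report(patient: str) -> Dict[str, float]:
    """Equilibrated baseline variables for a named virtual patient."""
    slow, fast = baseline_state(patient)
    p = build_patient(get_preset(patient))
    fast, bs = beats_to_periodic_steady_state(fast, p, slow)
    d = _diagnostics(slow, bs, p)
    return {
        "co_l_min": bs.co, "hr_bpm": bs.hr, "ef_pct": bs.ef * 100.0,
        "sv_ml": bs.sv, "edv_ml": bs.edv, "esv_ml": bs.esv,
        "edp_mmhg": bs.edp, "bv_l": slow.bv, "ifv_l": slow.ifv,
        "gfr_ml_min": d["gfr_ml_min"], "map_mmhg": bs.map,
        "sbp_mmhg": bs.sbp, "dbp_mmhg": bs.dbp, "p_cap_mmhg": bs.p_cap,
    }


def hypertension_step() -> Dict[str, float]:
    """Renal-injury step: healthy equilibrium → hypertensive equilibrium."""
    healthy = baseline_report("healthy")
    htn = baseline_report("hypertensive")
    return {
        "map_before_mmhg": healthy["map_mmhg"],
        "map_after_mmhg": htn["map_mmhg"],
        "gfr_before_ml_min": healthy["gfr_ml_min"],
        "gfr_after_ml_min": htn["gfr_ml_min"],
    }


def _progress_to_edp(slow, fast, params, edp_target: float,
                     max_days: float = 1500.0):
    days = 0.0
    bs = None
    while days < max_days:
        slow, fast, bs = advance(slow, fast, params, 15.0, step_days=1.0,
                                 day0=days)
        days += 15.0
        if bs.edp >= edp_target:
            return slow, fast, bs, days
    raise RuntimeError(
        f"placebo progression did not reach LVEDP {edp_target} mmHg in "
        f"{max_days:.0f} days (reached {bs.edp:.2f})")


def solvd_trial(arm_duration_days: float = 365.0) -> Dict[str, float]:
    """Chronic-HF progression trial: placebo vs ACE inhibition.

    From the anchored HF-rEF baseline, a placebo arm quantifies the one-year
    rightward P-V shift.  The treated arm starts from the progressed state
    whose LVEDP first matches the published ACEi-arm baseline (23.6 mmHg)
    and is compared against placebo continued from that same point.
    """
    params = build_patient(get_preset("hfref"))
    slow0, fast0 = baseline_state("hfref")
    f0, bs0 = beats_to_periodic_steady_state(copy.deepcopy(fast0), params,
                                             slow0)

    out: Dict[str, float] = {
        "anchor_edv_ml": bs0.edv, "anchor_esv_ml": bs0.esv,
        "anchor_edp_mmhg": bs0.edp,
    }

    # one-year placebo arm from the anchor (rightward shift)
    sp, fp = copy.deepcopy(slow0), copy.deepcopy(fast0)
    sp, fp, bsp = advance(sp, fp, params, arm_duration_days, step_days=1.0)
    out["placebo_1yr_edv_ml"] = bsp.edv
    out["placebo_1yr_esv_ml"] = bsp.esv
    out["placebo_1yr_edp_mmhg"] = bsp.edp

    # progress to the treated arm's baseline filling pressure
    slow, fast, bs, day_reached = _progress_to_edp(
        copy.deepcopy(slow0), copy.deepcopy(fast0), params,
        ACEI_ARM_BASELINE_EDP)
    out["acei_baseline_day"] = day_reached
    out["acei_baseline_edp_mmhg"] = bs.edp
    base_bv, base_ifv = slow.bv, slow.ifv

    acei = Intervention(kind="acei", start_day=0.0)
    s_t, f_t = copy.deepcopy(slow), copy.deepcopy(fast)
    s_t, f_t, b_m1 = advance(s_t, f_t, params, 30.4, step_days=1.0,
                             intervention=acei)
    out["acei_month1_bv_pct"] = 100.0 * (s_t.bv / base_bv - 1.0)
    out["acei_month1_ifv_pct"] = 100.0 * (s_t.ifv / base_ifv - 1.0)
    s_t, f_t, b_t = advance(s_t, f_t, params, arm_duration_days - 30.4,
                            step_days=1.0, day0=30.4, intervention=acei)
    out["acei_1yr_edp_mmhg"] = b_t.edp
    out["acei_1yr_bv_pct"] = 100.0 * (s_t.bv / base_bv - 1.0)
    out["acei_1yr_ifv_pct"] = 100.0 * (s_t.ifv / base_ifv - 1.0)
    out["acei_1yr_edv_ml"] = b_t.edv

    # placebo continued from the same progressed baseline (treatment gap)
    s_p, f_p = copy.deepcopy(slow), copy.deepcopy(fast)
    s_p, f_p, b_p = advance(s_p, f_p, params, arm_duration_days,
                            step_days=1.0)
    out["placebo_arm_1yr_edp_mmhg"] = b_p.edp
    out["placebo_arm_1yr_bv_l"] = s_p.bv
    out["placebo_arm_1yr_ifv_l"] = s_p.ifv
    out["placebo_arm_1yr_edv_ml"] = b_p.edv
    return out


def sglt2i_two_week(patients=("healthy", "diabetic", "hfref",
                              "diabetic_hfref")) -> Dict[str, Dict[str, float]]:
    """Two-week SGLT2-inhibitor responses in the four virtual patients."""
    results: Dict[str, Dict[str, float]] = {}
    for name in patients:
        slow, fast = baseline_state(name)
        p = build_patient(get_preset(name))
        fast, bs0 = beats_to_periodic_steady_state(fast, p, slow)
        d0 = _diagnostics(slow, bs0, p)
        iv = Intervention(kind="sglt2i", start_day=0.0)
        p_drug = p.copy(sglt2_inhibition=iv.effect_magnitude)
        s, f = copy.deepcopy(slow), copy.deepcopy(fast)
        day = 0.0
        uge_day1 = None
        gfr_min = float("inf")
        for k in range(14):
            s, f, bs = advance(s, f, p, 1.0, step_days=1.0, day0=day,
                               intervention=iv)
            day += 1.0
            diag = _diagnostics(s, bs, p_drug)
            gfr_min = min(gfr_min, diag["gfr_ml_min"])
            if k == 0:
                uge_day1 = diag["uge_mmol_day"]
        results[name] = {
            "map_change_mmhg": bs.map - bs0.map,
            "edp_change_mmhg": bs.edp - bs0.edp,
            "bv_change_pct": 100.0 * (s.bv / slow.bv - 1.0),
            "ifv_change_pct": 100.0 * (s.ifv / slow.ifv - 1.0),
            "uge_day1_mmol": uge_day1,
            "uge_day1_g": uge_day1 * 0.18016,
            "gfr_baseline_ml_min": d0["gfr_ml_min"],
            "gfr_min_ml_min": gfr_min,
            "gfr_day14_ml_min": diag["gfr_ml_min"],
        }
    return results


def sglt2i_long_term(duration_days: float = 336.0,
                     patients=("hfref", "diabetic_hfref")
                     ) -> Dict[str, Dict[str, float]]:
    """48-week placebo vs SGLT2i P-V loop progression in the HF patients."""
    results: Dict[str, Dict[str, float]] = {}
    for name in patients:
        slow0, fast0 = baseline_state(name)
        p = build_patient(get_preset(name))
        f0, bs0 = beats_to_periodic_steady_state(copy.deepcopy(fast0), p,
                                                 slow0)
        iv = Intervention(kind="sglt2i", start_day=0.0)
        arms = {}
        for arm, drug in (("placebo", None), ("sglt2i", iv)):
            s, f = copy.deepcopy(slow0), copy.deepcopy(fast0)
            s, f, b28 = advance(s, f, p, 28.0, step_days=1.0,
                                intervention=drug)
            s, f, b = advance(s, f, p, duration_days - 28.0, step_days=1.0,
                              day0=28.0, intervention=drug)
            arms[arm] = {"edv_4wk": b28.edv, "edv_end": b.edv,
                         "esv_end": b.esv, "edp_end": b.edp}
        results[name] = {
            "baseline_edv_ml": bs0.edv,
            "placebo_edv_4wk_ml": arms["placebo"]["edv_4wk"],
            "placebo_edv_end_ml": arms["placebo"]["edv_end"],
            "sglt2i_edv_4wk_ml": arms["sglt2i"]["edv_4wk"],
            "sglt2i_edv_end_ml": arms["sglt2i"]["edv_end"],
            "leftward_shift_4wk_ml":
                arms["placebo"]["edv_4wk"] - arms["sglt2i"]["edv_4wk"],
            "leftward_shift_end_ml":
                arms["placebo"]["edv_end"] - arms["sglt2i"]["edv_end"],
        }
    return results
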