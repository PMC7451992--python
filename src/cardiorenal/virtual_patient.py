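"""Virtual patients: disease parameterizations and verified baselines.

Disease states are pure parameter overlays on the healthy reference set:

* ``hypertensive`` — renal vascular disease / glomerulosclerosis / nephron
  loss (preafferent resistance, afferent diameter, ultrafiltration and
  nephron fractions).
* ``hfref`` — the hypertensive/renal-injury block plus the cardiac block
  (reduced intrinsic contractility, increased LV stiffness, stiffer arteries
  and veins, raised peripheral resistance).
* ``diabetic`` — elevated average plasma glucose only.
* ``diabetic_hfref`` — both.

Healthy, hypertensive and diabetic patients are brought to a true slow-system
equilibrium.  The HF-rEF patient remodels continuously and has no fixed
point; its baseline is anchored as the state whose converged P-V loop first
reaches the published end-diastolic volume of the chronic-HF population the
model was matched to (EDV ≈ 358.67 mL), after which treatment protocols run
forward from that anchor.
"""

from __future__ import annotations

import copy as _copy
import logging
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy import optimize

from .cardiac import beats_to_periodic_steady_state, initial_fast_state
from .parameters import ParameterSet, default_parameters
from .scheduler import BeatContext, advance, slow_derivatives
from .states import FastState, SlowState

__all__ = ["PatientPreset", "PRESETS", "get_preset", "build_patient",
           "equilibrate", "hfref_anchor", "baseline_state",
           "EquilibriumReport", "HFREF_EDV_ANCHOR"]

logger = logging.getLogger(__name__)

#: anchoring EDV for the chronic HF-rEF baseline (mL)
HFREF_EDV_ANCHOR = 358.67

_HYPERTENSION_DELTAS = {
    "r_preaff": 25.5,        # from 14, renal vascular disease
    "d_aa": 1.55e-5,         # from 1.65e-5 m, afferent narrowing
    "kf_scale": 0.80,        # glomerular permeability loss
    "nephron_frac": 0.60,    # nephron loss
}

_CARDIAC_DELTAS = {
    "contractility": 0.795,      # cardiac ischemic injury
    "lv_stiffness": 12.2,        # fibrosis-driven ventricular stiffening
    "r_arterial_si": 6.0e6,      # endothelial dysfunction / vascular stiffness
    "r_peripheral_si": 1.6e8,
    "c_venous_scale": 0.7,       # venous compliance 2e-7 -> 1.4e-7
}

#: initial myocyte hypertrophy of the HF-rEF patient (eccentric remodeling
#: already present at disease onset; the growth laws then continue from here)
_HFREF_STATE_DELTAS = {"dl": 3.35e-5, "dd": 2.0e-5}  # m


@dataclass
class PatientPreset:
    name: str
    deltas: Dict[str, float] = field(default_factory=dict)
    state_deltas: Dict[str, float] = field(default_factory=dict)


PRESETS: Dict[str, PatientPreset] = {
    "healthy": PatientPreset("healthy", {}),
    "hypertensive": PatientPreset("hypertensive", dict(_HYPERTENSION_DELTAS)),
    "diabetic": PatientPreset("diabetic", {"c_glu": 8.0}),
    "hfref": PatientPreset("hfref",
                           {**_HYPERTENSION_DELTAS, **_CARDIAC_DELTAS},
                           dict(_HFREF_STATE_DELTAS)),
    "diabetic_hfref": PatientPreset(
        "diabetic_hfref",
        {**_HYPERTENSION_DELTAS, **_CARDIAC_DELTAS, "c_glu": 8.0},
        dict(_HFREF_STATE_DELTAS)),
}


def get_preset(name: str) -> PatientPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown patient preset {name!r}; "
                       f"expected one of {sorted(PRESETS)}") from None


def build_patient(preset: PatientPreset,
                  base: ParameterSet | None = None) -> ParameterSet:
    """Apply a preset's parameter deltas to the base set (pure function)."""
    base = base or default_parameters()
    try:
        return base.copy(**preset.deltas)
    except KeyError as exc:
        raise KeyError(f"preset {preset.name!r} refers to {exc} which is not "
                       f"a model parameter") from None


_RESIDUAL_NAMES = ("bv", "ifv", "na_blood", "na_if",
                   "renin", "ang_ii", "aldosterone", "adh", "tone")


@dataclass
class EquilibriumReport:
    residual_per_day: Dict[str, float]
    max_rel_residual_per_day: float
    hormone_deviation: float
    net_fluid_balance_l_day: float
    days_run: float
    converged: bool


def _residuals(slow: SlowState, fast: FastState, p: ParameterSet
               ) -> tuple[np.ndarray, FastState]:
    fast, bs = beats_to_periodic_steady_state(fast, p, slow,
                                              tol=min(p.beat_tol, 1e-8))
    ctx = BeatContext.from_summary(bs, slow)
    dy = slow_derivatives(slow.as_vector(), ctx, p)
    return dy, fast


def _relative_residuals(dy: np.ndarray, y: np.ndarray) -> np.ndarray:
    scale = np.maximum(np.abs(y[:9]), np.array(
        [1.0, 1.0, 100.0, 100.0, 0.2, 0.2, 0.2, 0.2, 0.2]))
    return dy[:9] * 1440.0 / scale


def equilibrate(params: ParameterSet, freeze_remodeling: bool = True,
                tol: float = 1e-6, max_days: float = 1200.0,
                initial: Optional[tuple[SlowState, FastState]] = None
                ) -> tuple[SlowState, FastState, EquilibriumReport]:
    """Advance the coupled system to a verified slow-system equilibrium.

    The slow system is accelerated with multi-day implicit macro steps while
    each step's beat is held at periodic steady state; once close, the
    equilibrium is polished by a root solve on the slow derivatives.
    ``tol`` is the relative residual per day.  With ``freeze_remodeling``
    the growth laws are disabled (rate constants zeroed), which is how
    non-HF baselines are defined.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    p = params.copy(k_l0=0.0, k_d0=0.0) if freeze_remodeling else params
    if initial is not None:
        slow, fast = initial
    else:
        slow = SlowState()
        fast = initial_fast_state(p, slow)

    from .scheduler import BeatContext, beat_sensitivities, slow_derivatives

    def polish(slow, fast):
        """One outer/inner Newton-type pass: root of the smooth
        frozen-beat-context slow system, then beat refresh."""
        fast, bs = beats_to_periodic_steady_state(
            fast, p, slow, tol=min(p.beat_tol, 1e-8))
        sens = beat_sensitivities(fast, p, slow, bs)
        ctx = BeatContext.from_summary(bs, slow, sens)

        def fun(x: np.ndarray) -> np.ndarray:
            y = np.concatenate([x, [slow.dd, slow.dl]])
            return _relative_residuals(slow_derivatives(y, ctx, p), y)

        sol = optimize.root(fun, slow.as_vector()[:9], method="hybr",
                            options={"xtol": 1e-13})
        if not sol.success:
            return None
        return SlowState.from_vector(
            np.concatenate([sol.x, [slow.dd, slow.dl]])), fast

    days_run = 0.0
    chunk = 40.0
    dy, fast = _residuals(slow, fast, p)
    rel = _relative_residuals(dy, slow.as_vector())
    best = (slow, fast, float(np.max(np.abs(rel))))
    while days_run < max_days and best[2] >= tol:
        slow, fast, _ = advance(slow, fast, p, chunk, step_days=2.0)
        days_run += chunk
        dy, fast = _residuals(slow, fast, p)
        rel = _relative_residuals(dy, slow.as_vector())
        if float(np.max(np.abs(rel))) < best[2]:
            best = (slow, fast, float(np.max(np.abs(rel))))
        if best[2] < 1e4 * tol:
            # try Newton-type polish passes; accept only improvements
            for _ in range(10):
                out = polish(best[0], best[1])
                if out is None:
                    break
                cand_slow, cand_fast = out
                dy, cand_fast = _residuals(cand_slow, cand_fast, p)
                cand_rel = float(np.max(np.abs(
                    _relative_residuals(dy, cand_slow.as_vector()))))
                if cand_rel < best[2]:
                    best = (cand_slow, cand_fast, cand_rel)
                else:
                    break
            if best[2] < tol:
                break
        slow, fast = best[0], best[1]

    slow, fast = best[0], best[1]
    dy, fast = _residuals(slow, fast, p)
    rel = _relative_residuals(dy, slow.as_vector())
    max_rel = float(np.max(np.abs(rel)))
    horm = slow.hormones
    report = EquilibriumReport(
        residual_per_day=dict(zip(_RESIDUAL_NAMES, (rel).tolist())),
        max_rel_residual_per_day=max_rel,
        hormone_deviation=float(max(abs(horm.renin - 1), abs(horm.ang_ii - 1),
                                    abs(horm.aldosterone - 1),
                                    abs(horm.adh - 1))),
        net_fluid_balance_l_day=float((dy[0] + dy[1]) * 1440.0),
        days_run=days_run, converged=max_rel < tol)
    if not report.converged and max_rel > 1e-2:
        raise RuntimeError(
            f"no equilibrium within {days_run:.0f} days; largest residual "
            f"{max(report.residual_per_day, key=lambda k: abs(report.residual_per_day[k]))} "
            f"= {max_rel:.3g}/day")
    return slow, fast, report


def hfref_anchor(params: ParameterSet, edv_target: float = HFREF_EDV_ANCHOR,
                 max_years: float = 3.0, chunk_days: float = 10.0
                 ) -> tuple[SlowState, FastState]:
    """Construct the chronic HF-rEF baseline anchored to the published loop.

    The cardiac injury block is applied on top of the hypertensive/renal
    equilibrium together with the preset's established eccentric hypertrophy
    (ΔL, ΔD), and the non-remodeling slow system is equilibrated with the
    growth laws frozen.  Because the HF-rEF patient remodels continuously,
    this frozen-growth equilibrium — whose converged loop matches the
    published chronic-HF baseline — is the anchor; if its EDV still lies
    below ``edv_target`` the system is integrated forward with remodeling
    active until the converged-beat EDV first crosses it.
    """
    htn = params.copy(**{k: getattr(default_parameters(), k)
                         for k in _CARDIAC_DELTAS})
    slow, fast, _ = equilibrate(htn, freeze_remodeling=True)
    slow = slow.copy(day=0.0, **_HFREF_STATE_DELTAS)
    slow, fast, _ = equilibrate(params, freeze_remodeling=True,
                                initial=(slow, fast))
    fast, bs = beats_to_periodic_steady_state(fast, params, slow)
    days = 0.0
    max_days = max_years * 365.0
    while bs.edv < edv_target:
        if days >= max_days:
            raise RuntimeError(
                f"HF-rEF progression did not reach EDV {edv_target} mL "
                f"within {max_years:.0f} simulated years "
                f"(reached {bs.edv:.1f} mL)")
        slow, fast, bs = advance(slow, fast, params, chunk_days,
                                 step_days=1.0, day0=days)
        days += chunk_days
    return slow.copy(day=0.0), fast


_BASELINE_CACHE: Dict[str, tuple[SlowState, FastState]] = {}


def baseline_state(patient: str, recompute: bool = False
                   ) -> tuple[SlowState, FastState]:
    """Baseline (slow, fast) state for a named virtual patient, cached."""
    if not recompute and patient in _BASELINE_CACHE:
        slow, fast = _BASELINE_CACHE[patient]
        return _copy.deepcopy(slow), _copy.deepcopy(fast)
    params = build_patient(get_preset(patient))
    if patient in ("hfref", "diabetic_hfref"):
        slow, fast = hfref_anchor(params)
    else:
        slow, fast, _ = equilibrate(params, freeze_remodeling=True)
    _BASELINE_CACHE[patient] = (slow, fast)
    return _copy.deepcopy(slow), _copy.deepcopy(fast)
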