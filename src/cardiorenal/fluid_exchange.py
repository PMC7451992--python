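"""Starling-force fluid exchange between plasma and interstitium.

Net trans-capillary filtration is driven by hydrostatic, colloid-osmotic and
sodium-osmotic pressure differences,

    Phi_FR = K_f (P_c - P_if - pi_prot,c + pi_prot,if - pi_Na,c + pi_Na,if),

with a strain-stiffening interstitial pressure-volume curve split into an
expansion branch (IFV >= 15 L) and a contraction branch (IFV < 15 L).

Continuity repair
-----------------
The printed contraction-branch constants (A=-199, B=1.55, C=0.079) evaluate to
~2.1e4 mmHg at the 15 L branch point while the expansion branch gives
1.145 mmHg, so the printed set cannot describe a continuous compliance curve.
Keeping the expansion branch and B_con verbatim, A_con and C_con are refit
under value- and slope-continuity at IFV = 15 L (Guyton-type shape: nearly
flat below the normal volume, stiffening above).  The refit constants are
exposed as :data:`A_IF_CON_REFIT` / :data:`C_IF_CON_REFIT` and echoed into
every run log.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

from .parameters import ParameterSet
from .units import MMHG_PA

__all__ = [
    "CompartmentFluids",
    "filtration_rate",
    "interstitial_pressure",
    "colloid_osmotic_pressure",
    "sodium_osmotic_pressure",
    "advance_fluids",
    "refit_contraction_constants",
    "A_IF_CON_REFIT",
    "C_IF_CON_REFIT",
]

logger = logging.getLogger(__name__)


@dataclass
class CompartmentFluids:
    """Plasma/interstitium fluid and solute state (volumes in L, Na in mmol)."""

    bv: float            # blood volume, L
    ifv: float           # interstitial fluid volume, L
    na_blood: float      # plasma sodium amount, mmol
    na_if: float         # interstitial sodium amount, mmol
    protein_blood: float  # g, constant
    protein_if: float     # g, constant


def refit_contraction_constants(p: ParameterSet) -> tuple[float, float]:
    """Refit (A_con, C_con) for value+slope continuity at the branch point.

    The expansion branch P = A_ex·exp(B_ex·V) - C_ex and its slope are matched
    by the contraction form P = -A_con·exp(B_con·(V-12)) + C_con at
    V = ``ifv_branch``, keeping B_con as printed.
    """
    v0 = p.ifv_branch
    val = p.a_if_ex * math.exp(p.b_if_ex * v0) - p.c_if_ex
    slope = p.a_if_ex * p.b_if_ex * math.exp(p.b_if_ex * v0)
    e = math.exp(p.b_if_con * (v0 - 12.0))
    a_con = -slope / (p.b_if_con * e)          # negative, matching printed sign
    c_con = val + a_con * e
    return a_con, c_con


_DEFAULTS = ParameterSet()
A_IF_CON_REFIT, C_IF_CON_REFIT = refit_contraction_constants(_DEFAULTS)


def interstitial_pressure(ifv: float, p: ParameterSet | None = None) -> float:
    """Interstitial hydrostatic pressure (mmHg) from IFV (L).

    Uses the expansion branch at/above the branch point and the
    continuity-refit contraction branch below it.
    """
    p = p or _DEFAULTS
    if ifv <= 0:
        raise ValueError("interstitial fluid volume must be positive")
    if ifv < 5.0 or ifv > 40.0:
        logger.warning("IFV %.2f L outside fitted range (5-40 L); extrapolating", ifv)
    if ifv >= p.ifv_branch:
        return p.a_if_ex * math.exp(p.b_if_ex * ifv) - p.c_if_ex
    a_con, c_con = A_IF_CON_REFIT, C_IF_CON_REFIT
    if (p.a_if_ex, p.b_if_ex, p.c_if_ex, p.b_if_con, p.ifv_branch) != (
        _DEFAULTS.a_if_ex,
        _DEFAULTS.b_if_ex,
        _DEFAULTS.c_if_ex,
        _DEFAULTS.b_if_con,
        _DEFAULTS.ifv_branch,
    ):
        a_con, c_con = refit_contraction_constants(p)
    return -a_con * math.exp(p.b_if_con * (ifv - 12.0)) + c_con


def colloid_osmotic_pressure(c_prot: float) -> float:
    """Landis-Pappenheimer colloid osmotic pressure (mmHg) from g/dL."""
    if c_prot < 0:
        raise ValueError("protein concentration must be nonnegative")
    return 1.629 * c_prot + 0.2935 * c_prot ** 2


def sodium_osmotic_pressure(c_na: float, p: ParameterSet | None = None) -> float:
    """van't Hoff sodium osmotic pressure (mmHg) from mmol/L.

    pi = C·R·T with C in mol/m³ (numerically equal to mmol/L), converted from
    Pa to mmHg.
    """
    p = p or _DEFAULTS
    if c_na < 0:
        raise ValueError("sodium concentration must be nonnegative")
    return c_na * p.r_gas * p.temperature / MMHG_PA


def filtration_rate(
    p_c: float,
    p_if: float,
    pi_prot_c: float,
    pi_prot_if: float,
    pi_na_c: float,
    pi_na_if: float,
    p: ParameterSet | None = None,
) -> float:
    """Capillary filtration rate Phi_FR (mL/min); positive = plasma → interstitium."""
    p = p or _DEFAULTS
    return p.k_f * (p_c - p_if - pi_prot_c + pi_prot_if - pi_na_c + pi_na_if)


def plasma_volume(bv: float, p: ParameterSet | None = None) -> float:
    """Plasma volume (L) from blood volume at fixed hematocrit."""
    p = p or _DEFAULTS
    return bv * (1.0 - p.hematocrit)


def osmotic_terms(state: CompartmentFluids, p: ParameterSet | None = None):
    """All four osmotic pressures (mmHg): (pi_prot_c, pi_prot_if, pi_na_c, pi_na_if)."""
    p = p or _DEFAULTS
    pv = plasma_volume(state.bv, p)
    c_prot_c = state.protein_blood / (pv * 10.0)     # g/dL
    c_prot_if = state.protein_if / (state.ifv * 10.0)
    pi_c = colloid_osmotic_pressure(c_prot_c)
    pi_if = colloid_osmotic_pressure(c_prot_if)
    pi_na_c = sodium_osmotic_pressure(state.na_blood / pv, p)
    pi_na_if = sodium_osmotic_pressure(state.na_if / state.ifv, p)
    return pi_c, pi_if, pi_na_c, pi_na_if


def advance_fluids(
    state: CompartmentFluids,
    phi_fr: float,
    urine_flow: float,
    intake: float,
    dt: float,
) -> CompartmentFluids:
    """Advance compartment volumes by one explicit step of length dt (min).

    d(BV)/dt = intake - Phi_FR - urine_flow;  d(IFV)/dt = +Phi_FR, with all
    exchange folded into Phi_FR (no separate lymphatic term), so total body
    water obeys Delta(BV+IFV) = (intake - urine)·dt exactly.

    Flows in L/min (``phi_fr`` given in mL/min is the caller's concern: this
    function takes L/min throughout).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    bv = state.bv + (intake - urine_flow - phi_fr) * dt
    ifv = state.ifv + phi_fr * dt
    if bv <= 0 or ifv <= 0:
        raise ValueError(
            f"fluid step rejected: BV={bv:.4f} L, IFV={ifv:.4f} L would be non-positive "
            f"(phi_fr={phi_fr:.4g} L/min, urine={urine_flow:.4g}, intake={intake:.4g}, dt={dt:g})"
        )
    return replace(state, bv=bv, ifv=ifv)
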