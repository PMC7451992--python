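"""Stress-driven cardiac growth laws (Grossman framework).

Sustained elevation of peak systolic fiber stress drives parallel sarcomere
addition (myocyte diameter growth, concentric wall thickening); sustained
elevation of end-diastolic fiber stress drives series sarcomere addition
(myocyte lengthening, cavity dilatation).  Growth saturates as the offsets
approach one baseline unit (2x normal dimension).  Diameter may regress below
baseline when peak stress falls below its reference; length never regresses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .parameters import ParameterSet

__all__ = [
    "MyocytePopulation",
    "WallComposition",
    "d_dD_dt",
    "d_dL_dt",
    "cavity_volume",
    "myocyte_volume",
    "wall_volume",
]


@dataclass
class MyocytePopulation:
    """Myocyte geometry state; lengths in metres."""

    n_myo: float
    d_myo0: float
    l_myo0: float
    dd: float = 0.0   # diameter offset ΔD_myo
    dl: float = 0.0   # length offset ΔL_myo

    @property
    def dd_max(self) -> float:
        return self.d_myo0

    @property
    def dl_max(self) -> float:
        return self.l_myo0

    @property
    def d_myo(self) -> float:
        return self.d_myo0 + self.dd

    @property
    def l_myo(self) -> float:
        return self.l_myo0 + self.dl

    @classmethod
    def from_params(cls, p: ParameterSet, dd: float = 0.0, dl: float = 0.0):
        return cls(n_myo=p.n_myo, d_myo0=p.d_myo0, l_myo0=p.l_myo0, dd=dd, dl=dl)


@dataclass
class WallComposition:
    """LV wall constituents (mL): V_w = V_myo + V_IS + V_f identically."""

    v_myo: float
    v_is: float
    v_f: float

    @property
    def v_wall(self) -> float:
        return self.v_myo + self.v_is + self.v_f


def d_dD_dt(sigma_peak: float, pop: MyocytePopulation, p: ParameterSet) -> float:
    """Myocyte diameter growth rate (m per slow-time unit) from peak systolic fiber stress.

    rate = K_d (sigma_peak/sigma_peak_ref - 1), with K_d saturating linearly
    to zero as dD approaches dD_max during growth, and K_d = K_d0 during
    regression (sigma_peak below reference).  An atrophy floor at
    -dd_floor_frac*D_myo0 bounds regression (the printed law has no lower cap).
    """
    if p.sigma_peak_ref <= 0:
        raise ValueError("sigma_peak_ref must be positive")
    if sigma_peak < 0:
        raise ValueError("sigma_peak must be nonnegative")
    ratio = sigma_peak / p.sigma_peak_ref - 1.0
    if sigma_peak >= p.sigma_peak_ref:
        kd = p.k_d0 * max(0.0, (pop.dd_max - pop.dd) / pop.dd_max)
    else:
        kd = p.k_d0
        if pop.dd <= -p.dd_floor_frac * pop.d_myo0:
            return 0.0
    return kd * ratio


def d_dL_dt(sigma_ed: float, pop: MyocytePopulation, p: ParameterSet) -> float:
    """Myocyte length growth rate (m per slow-time unit) from end-diastolic fiber stress.

    Asymmetric: exactly zero when sigma_ed < sigma_ed_ref (no regression);
    saturating growth otherwise.
    """
    if p.sigma_ed_ref <= 0:
        raise ValueError("sigma_ed_ref must be positive")
    if sigma_ed < 0:
        raise ValueError("sigma_ed must be nonnegative")
    if sigma_ed < p.sigma_ed_ref:
        return 0.0
    kl = p.k_l0 * max(0.0, (pop.dl_max - pop.dl) / pop.dl_max)
    return kl * (sigma_ed / p.sigma_ed_ref - 1.0)


def cavity_volume(pop: MyocytePopulation, v_lv0: float, l_scale: float = 1.0) -> float:
    """Unloaded LV cavity volume (mL) after length remodeling.

    V = V_LV0 (1 + L_scale·ΔL/L_myo0)³ — isotropic dilatation of the
    spherical chamber with fractional fiber lengthening.
    """
    if v_lv0 <= 0:
        raise ValueError("v_lv0 must be positive")
    return v_lv0 * (1.0 + l_scale * pop.dl / pop.l_myo0) ** 3


def myocyte_volume(pop: MyocytePopulation) -> float:
    """Total myocyte volume (mL); cylinders of diameter D_myo, length L_myo."""
    return pop.n_myo * math.pi * pop.d_myo ** 2 * pop.l_myo / 4.0 * 1.0e6


def wall_volume(pop: MyocytePopulation, comp: WallComposition | None = None,
                p: ParameterSet | None = None) -> float:
    """LV wall volume (mL): myocytes + interstitium + fibrosis."""
    v_myo = myocyte_volume(pop)
    if comp is not None:
        return v_myo + comp.v_is + comp.v_f
    p = p or ParameterSet()
    return v_myo + p.v_interstitial + p.v_fibrosis
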