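"""Lumped-parameter systemic circulation relations.

Compartment pressures are linear in stressed volume (V - V_unstressed)/C.
The mean capillary hydrostatic pressure consumed by the Starling exchange is
the beat-averaged fixed-weight interpolation between arterial and venous
node pressures; the weight is calibrated so that net filtration vanishes at
the healthy equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .parameters import ParameterSet
from .states import BeatSummary, FastState

__all__ = ["CirculationParams", "PressureSummary", "compartment_pressures",
           "mean_capillary_pressure", "pressure_summary"]


@dataclass
class CirculationParams:
    """Conventional-unit view of the circulatory constants."""

    r_arterial: float      # mmHg·s/mL
    r_peripheral: float    # mmHg·s/mL
    c_arterial: float      # mL/mmHg
    c_venous: float        # mL/mmHg
    c_pulm_ven: float      # mL/mmHg

    def __post_init__(self):
        for name in ("r_arterial", "r_peripheral", "c_arterial", "c_venous",
                     "c_pulm_ven"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_params(cls, p: ParameterSet) -> "CirculationParams":
        return cls(r_arterial=p.r_arterial, r_peripheral=p.r_peripheral,
                   c_arterial=p.c_arterial, c_venous=p.c_venous_eff,
                   c_pulm_ven=p.c_pulm_ven)


@dataclass
class PressureSummary:
    map: float
    sbp: float
    dbp: float
    p_capillary_mean: float
    p_venous: float

    def __post_init__(self):
        if not (self.dbp <= self.map <= self.sbp):
            raise ValueError("requires DBP <= MAP <= SBP")


def compartment_pressures(fast: FastState, p: ParameterSet) -> Mapping[str, float]:
    """Instantaneous compartment pressures (mmHg) from stressed volumes."""
    for name, v in (("arterial", fast.v_art), ("venous", fast.v_ven),
                    ("pulmonary venous", fast.v_pulm)):
        if v < 0:
            raise ValueError(f"negative {name} compartment volume")
    return {
        "arterial": (fast.v_art - p.v_art_unstressed) / p.c_arterial,
        "venous": (fast.v_ven - p.v_ven_unstressed) / p.c_venous_eff,
        "pulmonary_venous": (fast.v_pulm - p.v_pulm_unstressed) / p.c_pulm_ven,
    }


def mean_capillary_pressure(beat: BeatSummary) -> float:
    """Beat-averaged capillary hydrostatic pressure (mmHg) from the summary.

    The averaging over the pressure waveform happens inside the beat
    integrator; this accessor exists as the single point of consumption for
    the fluid-exchange module.
    """
    return beat.p_cap


def pressure_summary(beat: BeatSummary) -> PressureSummary:
    return PressureSummary(map=beat.map, sbp=beat.sbp, dbp=beat.dbp,
                           p_capillary_mean=beat.p_cap, p_venous=beat.p_ven)
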