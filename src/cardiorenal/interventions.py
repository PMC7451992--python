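"""Drug pharmacodynamics layered onto model parameters.

Two steady-dosing interventions are supported, each a pure parameter overlay
with no pharmacokinetics:

* ACE inhibition (enalapril class): blocks a fraction of ANG II formation in
  the neurohormonal module.  Purely renal/hormonal — no cardiac parameter is
  touched.
* SGLT2 inhibition (dapagliflozin class): blocks a fraction of proximal
  SGLT2 glucose-transport capacity in the kidney module, with coupled NHE3
  sodium-reabsorption inhibition handled there.

Effect magnitudes are fixed fractions calibrated once against the published
antihypertensive and glucosuric response classes, then frozen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .parameters import ParameterSet

__all__ = ["Intervention", "apply_intervention",
           "ACEI_DEFAULT_MAGNITUDE", "SGLT2I_DEFAULT_MAGNITUDE"]

#: enalapril-class ACE blockade fraction (calibrated: first-month HF-rEF
#: volume response in the clinical validation class)
ACEI_DEFAULT_MAGNITUDE = 0.925

#: dapagliflozin-class SGLT2 capacity blockade fraction (calibrated: 24-h
#: urinary glucose excretion in healthy vs diabetic subjects)
SGLT2I_DEFAULT_MAGNITUDE = 0.98

_KINDS = ("none", "acei", "sglt2i")


@dataclass
class Intervention:
    kind: str = "none"
    effect_magnitude: float | None = None   # None → per-drug calibrated default
    start_day: float = 0.0
    duration_days: float = math.inf

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown intervention kind {self.kind!r}; "
                             f"expected one of {_KINDS}")
        if self.effect_magnitude is None:
            self.effect_magnitude = {
                "none": 0.0,
                "acei": ACEI_DEFAULT_MAGNITUDE,
                "sglt2i": SGLT2I_DEFAULT_MAGNITUDE,
            }[self.kind]
        if not 0.0 <= self.effect_magnitude <= 1.0:
            raise ValueError("effect_magnitude must be a fraction in [0, 1]")
        if self.start_day < 0:
            raise ValueError("start_day must be nonnegative")

    def active(self, day: float) -> bool:
        return (self.kind != "none"
                and self.start_day <= day < self.start_day + self.duration_days)


def apply_intervention(params: ParameterSet, iv: Intervention | None,
                       day: float) -> ParameterSet:
    """Return the parameter set in effect on ``day`` (step-onset dosing).

    ACEi sets the ACE-inhibition fraction; SGLT2i sets the SGLT2-inhibition
    fraction.  No cardiac parameter is modified by either drug.
    """
    if iv is None or not iv.active(day):
        if params.ace_inhibition != 0.0 or params.sglt2_inhibition != 0.0:
            return params.copy(ace_inhibition=0.0, sglt2_inhibition=0.0)
        return params
    if iv.kind == "acei":
        return params.copy(ace_inhibition=iv.effect_magnitude,
                           sglt2_inhibition=0.0)
    return params.copy(sglt2_inhibition=iv.effect_magnitude,
                       ace_inhibition=0.0)
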