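"""In-memory state containers shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .neurohormonal import NeurohormonalState

__all__ = ["FastState", "SlowState", "BeatSummary"]


@dataclass
class FastState:
    """Within-beat circulatory state (mL)."""

    v_lv: float
    v_art: float
    v_ven: float
    v_pulm: float

    @property
    def total(self) -> float:
        return self.v_lv + self.v_art + self.v_ven + self.v_pulm

    def as_array(self) -> np.ndarray:
        return np.array([self.v_lv, self.v_art, self.v_ven, self.v_pulm])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "FastState":
        return cls(*map(float, y))


@dataclass
class SlowState:
    """Day-scale state: volumes (L), sodium (mmol), hormones, remodeling (m)."""

    bv: float = 4.9
    ifv: float = 15.0
    na_blood: float = 397.9
    na_if: float = 2100.0
    hormones: NeurohormonalState = field(default_factory=NeurohormonalState)
    dd: float = 0.0
    dl: float = 0.0
    day: float = 0.0

    _VEC = ("bv", "ifv", "na_blood", "na_if")
    _HORM = ("renin", "ang_ii", "aldosterone", "adh", "tone")

    def as_vector(self) -> np.ndarray:
        h = self.hormones
        return np.array([self.bv, self.ifv, self.na_blood, self.na_if,
                         h.renin, h.ang_ii, h.aldosterone, h.adh, h.tone,
                         self.dd, self.dl])

    @classmethod
    def from_vector(cls, y: np.ndarray, day: float = 0.0) -> "SlowState":
        return cls(bv=float(y[0]), ifv=float(y[1]), na_blood=float(y[2]),
                   na_if=float(y[3]),
                   hormones=NeurohormonalState(*map(float, y[4:9])),
                   dd=float(y[9]), dl=float(y[10]), day=day)

    def copy(self, **kw) -> "SlowState":
        return replace(self, **kw)


@dataclass
class BeatSummary:
    """Per-beat derived quantities (pressures mmHg, volumes mL, stresses mmHg)."""

    edv: float
    esv: float
    edp: float
    map: float
    sbp: float
    dbp: float
    p_ven: float
    p_pulm_ven: float
    p_cap: float
    sigma_peak: float
    sigma_ed: float
    sv_ejected: float      # aortic-valve integrated outflow over the beat
    stroke_work: float     # mmHg·mL, P-V loop area
    hr: float

    @property
    def sv(self) -> float:
        return self.edv - self.esv

    @property
    def ef(self) -> float:
        return self.sv / self.edv

    @property
    def co(self) -> float:
        """Cardiac output, L/min."""
        return self.sv * self.hr / 1000.0
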