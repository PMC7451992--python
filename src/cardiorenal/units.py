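"""Unit conversion helpers.

The circulatory parameters are stored verbatim in an SI-based internal unit
system (resistances in Pa·s·m⁻³, compliances in m³·Pa⁻¹) and converted to the
conventional haemodynamic units (mmHg·s·mL⁻¹, mL·mmHg⁻¹) used by the solver
and by all reporting.  Fiber stresses are carried in mmHg internally and
reported in kPa.
"""

MMHG_PA = 133.322387415  # 1 mmHg in Pa
ML_M3 = 1.0e-6           # 1 mL in m³


def resistance_si_to_mmhg_s_ml(r_si: float) -> float:
    """Pa·s·m⁻³ → mmHg·s·mL⁻¹."""
    return r_si / MMHG_PA * ML_M3


def resistance_si_to_mmhg_min_ml(r_si: float) -> float:
    """Pa·s·m⁻³ → mmHg·min·mL⁻¹."""
    return resistance_si_to_mmhg_s_ml(r_si) / 60.0


def compliance_si_to_ml_mmhg(c_si: float) -> float:
    """m³·Pa⁻¹ → mL·mmHg⁻¹."""
    return c_si * MMHG_PA / ML_M3


def mmhg_to_kpa(p: float) -> float:
    return p * MMHG_PA / 1000.0


def kpa_to_mmhg(p: float) -> float:
    return p * 1000.0 / MMHG_PA


def pa_to_mmhg(p: float) -> float:
    return p / MMHG_PA
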