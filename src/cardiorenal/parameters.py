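"""The model's named constant vector.

Every tunable quantity of the integrated model lives in :class:`ParameterSet`,
a flat dataclass.  ``PARAM_INFO`` records units and provenance for each entry:

``reference``
    published reference value adopted verbatim.
``calibrated``
    coefficient with no published value, recovered by calibrating the closed-loop
    model against the printed healthy / disease-state outputs (the run log of
    any simulation lists these).
``structural``
    a modelling choice of this implementation (documented in docs/methods.md).

Disease presets (virtual patients) are expressed as parameter deltas in
:mod:`cardiorenal.virtual_patient`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Dict

import yaml

from .units import resistance_si_to_mmhg_s_ml

__all__ = ["ParameterSet", "PARAM_INFO", "default_parameters"]


@dataclass
class ParameterSet:
    # --- cardiac mechanics -------------------------------------------------
    hr0: float = 70.0                  # beats/min, healthy resting heart rate
    contractility: float = 1.0         # kappa_C, dimensionless multiplier
    sigma_act0: float = 224.41          # mmHg, isometric active stress scale
    act_len_slope: float = 3.58005         # dimensionless length-dependence slope
    t_sys_coeff: float = 0.419782         # s^0.5, systolic interval = c*sqrt(T)
    lv_stiffness: float = 11.0         # C_f, passive exponential stiffness
    sigma_pas0: float = 3.97212           # mmHg, passive stress scale
    v_lv0: float = 43.0678                # mL, unloaded cavity volume pre-remodeling
    r_mitral: float = 0.005            # mmHg·s/mL, mitral inflow resistance

    # --- circulation -------------------------------------------------------
    r_arterial_si: float = 5.0e6       # Pa·s/m³, proximal arterial resistance
    r_peripheral_si: float = 1.3e8     # Pa·s/m³, peripheral resistance
    c_venous: float = 220.0            # mL/mmHg, systemic venous compliance
    c_venous_scale: float = 1.0        # preset multiplier (HF-rEF: 0.7)
    c_arterial: float = 1.54804            # mL/mmHg
    c_pulm_ven: float = 18.0           # mL/mmHg, pulmonary venous reservoir
    v_art_unstressed: float = 600.0    # mL
    v_ven_unstressed: float = 2525.63   # mL
    v_pulm_unstressed: float = 350.0   # mL
    v_circ_fixed: float = 300.0        # mL, capillary bed + remaining chambers
    g_right_heart: float = 38.2748        # mL/s/mmHg, right-side pump conductance
    rh_backpressure_ratio: float = 4.45615 # pulmonary-venous afterload coupling
    cap_pressure_weight: float = 0.128 # P_c = w*P_a + (1-w)*P_v
    hematocrit: float = 0.42

    # --- kidney ------------------------------------------------------------
    r_preaff: float = 14.0             # published reference units (relative)
    r_preaff_scale: float = 1.336e-3   # → mmHg·min/mL whole kidney
    d_aa: float = 1.65e-5              # m, afferent arteriole diameter
    k_aff: float = 7.93e-22            # mmHg·min/mL·m⁴; R_aff = k_aff/d_aa⁴
    r_efferent: float = 0.030          # mmHg·min/mL whole kidney
    r_renal_venous: float = 0.021      # mmHg·min/mL
    p_bowman: float = 18.0             # mmHg
    kf_glom: float = 13.775              # mL/min/mmHg whole-kidney UF coefficient
    kf_scale: float = 1.0              # C_DED-Kf (fraction)
    nephron_frac: float = 1.0          # C_DE-N (fraction)
    c_glu: float = 5.5                 # mmol/L plasma glucose
    tm_sglt2: float = 1.8              # mmol/min, SGLT2 transport maximum
    tm_sglt1: float = 0.2              # mmol/min, downstream SGLT1 capacity
    f_prox0: float = 0.70              # proximal fractional Na reabsorption
    f_loop0: float = 0.80              # loop of Henle
    f_dist0: float = 0.85              # distal tubule
    f_cd0: float = 0.424691                # collecting duct (closed at calibration)
    na_intake: float = 100.0 / 1440.0  # mmol/min dietary sodium
    urea_osm_rate: float = 450.0 / 1440.0  # mosm/min obligatory solute load
    u_osm0: float = 433.33             # mosm/L urine osmolality setpoint
    water_intake0: float = 1.5 / 1440.0    # L/min baseline water intake
    pn_prox_exp: float = 0.6           # pressure-natriuresis exponent, proximal
    pn_cd_exp: float = 1.2             # pressure-natriuresis exponent, CD
    tgf_gain: float = 0.4              # TGF afferent-tone exponent
    nhe3_coupling: float = 0.08        # PT Na reabs reduction at full SGLT2 block
    glu_pt_coupling: float = 0.1       # PT Na reabs reduction per mmol/min tubular glucose
    osm_drag_gain: float = 0.8         # CD water-reabs reduction per mmol/min tubular glucose
    sglt2_inhibition: float = 0.0      # fraction, set by intervention

    # --- neurohormonal -----------------------------------------------------
    tau_renin: float = 30.0            # min
    tau_ang: float = 30.0
    tau_aldo: float = 60.0
    tau_adh: float = 30.0
    tau_tone: float = 2880.0           # min, whole-body autoregulation
    md_gain: float = 5.0               # renin sensitivity to MD Na delivery
    renin_pressure_gain: float = 1.0   # renin sensitivity to perfusion pressure
    renin_shortloop_gain: float = 0.8  # ANG II short-loop feedback on renin
    aldo_ang_gain: float = 0.6         # aldosterone = ANGII^gain
    adh_osm_gain: float = 20.0
    adh_vol_gain: float = 3.0
    uosm_adh_gain: float = 1.0
    thirst_gain: float = 30.0
    ang_reff_gain: float = 4.0         # ANG II → efferent resistance (constriction)
    ang_reff_dilation_gain: float = 0.5  # efferent dilation slope below setpoint
    ang_prox_gain: float = 0.3        # ANG II → proximal reabsorption
    aldo_dist_gain: float = 0.9
    aldo_cd_gain: float = 0.5
    effect_min: float = 0.3            # saturation bounds for effect factors
    effect_max: float = 3.0
    co_ref_lmin: float = 4.998          # L/min autoregulation target
    autoreg_exp: float = 3.0
    hr_gain: float = 0.0394            # HR rise per unit pulmonary congestion
    p_pulm_ref: float = 6.577            # mmHg reference pulmonary venous pressure
    ace_inhibition: float = 0.0        # fraction, set by intervention

    # --- capillary / interstitial fluid exchange ---------------------------
    k_f: float = 6.67                  # mL/min/mmHg capillary filtration coeff
    a_if_ex: float = 0.01
    b_if_ex: float = 0.25              # mmHg/L
    c_if_ex: float = -0.72             # mmHg
    a_if_con: float = -199.0           # printed (superseded by continuity refit)
    b_if_con: float = 1.55             # mmHg/L
    c_if_con: float = 0.079            # mmHg (printed, superseded)
    ifv_branch: float = 15.0           # L, expansion/contraction branch point
    r_gas: float = 8.314               # J/K/mol
    temperature: float = 310.0         # K
    protein_blood_g: float = 198.9     # g, constant plasma protein mass
    protein_if_g: float = 666.0        # g, constant interstitial protein mass
    ps_na: float = 40.0                # L/min trans-capillary Na exchange
    c_na_ref: float = 140.0            # mmol/L plasma sodium setpoint

    # --- remodeling --------------------------------------------------------
    k_l0: float = 1.0e-10              # m per slow-time unit, length rate
    remodel_time_unit_min: float = 6.0    # min per slow-time unit (clock)
    k_d0: float = 1.33e-11             # m per slow-time unit, diameter rate
    l_scale: float = 1.0
    d_myo0: float = 2.0e-5             # m, baseline myocyte diameter
    l_myo0: float = 1.0e-4             # m, baseline myocyte length
    n_myo: float = 3.183e9             # myocyte count (constant)
    v_interstitial: float = 30.0       # mL wall interstitium
    v_fibrosis: float = 10.0           # mL fibrosis volume (static)
    sigma_peak_ref: float = 320.59      # mmHg, frozen healthy peak fiber stress
    sigma_ed_ref: float = 21.974         # mmHg, frozen healthy ED fiber stress
    dd_floor_frac: float = 0.5         # atrophy floor: dD >= -0.5*D_myo0

    # --- setpoints (healthy equilibrium, frozen at calibration) -------------
    map_ref: float = 84.4              # mmHg
    bv_ref: float = 4.9                # L
    md_ref: float = 0.80472              # mmol/min macula densa Na delivery

    # --- solver ------------------------------------------------------------
    beat_dt: float = 5.0e-4            # s, fixed RK4 step within a beat
    beat_tol: float = 1.0e-6           # relative periodic-steady-state tol
    max_beats: int = 2000
    slow_rtol: float = 1.0e-6

    # ------------------------------------------------------------------ api
    @property
    def r_arterial(self) -> float:
        """Proximal arterial resistance, mmHg·s/mL."""
        return resistance_si_to_mmhg_s_ml(self.r_arterial_si)

    @property
    def r_peripheral(self) -> float:
        """Peripheral resistance, mmHg·s/mL (before autoregulation tone)."""
        return resistance_si_to_mmhg_s_ml(self.r_peripheral_si)

    @property
    def c_venous_eff(self) -> float:
        return self.c_venous * self.c_venous_scale

    @property
    def v_wall0(self) -> float:
        """Baseline LV wall volume, mL (Eq-1 sum at zero remodeling)."""
        import math
        v_myo = self.n_myo * math.pi * self.d_myo0 ** 2 * self.l_myo0 / 4.0 * 1e6
        return v_myo + self.v_interstitial + self.v_fibrosis

    def copy(self, **overrides: float) -> "ParameterSet":
        new = dataclasses.replace(self)
        for key, val in overrides.items():
            if not hasattr(new, key):
                raise KeyError(f"unknown parameter: {key!r}")
            setattr(new, key, val)
        return new

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "ParameterSet":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


#: units / provenance metadata (subset of fields with external meaning)
PARAM_INFO: Dict[str, Dict[str, str]] = {
    "hr0": {"units": "1/min", "provenance": "reference"},
    "contractility": {"units": "-", "provenance": "reference"},
    "sigma_act0": {"units": "mmHg", "provenance": "calibrated"},
    "act_len_slope": {"units": "-", "provenance": "calibrated"},
    "t_sys_coeff": {"units": "s^0.5", "provenance": "calibrated"},
    "lv_stiffness": {"units": "-", "provenance": "reference"},
    "sigma_pas0": {"units": "mmHg", "provenance": "calibrated"},
    "v_lv0": {"units": "mL", "provenance": "calibrated"},
    "r_arterial_si": {"units": "Pa·s/m³", "provenance": "reference"},
    "r_peripheral_si": {"units": "Pa·s/m³", "provenance": "reference"},
    "c_venous": {"units": "mL/mmHg", "provenance": "calibrated"},
    "c_venous_scale": {"units": "-", "provenance": "reference"},
    "c_arterial": {"units": "mL/mmHg", "provenance": "calibrated"},
    "r_preaff": {"units": "reference units (relative)", "provenance": "reference"},
    "d_aa": {"units": "m", "provenance": "reference"},
    "kf_scale": {"units": "-", "provenance": "reference"},
    "nephron_frac": {"units": "-", "provenance": "reference"},
    "c_glu": {"units": "mmol/L", "provenance": "reference"},
    "k_f": {"units": "mL/min/mmHg", "provenance": "reference"},
    "a_if_ex": {"units": "-", "provenance": "reference"},
    "b_if_ex": {"units": "mmHg/L", "provenance": "reference"},
    "c_if_ex": {"units": "mmHg", "provenance": "reference"},
    "a_if_con": {"units": "-", "provenance": "reference (superseded by refit)"},
    "b_if_con": {"units": "mmHg/L", "provenance": "reference"},
    "c_if_con": {"units": "mmHg", "provenance": "reference (superseded by refit)"},
    "r_gas": {"units": "J/K/mol", "provenance": "reference"},
    "temperature": {"units": "K", "provenance": "reference"},
    "k_l0": {"units": "m per slow-time unit", "provenance": "reference (time unit calibrated)"},
    "k_d0": {"units": "m per slow-time unit", "provenance": "reference (time unit calibrated)"},
    "l_scale": {"units": "-", "provenance": "reference"},
}


def default_parameters() -> ParameterSet:
    """Healthy reference parameterization (calibration anchor)."""
    return ParameterSet()
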