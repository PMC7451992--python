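"""Readers, writers and summary tables.

All interchange is RFC-4180 CSV with '.' decimal separator, UTF-8, and
unit-suffixed column headers.  Floats are written at full precision (repr)
so every file round-trips bit-exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .fluid_exchange import A_IF_CON_REFIT, C_IF_CON_REFIT
from .parameters import PARAM_INFO, ParameterSet
from .states import BeatSummary, SlowState

__all__ = ["table1_report", "write_pv_trace", "write_trajectory",
           "read_trajectory", "figure_exports", "write_run_log"]

logger = logging.getLogger(__name__)


def _fmt_float(v) -> str:
    """Shortest round-trip decimal representation (bit-exact reload)."""
    return repr(float(v))

_TABLE1_ROWS = [
    ("Cardiac output", "L/min", "co_l_min"),
    ("Heart rate", "beats/min", "hr_bpm"),
    ("Ejection fraction", "%", "ef_pct"),
    ("Stroke volume", "mL", "sv_ml"),
    ("LV end-diastolic volume", "mL", "edv_ml"),
    ("LV end-systolic volume", "mL", "esv_ml"),
    ("LV end-diastolic pressure", "mmHg", "edp_mmhg"),
    ("Blood volume", "L", "bv_l"),
    ("Interstitial fluid volume", "L", "ifv_l"),
    ("Glomerular filtration rate", "mL/min", "gfr_ml_min"),
    ("Mean arterial pressure", "mmHg", "map_mmhg"),
    ("Systolic blood pressure", "mmHg", "sbp_mmhg"),
    ("Diastolic blood pressure", "mmHg", "dbp_mmhg"),
    ("Mean capillary pressure", "mmHg", "p_cap_mmhg"),
]


def table1_report(slow: SlowState, beat: BeatSummary, gfr_ml_min: float,
                  residual_report=None) -> pd.DataFrame:
    """Summary table of the standard baseline variables for one patient state.

    Refuses unequilibrated input when an equilibrium report with residuals
    above tolerance is supplied.
    """
    if residual_report is not None and not residual_report.converged:
        raise ValueError(
            "refusing to summarize an unequilibrated state; residuals/day: "
            f"{residual_report.residual_per_day}")
    values = {
        "co_l_min": beat.co, "hr_bpm": beat.hr, "ef_pct": beat.ef * 100.0,
        "sv_ml": beat.sv, "edv_ml": beat.edv, "esv_ml": beat.esv,
        "edp_mmhg": beat.edp, "bv_l": slow.bv, "ifv_l": slow.ifv,
        "gfr_ml_min": gfr_ml_min, "map_mmhg": beat.map,
        "sbp_mmhg": beat.sbp, "dbp_mmhg": beat.dbp, "p_cap_mmhg": beat.p_cap,
    }
    return pd.DataFrame(
        [{"variable": name, "units": units, "value": values[key]}
         for name, units, key in _TABLE1_ROWS])


def write_pv_trace(trace: np.ndarray, path: str | Path,
                   t_sys: float | None = None) -> None:
    """Write a per-beat P-V trace CSV (time_s, V_lv_mL, P_lv_mmHg, P_ao_mmHg,
    phase)."""
    df = pd.DataFrame(trace, columns=["time_s", "V_lv_mL", "P_lv_mmHg",
                                      "P_ao_mmHg"])
    if t_sys is not None:
        df["phase"] = np.where(df["time_s"] < t_sys, "systole", "diastole")
    else:
        df["phase"] = ""
    df.to_csv(path, index=False, float_format=_fmt_float)


def write_trajectory(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, float_format=_fmt_float)


def read_trajectory(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def figure_exports(frame: pd.DataFrame, outdir: str | Path,
                   label: str = "run") -> dict:
    """Write tidy CSV bundles for the standard panels of a finished run.

    Returns a manifest mapping panel name → file path; an empty trajectory
    yields an empty bundle (no files, empty manifest).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {}
    if frame.empty:
        logger.warning("empty trajectory: writing empty figure bundle")
        return manifest
    panels = {
        "hemodynamics": ["day", "edp_mmhg", "map_mmhg", "sbp_mmhg",
                         "dbp_mmhg", "edv_ml", "esv_ml", "ef"],
        "volumes": ["day", "bv_l", "ifv_l", "p_cap_mmhg", "p_if_mmhg",
                    "phi_fr_ml_min"],
        "renal": ["day", "gfr_ml_min", "urine_na_mmol_day",
                  "urine_flow_l_day", "uge_mmol_day"],
        "hormones": ["day", "renin", "ang_ii", "aldosterone", "adh", "tone"],
        "remodeling": ["day", "dd_um", "dl_um", "sigma_peak_mmhg",
                       "sigma_ed_mmhg"],
    }
    for panel, cols in panels.items():
        missing = [c for c in cols if c not in frame.columns]
        if missing:
            raise KeyError(f"trajectory lacks columns {missing} for panel "
                           f"{panel!r}")
        path = outdir / f"{label}_{panel}.csv"
        frame[cols].to_csv(path, index=False)
        manifest[panel] = str(path)
    return manifest


def write_run_log(params: ParameterSet, path: str | Path,
                  extra: Mapping | None = None) -> None:
    """Emit the run log: full parameter vector with provenance, including
    every calibrated/refit constant (interstitial-compliance refit among
    them)."""
    log = {
        "parameters": params.to_dict(),
        "provenance": PARAM_INFO,
        "interstitial_compliance_refit": {
            "a_if_con": A_IF_CON_REFIT, "c_if_con": C_IF_CON_REFIT,
            "note": "contraction branch refit for value+slope continuity "
                    "at the branch point; printed constants retained in "
                    "parameters for provenance",
        },
    }
    if extra:
        log.update(extra)
    with open(path, "w") as fh:
        json.dump(log, fh, indent=2, default=float)
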