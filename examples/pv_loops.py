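"""Export converged pressure-volume loops for the healthy and HF-rEF hearts.

Writes one CSV per patient (time, LV volume, LV pressure, aortic pressure)
for a single converged beat.  The healthy loop spans roughly 25-96 mL at
peak pressures ~105 mmHg; the HF-rEF loop is shifted far rightward
(~295-359 mL) with a narrow width (stroke volume ~65 mL).
"""

import logging
import math
from pathlib import Path

from cardiorenal.cardiac import beats_to_periodic_steady_state, run_beat
from cardiorenal.io_reporting import write_pv_trace
from cardiorenal.virtual_patient import baseline_state, build_patient, get_preset

logging.disable(logging.WARNING)

outdir = Path("pv_loops_out")
outdir.mkdir(exist_ok=True)
for patient in ("healthy", "hfref"):
    slow, fast = baseline_state(patient)
    params = build_patient(get_preset(patient))
    fast, beat = beats_to_periodic_steady_state(fast, params, slow)
    _, _, trace = run_beat(fast, params, slow, hr=beat.hr, return_trace=True)
    t_sys = params.t_sys_coeff * math.sqrt(60.0 / beat.hr)
    path = outdir / f"pv_loop_{patient}.csv"
    write_pv_trace(trace, path, t_sys=t_sys)
    print(f"{patient:8s}: EDV {beat.edv:6.1f} mL  ESV {beat.esv:6.1f} mL  "
          f"EF {100 * beat.ef:4.1f}%  stroke work {beat.stroke_work:7.0f} "
          f"mmHg*mL  -> {path}")
print("\nLoop area is the stroke work of one beat; the rightward-shifted "
      "HF-rEF loop at preserved arterial pressure is the dilated failing "
      "ventricle.")
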