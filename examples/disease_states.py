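"""Build the diseased virtual patients and summarize their baselines.

Renal injury (raised preafferent resistance, narrowed afferent arterioles,
fewer nephrons, reduced glomerular permeability) raises arterial pressure
and lowers GFR; adding the cardiac injury block (reduced contractility,
stiffer ventricle and vessels) with established eccentric hypertrophy yields
the chronic HF-rEF state: a dilated ventricle (EDV ~359 mL), ejection
fraction ~18%, raised filling pressure (~20 mmHg) and interstitial
congestion (~23.5 L).
"""

import logging

from cardiorenal.studies import baseline_report, hypertension_step

logging.disable(logging.WARNING)

step = hypertension_step()
print("Hypertension / renal-injury step:")
print(f"  MAP : {step['map_before_mmhg']:6.2f} -> {step['map_after_mmhg']:6.2f} mmHg")
print(f"  GFR : {step['gfr_before_ml_min']:6.2f} -> {step['gfr_after_ml_min']:6.2f} mL/min")

hf = baseline_report("hfref")
print("\nChronic HF-rEF baseline (anchored to the published dilated loop):")
for key, unit in [("edv_ml", "mL"), ("esv_ml", "mL"), ("ef_pct", "%"),
                  ("edp_mmhg", "mmHg"), ("bv_l", "L"), ("ifv_l", "L"),
                  ("co_l_min", "L/min"), ("hr_bpm", "1/min"),
                  ("map_mmhg", "mmHg")]:
    print(f"  {key:10s} = {hf[key]:8.2f} {unit}")
print("\nThe HF-rEF patient has no true steady state: its end-diastolic "
      "fiber stress stays above the remodeling setpoint, so the chamber "
      "keeps dilating (the basis of the progression studies).")
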