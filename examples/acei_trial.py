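"""Chronic-HF progression under placebo vs one year of ACE inhibition.

The untreated HF-rEF patient's P-V loop drifts rightward (continued
dilatation).  Enalapril-class ACE inhibition acts purely through the kidney
(less ANG II -> less sodium reabsorption -> volume loss): filling pressure
falls from ~23.6 toward ~16 mmHg over a year, blood volume and interstitial
volume dip ~8-16% in the first month and partially rebound, and the
placebo-treatment gap persists.  Takes a few minutes.
"""

import logging

from cardiorenal.studies import solvd_trial

logging.disable(logging.WARNING)

r = solvd_trial()
print("Placebo arm (one year from the anchored baseline):")
print(f"  EDV {r['anchor_edv_ml']:.1f} -> {r['placebo_1yr_edv_ml']:.1f} mL "
      f"(rightward shift +{r['placebo_1yr_edv_ml']-r['anchor_edv_ml']:.1f})")
print(f"  LVEDP {r['anchor_edp_mmhg']:.2f} -> "
      f"{r['placebo_1yr_edp_mmhg']:.2f} mmHg")
print("\nACE-inhibitor arm (from the progressed baseline):")
print(f"  LVEDP {r['acei_baseline_edp_mmhg']:.2f} -> "
      f"{r['acei_1yr_edp_mmhg']:.2f} mmHg over one year")
print(f"  first month: BV {r['acei_month1_bv_pct']:+.1f}%  "
      f"IFV {r['acei_month1_ifv_pct']:+.1f}%")
print(f"  one year   : BV {r['acei_1yr_bv_pct']:+.1f}%  "
      f"IFV {r['acei_1yr_ifv_pct']:+.1f}% (partial rebound)")
print(f"  placebo-arm LVEDP at one year: "
      f"{r['placebo_arm_1yr_edp_mmhg']:.2f} mmHg (gap persists)")
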