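# cardiorenal

An integrated heart–kidney simulator for chronic heart failure with reduced
ejection fraction (HF-rEF) and its renally acting therapies.

Congestive heart failure couples two organs: a failing ventricle lowers
arterial filling, the kidney responds by retaining salt and water, and the
retained volume overloads the heart further, driving edema and progressive
ventricular dilatation. `cardiorenal` models this loop end to end — a
beat-resolved left ventricle and lumped systemic circulation coupled to
day-scale renal sodium/glucose/water handling, renin–angiotensin–aldosterone
feedback, capillary–interstitium Starling exchange, and stress-driven
cardiac remodeling — and simulates virtual patients (healthy, hypertensive,
diabetic, HF-rEF, diabetic HF-rEF) over protocols up to a year, untreated or
under ACE inhibition (enalapril class) or SGLT2 inhibition (dapagliflozin
class).

It is intended for quantitative-systems-pharmacology style exploration of
cardiorenal mechanisms: why an SGLT2 inhibitor decongests the interstitium
without collapsing plasma volume, how a purely renal natriuretic drug shifts
a pressure–volume loop leftward, how renal injury resets long-term arterial
pressure.

## The model in brief

**Ventricle.** Spherical thick-walled chamber, one-fiber mechanics:
`P_lv = σ_f/3 · ln(1 + V_w/V)` with fiber stress
`σ_f = σ_pas(λ) + κ_C·σ_a0·a(t)·f(λ)`, exponential passive stiffness
(parameter C_f), a rise/plateau/fall activation twitch `a(t)`, linear
length-dependent activation `f(λ)`, and ideal valves. A lumped circulation
(arterial / peripheral / venous / pulmonary-venous compartments, right side
as a congestion-sensitive flow source) closes the loop.

**Kidney.** Glomerular pressure balance → GFR; segmental tubular
reabsorption modulated by ANG II, aldosterone, ADH, pressure natriuresis,
tubuloglomerular feedback, and transport-maximum glucose handling with
SGLT2/SGLT1 capacities.

**Fluids.** Starling exchange
`Φ = K_f(P_c − P_if − π_c + π_if − π_Na,c + π_Na,if)` with the
Landis–Pappenheimer colloid relation, van't Hoff sodium osmosis and a
strain-stiffening interstitial pressure–volume curve.

**Remodeling.** Grossman-pattern growth laws: peak systolic fiber stress
above its healthy reference thickens the wall (parallel sarcomere addition);
end-diastolic fiber stress above reference lengthens the myocytes and
dilates the cavity (`V_LV0·(1+ΔL/L₀)³`), with saturation at twice the
baseline dimensions.

**Numerics.** Timescale splitting: each macro step holds the beat at its
periodic fixed point, freezes its summary (MAP, capillary pressure, fiber
stresses) with blood-volume/tone sensitivities, and integrates the slow
states implicitly (LSODA). Validated against a per-beat-coupled reference
integrator. Fully deterministic; numba-accelerated beat kernel with a pure
Python fallback. See `docs/methods.md` for the complete account.

## Worked example

```python
from cardiorenal.studies import baseline_report, hypertension_step

print(baseline_report("healthy"))
print(hypertension_step())
```

prints (abridged):

```
{'co_l_min': 4.99, 'hr_bpm': 70.1, 'ef_pct': 74.1, 'sv_ml': 71.3,
 'edv_ml': 96.2, 'esv_ml': 24.9, 'edp_mmhg': 6.30, 'bv_l': 4.885,
 'ifv_l': 14.95, 'gfr_ml_min': 95.7, 'map_mmhg': 84.5, ...}
{'map_before_mmhg': 84.54, 'map_after_mmhg': 94.33,
 'gfr_before_ml_min': 95.66, 'gfr_after_ml_min': 80.33}
```

The first dictionary is the equilibrated healthy patient: cardiac output
~5 L/min at 70 bpm, ejection fraction in the low 70s, end-diastolic pressure
6.3 mmHg, blood volume 4.9 L, interstitial volume 15 L, GFR ~96 mL/min —
all at their clinical resting norms, with every hormonal feedback exactly at
its setpoint. The second shows the renal-injury step: losing nephrons and
narrowing the renal vasculature forces mean arterial pressure up by
~10 mmHg (the pressure the kidney now needs to excrete the same sodium
intake) while GFR falls to ~80 mL/min.

The `examples/` directory holds one short script per capability:

| script | what it runs |
| --- | --- |
| `examples/healthy_baseline.py` | equilibrate + baseline summary table |
| `examples/disease_states.py` | hypertension step and the HF-rEF anchor |
| `examples/pv_loops.py` | converged P-V loop CSV export, healthy vs HF-rEF |
| `examples/acei_trial.py` | 1-year placebo vs ACE-inhibitor trial |
| `examples/sglt2i_response.py` | two-week SGLT2i study in four patients |

A thin CLI wraps the same machinery:

```
cardiorenal equilibrate --patient healthy
cardiorenal run --patient hfref --drug sglt2i --days 336 --out out/
cardiorenal pvloop --run out/ --day 336
```

## Layout

```
src/cardiorenal/
  cardiac.py         beat-resolved LV + circulation kernel
  circulation.py     compartment pressure relations
  kidney.py          renal hemodynamics and tubular handling
  fluid_exchange.py  Starling forces, interstitial compliance
  neurohormonal.py   RAAS, ADH, autoregulation, heart-rate control
  remodeling.py      stress-driven growth laws
  interventions.py   ACEi / SGLT2i pharmacodynamics
  virtual_patient.py disease presets, equilibration, HF-rEF anchor
  scheduler.py       timescale-split orchestrator + reference integrator
  studies.py         the standard simulation studies
  io_reporting.py    CSV writers, summary tables, run logs
  parameters.py      the full named constant vector with provenance
```
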