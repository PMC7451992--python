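# Methods

`cardiorenal` simulates the coupled resting physiology of the left heart,
systemic circulation, kidney, body-fluid compartments and their hormonal
control, across timescales from milliseconds (one heartbeat) to a year
(disease progression and drug therapy). This note records the model, its
assumptions, the numerical scheme, and the design choices made where the
design was genuinely open.

## Model structure

### Beat-scale subsystem

The left ventricle is a thick-walled sphere. Cavity pressure follows from
the total myofiber Cauchy stress by the one-fiber relation

    P_lv = (σ_f / 3) · ln(1 + V_w / V),

where `V_w` is wall volume and `V` cavity volume. The fiber stretch is
λ = ((V + V_w/3)/(V_ref + V_w/3))^(1/3), measured from the *remodeled*
unloaded cavity volume `V_ref`; passive stress is exponential in stretch,
σ_pas = σ_p0·(exp(C_f·(λ−1)) − 1), with `C_f` the stiffness parameter that
disease raises from 11 to 12.2. Active stress is
σ_act = κ_C·σ_a0·a(t)·f(λ), with contractility scale κ_C (0.795 in HF-rEF),
a rise/plateau/fall activation twitch a(t) over the systolic interval
(0.42·√T s), and a linear length-dependence f(λ) = 1 + 3.58·(λ−1) clipped at
zero. The plateau twitch matters: a peaked twitch never completes ejection
onto the end-systolic pressure-volume relation, which flattens the
Frank-Starling response of the closed loop and removes the pressure signal
the renal volume controller relies on.

The systemic loop has arterial, peripheral/capillary and venous compartments
(linear stressed-volume compliances) plus a pulmonary-venous reservoir that
fills the LV. The right side is lumped into a flow source
q = G·(P_ven − P_pv/γ): systemic venous return sensitive to pulmonary
congestion, so left-sided filling-pressure elevation backs up into the
systemic veins — the pathway by which heart failure produces peripheral
edema here. Valves are ideal diodes smoothed over 10⁻⁶ mmHg. Arterial and
peripheral resistances and the venous-compliance disease ratio are carried
verbatim (SI units) from the reference parameterization; compliance
magnitudes and unstressed volumes are calibrated (see below).

One beat is integrated by fixed-step RK4 (0.5 ms; numba-compiled when
available, identical pure-Python fallback otherwise). RK4 preserves the
circulating-volume invariant exactly. The beat map is iterated to its
periodic fixed point with relative tolerance 10⁻⁶ per beat (adaptive
averaging damps the occasional period-2 beat-map mode).

### Day-scale subsystem

Eleven slow states: blood volume, interstitial volume, plasma and
interstitial sodium amounts, four normalized hormones (renin, ANG II,
aldosterone, ADH), a whole-body autoregulation tone, and the two myocyte
remodeling offsets ΔD, ΔL.

*Fluid exchange.* Trans-capillary filtration follows the Starling relation
Φ = K_f(P_c − P_if − π_c + π_if − π_Na,c + π_Na,if) with K_f = 6.67
mL·min⁻¹·mmHg⁻¹; colloid osmotic pressures from the Landis-Pappenheimer
polynomial (protein masses constant); sodium osmotic pressures from van't
Hoff at 310 K. The interstitial pressure-volume curve uses the published
expansion branch verbatim; the contraction branch is refit for value and
slope continuity at the 15 L branch point because the printed contraction
constants evaluate ~2·10⁴ mmHg there (four orders of magnitude above the
expansion branch). Mean capillary pressure is the beat-averaged interpolant
P_c = w·P_a + (1−w)·P_ven with w = 0.128 calibrated so healthy net
filtration is zero at IFV = 15 L. Trans-capillary sodium exchange combines
convective drag with a large diffusive permeability-surface product
(40 L/min); a small PS leaves the convective salt-carriage loop unstable
(water dragging salt toward the saltier side faster than it dilutes it).

*Kidney.* Whole-kidney GFR from a glomerular pressure balance: preafferent
and afferent (Poiseuille in the arteriolar diameter) resistance drops,
ANG II-controlled efferent resistance, mean glomerular oncotic pressure
π·(1+FF) solved self-consistently with the filtration fraction, scaled by
the ultrafiltration coefficient, permeability fraction and nephron fraction.
Tubular handling is segmental (proximal 70%, loop 80%, distal 85%,
collecting duct ~42% fractional sodium reabsorption at setpoint) with
modulation by ANG II (proximal), aldosterone (distal/CD), pressure
natriuresis (proximal exponent 0.6, CD exponent 1.2), tubuloglomerular
feedback (exponent 0.4 on afferent tone), NHE3 inhibition coupled to SGLT2
blockade, and the osmotic drag of unreabsorbed tubular glucose on both
proximal sodium and CD water. Glucose reabsorption is transport-maximum
limited (SGLT2 1.8 + SGLT1 0.2 mmol/min, smooth saturation); urine flow is
the excreted osmole load at an ADH-controlled urine osmolality.

*Hormones.* First-order kinetics toward algebraic secretion targets. Renin
rises when macula-densa delivery or perfusion pressure falls and is
restrained by ANG II short-loop feedback; ANG II is renin scaled by
(1 − ACE inhibition); aldosterone follows ANG II; ADH integrates osmolality
and volume. Effector factors are multiplicative, equal 1 at setpoint, and
saturate at [0.3, 3]. The efferent-arteriolar ANG II effect is asymmetric
(constriction gain 4 above setpoint, dilation slope 0.5 below): strong
constriction is required for GFR preservation under renal injury, while a
symmetric gain would make ACE inhibition collapse GFR and paradoxically
retain volume. Heart rate is an algebraic map from pulmonary-venous
congestion (a sympathetic surrogate), calibrated to the two published rates
(70 healthy, 75 HF-rEF). A slow whole-body autoregulation tone relaxes the
peripheral-resistance multiplier toward (CO/CO_ref)³ over two days, the
Guyton-type mechanism that lets the kidney set long-term pressure while
metabolic demand sets flow.

*Remodeling.* The Grossman-pattern growth laws: myocyte diameter grows when
peak systolic fiber stress exceeds its healthy reference (saturating at 2×
baseline diameter, regressing with the uncapped rate below reference, with
an atrophy floor at −0.5·D₀ because the published law has no lower cap);
myocyte length grows when end-diastolic fiber stress exceeds its reference
(saturating at 2× baseline length, never regressing). Unloaded cavity
volume dilates as V_LV0·(1 + ΔL/L₀)³ and wall volume follows the cylinder
geometry of the myocyte population plus constant interstitium and (static)
fibrosis. Stresses driving growth are taken from the converged beat of each
macro step, not instantaneous values. The printed rate constants
(K_l0 = 10⁻¹⁰, K_d0 = 1.33·10⁻¹¹, dimensionless units) are interpreted per
abstract slow-time unit with a calibrated clock of 6 minutes per unit,
chosen so the untreated HF-rEF patient's filling pressure progresses from
the anchored 19.7 mmHg to the treated-arm baseline 23.6 mmHg in roughly ten
months with a clear one-year rightward loop shift.

## Timescale splitting

Direct co-integration would cost ~37 million beats per simulated year. The
scheduler instead alternates: (a) iterate the beat map to its periodic fixed
point; (b) freeze the beat summary (MAP, mean capillary pressure, cardiac
output, fiber stresses) together with central-difference sensitivities to
blood volume and autoregulation tone; (c) integrate the slow ODE system
across the macro step (≤1 day) with LSODA (rtol 10⁻⁶, per-state absolute
tolerances), linearizing the beat quantities in blood volume and tone.
Sensitivities are refreshed every 14 days or when blood volume moves more
than 0.05 L. A per-beat-coupled reference integrator (slow states advanced
every cardiac cycle with that cycle's own summary — a ~60-fold finer
coupling) validates the split: over a one-day horizon the two agree within
1% on blood volume, interstitial volume, MAP and EDV, and halving the macro
step changes 8-day transient endpoints by well under 0.5%.

Equilibria are found by multi-day implicit marching followed by a
Newton-type outer/inner polish (inner: a root solve of the smooth
frozen-context slow system; outer: beat refresh), which converges the
healthy equilibrium to ~10⁻¹² relative residual per day. The model is
deterministic throughout — there is no random number anywhere, and repeated
runs are bit-identical.

## Virtual patients

Disease states are parameter overlays: renal injury (preafferent resistance
14→25.5, afferent diameter 16.5→15.5 µm, permeability ×0.8, nephrons ×0.6);
the cardiac block (κ_C 0.795, C_f 12.2, arterial resistance ×1.2,
peripheral ×1.23, venous compliance ×0.7); diabetes (plasma glucose
5.5→8 mmol/L only). The HF-rEF patient additionally carries established
eccentric hypertrophy (ΔL = 33.5 µm, ΔD = 20 µm, fitted to the published
chronic-HF baseline): growing the dilated heart from the growth laws alone
is not dynamically admissible here, because an undilated injured ventricle
cannot eject against the renally defended arterial pressure and the volume
loop runs away. The HF-rEF baseline is the frozen-growth equilibrium of the
full parameter set, advanced with growth active until EDV first crosses
358.67 mL (the anchor); treatment protocols run forward from that anchor.
Healthy, hypertensive and diabetic patients are true equilibria with all
feedbacks at setpoint.

## Interventions

Steady-dosing pharmacodynamics only, no pharmacokinetics; effects switch on
as a step at the scheduled day, touch only renal/hormonal parameters, and
are fully reversible. ACE inhibition blocks 92.5% of ANG II formation
(calibrated once against the first-month HF-rEF volume response, then
frozen); its natriuresis flows mainly through the aldosterone→distal/CD
axis — an equally strong ANG II→proximal effect creates an unstable
macula-densa→renin→ANG II→proximal loop. SGLT2 inhibition removes 98% of
SGLT2 transport capacity (calibrated against the healthy/diabetic 24-h
glucosuria class and their ≈2:1 ratio) with NHE3 coupling 0.08 and tubular
glucose coupling to proximal sodium (0.1 per mmol/min) and CD water
(0.8 per mmol/min).

## Calibration and parameter provenance

Printed reference values (Tables of the reference parameterization) are
carried verbatim: the Starling coefficients, interstitial-curve expansion
branch, remodeling rate constants and caps, disease-state parameter values,
and the SI circulatory resistances. Everything supplement-resident was
calibrated in stages against the printed outputs, each stage frozen before
the next: (1) the beat-scale constitutive and circulatory constants against
the healthy hemodynamics (SV 71 mL, EDV ≈ 96 mL, EDP 6.5 mmHg, MAP 84.4
mmHg) plus a positive closed-loop Frank-Starling gain; (2) renal closure
constants so the healthy kidney excretes exactly the daily sodium and water
intake at GFR 95.8 mL/min; (3) RAAS/natriuresis gains against the
renal-injury step (MAP → 96, GFR → 80.8); (4) the HF-rEF hypertrophy state
against the chronic-HF baseline; (5) the capillary-pressure weight and
interstitial protein mass against healthy (15 L) and congested (23.5 L)
interstitial volumes; (6) drug magnitudes as above. `PARAM_INFO` marks
every parameter `reference` or `calibrated`, and every run log echoes the
full vector plus the interstitial-curve refit.

## Numerical choices

Beat step 0.5 ms RK4; valve smoothing 10⁻⁶ mmHg; beat-map tolerance 10⁻⁶
(10⁻⁸ inside equilibration); slow integrator LSODA rtol 10⁻⁶ with per-state
atol down to 10⁻¹³ for the remodeling offsets; macro step 1 day in
protocols, 2 days inside equilibration; domain guards clamp implicit-solver
trial states (volumes, concentrations, MAP range) without affecting
admissible trajectories; renal fixed-point loops (filtration fraction, TGF)
iterate to 10⁻¹² with 0.5 damping. Degenerate inputs raise informative
errors (non-physical volumes, out-of-range MAP, invalid fractions), and the
interstitial curve warns outside its 5–40 L fitted range.

## What the studies do and do not show

The simulated trials use a single representative patient per state; there
is no inter-patient variability, no sex-specific physiology, no exercise
reserve, no diurnal glucose variation, and no diabetic nephropathy
progression. The lumped circulation has no wave propagation, so early
systolic ejection is faster than measured loops and pulse pressure is
underestimated by a few percent (systolic ~105 vs ~112 mmHg healthy).
Valves are perfect; the heart is spherical. The two-compartment fluid space
ties the steady interstitial drawdown to blood volume along the
colloid-osmotic/hydrostatic manifold, giving an IFV:BV percentage-reduction
ratio of ≈2.5–3 for every patient; reproducing strongly patient-specific
ratios (notably a diabetic HF-rEF interstitial reduction of ~17% at ~3%
blood-volume reduction) would need a third, nonosmotically-bound sodium
store, which is outside this model's compartment structure. Passing tests
therefore demonstrate internal consistency and agreement with the published
class-level behaviors under these assumptions, not validated prediction for
real patients.
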