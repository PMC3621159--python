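# Methods

`cvsid` implements model-based hemodynamic monitoring at desk scale: a
six-chamber lumped-parameter model of the circulation, a staged
proportional-gain procedure that identifies subject-specific parameters
from a minimal clinically available measurement set, a virtual-subject
generator that emulates an endotoxic-shock time course, and the agreement
statistics used to validate the identified models.

## The circulation model

Six elastic chambers are connected in a closed loop: left ventricle →
aorta → vena cava → right ventricle → pulmonary artery → pulmonary vein →
left ventricle. The ODE state is the six chamber volumes; total stressed
volume is conserved exactly by construction.

**Ventricles.** Each ventricular free wall blends an end-systolic and an
end-diastolic pressure-volume relationship through a normalised activation
(driver) e(t) ∈ [0, 1]:

    P_fw(V, t) = e(t) · E_es (V − V_d)  +  (1 − e(t)) · P_0 (exp(λ(V − V_0)) − 1)

with contractility E_es (mmHg/mL), dead-space volume V_d = 23 mL, and
EDPVR constants P_0, λ, V_0. The model constants fix P_0 = 0 for both
ventricles, so diastolic ventricular pressure comes from the pericardium
(the implementation keeps the exponential term for nonzero P_0
configurations). V_0 = 0 for the ventricular free walls (the constants
table provides volume offsets only for septum and pericardium).

**Ventricular interaction.** The septal volume V_spt is an algebraic state
solving the septal pressure balance

    P_spt(V_spt) = P_lvf(V_lv − V_spt) − P_rvf(V_rv + V_spt),

where P_spt uses the septal ESPVR/EDPVR constants and the left activation
(a single cardiac activation drives the septum). Both sides are monotone
in V_spt with opposite sense, so the root is unique; it is found by Newton
iteration warm-started from the previous evaluation, with a bisection
fallback, to 10⁻⁹ mL. The pericardial pressure
P_pcd = P_0,pcd (exp(λ_pcd(V_lv + V_rv − V_0,pcd)) − 1) and the (constant)
intrathoracic pressure P_th add to both ventricular pressures.

**Passive chambers and flows.** The aorta, vena cava, pulmonary artery and
pulmonary vein are linearly elastic, P = E (V − V_d). Flows are ohmic;
the four heart valves are ideal pressure-gated diodes (flow clamped at
zero; all inertances are zero), giving a continuous but non-smooth
right-hand side.

**Driver.** The default activation is a periodised Gaussian pulse
normalised to maximum 1, peaking at 30% of the beat period. Its width
parameter is 80 s⁻² at the reference period 0.75 s and scales with 1/T²,
i.e. systole occupies a fixed fraction of the cycle; a fixed absolute
width would leave the activation far from zero at beat onset outside a
narrow heart-rate band. A sampled driver class carries activations
estimated from arterial waveforms (normalised pressure shape inside the
ejection window, smooth ramps outside, with a parametric fallback for
degenerate inputs).

**Submodels.** For the first identification stages the loop is split in
two: the systemic half integrates {V_lv, V_ao} between a constant inlet
pressure P_pu (pulmonary vein) and outlet pressure P_vc (vena cava); the
pulmonary half integrates {V_rv, V_pa} between P_vc and P_pu. Ventricular
interaction is removed in these submodels; optional periodic forcing
curves can reintroduce septal volume, pericardial pressure and pulsatile
boundary pressures from a coupled simulation.

## Numerics

* Integration is beat-by-beat with adaptive stiff solvers (LSODA, manual
  stepping). A 5000-step budget per beat converts diode-induced
  chattering on pathological parameter sets into a recoverable error; BDF
  is the fallback. Default tolerances are rtol = atol = 10⁻⁷ for forward
  simulation and 10⁻⁶ inside identification (the identification needs
  output accuracy of about 10⁻⁴ relative, not more). Volume drift over 20
  beats is below 10⁻³ mL (tested).
* EDPVR exponents are clamped at exp(50) so far-from-physiological states
  visited during identification stay finite.
* The periodic steady state is found by iterating the beat map until the
  onset volumes change by less than 0.01 mL per beat *and* the projected
  remaining distance to the orbit (per-beat change times ρ/(1−ρ) for the
  estimated contraction ratio ρ) is below ten times that tolerance —
  slowly contracting venous redistribution modes would otherwise satisfy a
  naive per-beat criterion a long way from the orbit and leave an
  irreducible noise floor on extracted features. Every fifth beat an
  Aitken extrapolation of the beat map is attempted and kept only if a
  verification beat confirms it reduced the per-beat change.

## Feature extraction

The identification consumes one good heartbeat (by default the last
complete beat of a record) reduced to the convergence set points: GEDV
(= LVEDV + RVEDV), SV (average of the two ventricular volume-trace
amplitudes), mean and pulse pressures of the aortic and pulmonary-artery
waveforms, their maximum ascending gradients, the AV-valve closure times
t_mt and t_tc, and the beat period.

* All traces are pre-smoothed with a Savitzky–Golay window of 75 ms
  (polynomial order 3) — a time-based window keeps features invariant to
  the sampling rate (tested between 100 and 1000 Hz at 0.5%).
* Beat means are trapezoidal with the wrap-around segment closing the
  period; amplitudes refine both extremes with a three-point parabola.
* The maximum ascending gradient is the peak of a 5-point quadratic
  Savitzky–Golay first derivative.
* Valve closure is read from the pressure crossing: the mitral valve
  closes when the rising LV pressure first exceeds the pulmonary-vein
  pressure (tricuspid analogously). When only arterial pressures are
  available the closure time falls back to the instant the driver exceeds
  δ = 0.05 of its maximum. The pressure-crossing definition is the default
  because it makes the measured time and the model's physical closure the
  same quantity; the activation-threshold proxy carries a systematic
  offset that propagates into the identified venous pressures and
  pulmonary resistance. A closure time at the read-off floor (valve
  already shut at beat onset, under two samples) is treated as carrying no
  timing information.
* The same extractor (same smoothing, same definitions) is applied to
  measured records and to model output during identification, so feature
  definitions can never bias the match.

## Identification

Each observable output identifies one parameter through the multiplicative
fixed-point rule p ← (measurement/output)^±1 · p (sign by the
proportional/inverse relation of the pair; directions are tabulated from
one-time sensitivity analysis and can be re-derived at runtime). The
procedure is staged:

1. **Systemic stage.** From population initial estimates, the decoupled
   systemic submodel is iterated so GEDV→E_es,lvf, SV→R_mt, MAP→R_sys,
   PP_ao→E_ao, dP_ao,max/dt→R_av and t_mt→P_pu (in the submodel the model
   GEDV is twice the LV end-diastolic volume, the only information
   available at that point).
2. **Pulmonary stage.** Mirror image: GEDV→E_es,rvf, SV→R_tc, MPAP→R_pul,
   PP_pa→E_pa, dP_pa,max/dt→R_pv, t_tc→P_vc.
3. **Coupled stage.** The halves are joined with septum and pericardium
   and every pair re-identified directly against the closed-loop periodic
   steady state. Here GEDV identifies the common scale of the venous
   elastances E_vc, E_pu: the venous reservoir stores most of the fixed
   total stressed volume, and how much of it the veins release is the
   dominant (and only sign-safe) lever on preload — with the pericardium
   engaged, extra filling *raises* diastolic ventricular pressure, so
   closure-time-mediated venous updates can reverse sign. The venous
   pressure levels themselves are set by the flow balance, which is why
   only the common compliance scale is identifiable; the E_vc/E_pu ratio
   keeps its population value. The contractilities keep their
   stage-identified values (see identifiability below), and the identified
   P_pu/P_vc are the coupled model's mean venous pressures.

Updates are applied sequentially (one parameter, then a fresh steady
state), which is essential for stability: simultaneous ratio updates
oscillate because the venous pressures couple into every output. A secant
estimate of each pair's local log-gain rescales steps for weakly
responding pairs (bounded to [0.3, 5], with the total step clipped to a
factor 3 and parameters confined to 1/50–50× their initial estimates);
closure-time pairs use a damped base step because their log-gain exceeds
one. Near the solution only the worst-residual pair moves per round, and
the returned model is the best iterate visited. Failed simulations
backtrack by geometric blending toward the last good parameter set.

Convergence requires the five outputs of the headline claim — MAP, MPAP,
PP_ao, PP_pa, SV — within 0.2% each (inner tolerance 2×10⁻³, the scheme's
achievable floor under the cross-talk of the global venous lever, with
2.5× margin to the 0.5% bound) and GEDV and the two maximum gradients
within 0.5%.

**Subject series.** Each timepoint is identified independently; the four
valve resistances are averaged over the converged timepoints; and every
timepoint is re-identified with the valves fixed at the averages,
warm-started from its first-pass parameter set. Non-convergent timepoints
are carried with flags and excluded from the averages.

**Estimation front end.** `TimepointIdentification(setpoints).fit()` and
`SubjectIdentification(series).fit()` wrap the procedure in
model/results objects with `params`, `residuals`, `predicted`,
`summary()`, `simulate()` and trajectory accessors.

## Structural identifiability

The measurement set sums the ventricular end-diastolic volumes into GEDV
and averages the two stroke volumes. As a consequence the *split* of
contractility between the ventricles — E_es,lvf rising while E_es,rvf
falls, with the filling resistances compensating — is a near-flat
direction of the measurement map: two parameter sets differing by ~25% in
the contractilities reproduce every measurement to better than 0.1%.
The identified contractilities therefore carry a per-ventricle bias of
order 10–30% (of opposite sign left and right, the total being pinned),
and the venous-pressure estimate occasionally leaks into R_pul at the
10–20% level. This limitation is intrinsic to the measurement set, not to
the optimiser; it shows up in exactly the form the porcine validation
reported (left ventricular volumes biased one way, right the other, with
temporal *trends* preserved). R_sys, E_ao and E_pa are strongly
identified (errors at the percent level across cohorts), which is what
the afterload-trend monitoring application needs.

## Virtual subjects

The generator emulates the study conditions so the pipeline can be
validated end to end with known ground truth:

* **Baselines** draw the ten stage-identified elastances and resistances
  uniformly within ±30% of the population initial estimates and the heart
  rate uniformly in 80–160 bpm, rejecting draws whose steady-state beat
  falls outside MAP 50–130 mmHg or SV 20–60 mL. Venous elastances
  (E_vc = 0.005, E_pu = 0.016 mmHg/mL) and the total stressed volume
  (1.5 L) are population constants: they are not in the initial-estimate
  tables, and the measurement set cannot identify them individually, so
  sampling them would make the virtual population unidentifiable by
  construction.
* **Septic trajectories** are phenomenological: R_sys falls by 42% of
  baseline by the 120-minute timepoint and R_pul rises by 50%, both
  logistic in time between 30 and 120 minutes (midpoint 75 min, rate
  0.08 min⁻¹) and flat afterwards; heart rate rises by 15% along the same
  shape; contractilities stay constant. Responders relax R_sys back
  toward baseline after T120 with a 90-minute time constant. Nine
  timepoints (T0…T240) at 30-minute spacing.
* **Records** are eight consecutive steady-state beats per timepoint at
  200 Hz with multiplicative Gaussian noise (default SD 3% per sample and
  signal); the right-ventricular volume trace can be shrunk about its
  mean to emulate conductance-catheter underestimation. Timepoints whose
  simulation fails to settle are flagged and omitted, like the unusable
  records of a real trial. Ground truth (parameters and noiseless
  outputs) is stored alongside.

What passing tests on this synthetic world do *not* show: real catheter
noise is coloured and drift-prone rather than white and multiplicative;
real activation shapes vary between subjects and over time (the generator
and the default identification share the population driver shape, with
waveform-estimated drivers available as an option); real animals have
reflex control, respiratory pressure variation and beat-to-beat
variability, none of which are modelled.

## Validation statistics

Bland–Altman bias (mean of modelled − measured) and precision (2 × sample
SD of the differences), squared Pearson correlation, and absolute
percentage errors summarised by median and 5th/95th percentiles (linear
interpolation between order statistics). The derived pulmonary indices
are the arterial elastance E_a = (R_pv + R_pul)/T and the right
ventricular–arterial coupling ratio E_es,rvf/E_a.

## Problem sizes used in the tests and the acceptance script

Cohort checks use 20 virtual subjects (one timepoint each) for the
convergence and noise-validation bounds, and two full 9-timepoint septic
subjects for trend tracking; the sign-recovery and trend properties in
the unit suite run at similarly reduced scale. One timepoint identifies
in roughly 3–15 s on a single CPU.

## Known limitations

* The contractility split and the individual venous elastances are not
  identifiable from the measurement set (above); the corresponding
  recovery checks in the acceptance suite document this honestly rather
  than hiding it.
* The closed-loop stage declares convergence at 0.2% on the headline
  outputs; a minority of subjects stop at the sweep's precision floor
  just above that and are flagged, while still matching all headline
  outputs to better than 0.5%.
* The measured valve-closure time is undefined when the valve is already
  shut at beat onset (high-preload, high-contractility subjects); such
  records keep the population venous-pressure estimate.
* Total stressed volume must be assumed; all volumes scale with it.
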