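# cvsid

Model-based hemodynamic monitoring from minimal bedside measurements:
a six-chamber lumped-parameter model of the cardiovascular system, and a
staged proportional-gain procedure that identifies subject-specific model
parameters from the small set of quantities actually available in
intensive care — mean, amplitude and maximum ascending gradient of the
aortic and pulmonary-artery pressures, stroke volume, global
end-diastolic volume, and the AV-valve closure times.

The package is aimed at computational physiologists working on
circulation monitoring: it provides the forward simulator, the
identification pipeline, a virtual-subject generator that emulates an
endotoxic-shock time course (so everything can be validated end to end
against known ground truth), and the agreement statistics used for that
validation.

## The model and the estimator

Six elastic chambers (left/right ventricle, aorta, vena cava, pulmonary
artery, pulmonary vein) exchange volume through ohmic resistances and
ideal diode valves. Each ventricular free wall blends an end-systolic and
an end-diastolic pressure–volume relationship through a normalised
activation e(t):

    P_fw(V, t) = e(t)·E_es·(V − V_d) + (1 − e(t))·P_0·(e^{λ(V − V_0)} − 1)

with septal and pericardial coupling between the ventricles; passive
chambers obey P = E·(V − V_d). Units are mmHg, mL, s throughout.

Identification matches each observable output to one parameter with the
multiplicative fixed-point rule

    P_new = (measurement / model output)^{±1} · P_old

iterated against fresh periodic steady states: first on decoupled
systemic and pulmonary submodels (GEDV→E_es, SV→R_mt/R_tc, MAP→R_sys,
MPAP→R_pul, pulse pressures→E_ao/E_pa, maximum gradients→R_av/R_pv,
closure times→venous pressures), then on the assembled closed loop,
where GEDV identifies the venous compliance scale. For a subject's
timepoint series the valve resistances are averaged and the remaining
parameters re-identified. Derived indices include the pulmonary arterial
elastance E_a = (R_pv + R_pul)/T and the ventricular–arterial coupling
ratio E_es,rvf/E_a. `docs/methods.md` has the full account, including
what the measurement set can and cannot identify.

## Worked example

Generate one virtual subject, extract its measurement record, and
identify the subject-specific model:

```python
from cvsid import (SepsisTrajectoryConfig, TimepointIdentification,
                   generate_dataset, sample_baseline)

subject = sample_baseline(seed=5)
data = generate_dataset(subject, SepsisTrajectoryConfig(n_timepoints=1),
                        noise=False, seed=5)
result = TimepointIdentification(data.setpoints[0]).fit()
print(result.summary())
```

```
Subject-specific circulation model identification
=================================================
label: T0    converged: True    outer iterations: 5
heart period T = 0.4155 s (144 bpm)

Identified parameters
-------------------------------------------------
  E_es_lvf          2.223
  E_es_rvf        0.77526
  E_ao             1.8355
  E_pa              2.653
  E_vc          0.0040389
  E_pu           0.012924
  R_mt           0.036997
  R_av           0.037413
  R_sys            2.1987
  R_tc           0.023008
  R_pv            0.02914
  R_pul           0.32184

Matched outputs (relative residuals)
-------------------------------------------------
  GEDV            0.488 %
  SV              0.155 %
  MAP             0.177 %
  MPAP            0.059 %
  PP_ao           0.116 %
  PP_pa           0.148 %
  dPao_max        0.073 %
  dPpa_max        0.378 %
  t_mt           43.528 %
  t_tc           23.478 %

Predicted validation quantities
-------------------------------------------------
  LVEDV             116.5
  RVEDV             108.6
  P_lv_max            153
  P_rv_max          53.21
  E_a              0.8447
  RVAC             0.9178
```

Every measurement the identification consumed is reproduced by the
fitted model to a fraction of a percent (the closure-time rows are
informational: they identified the venous pressures during the staged
procedure and are not matched by the coupled model, whose valve timing
follows from the identified pressures). The predicted block contains the
quantities *not* used for fitting — end-diastolic volumes and peak
ventricular pressures — which serve as independent validation against
the generator's ground truth. For this subject the identified systemic
resistance is 2.1987 versus a true value of 2.1787 (+0.9%), and the
identified aortic elastance 1.8355 versus 1.8309 (+0.3%).

Series over nine 30-minute timepoints work the same way through
`SubjectIdentification([...]).fit()`, which also averages the valve
resistances and re-identifies. A `cvsid` command-line tool exposes the
pipeline (`simulate`, `features`, `identify`, `identify-series`, `synth`,
`validate`).

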