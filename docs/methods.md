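# Methods

## Model

The circulation is a closed zero-dimensional hydraulic loop with eight
volume compartments: four heart chambers (LV, RV, LA, RA) and four
vascular reservoirs (systemic arterial and venous, pulmonary arterial
and venous). Chambers follow the time-varying elastance model: the
instantaneous pressure interpolates between a linear end-systolic
relation and an exponential end-diastolic relation,

    P(V, t) = e(t) · E_es (V − V0)  +  (1 − e(t)) · β (exp(α (V − V0)) − 1),

with a shared volume intercept V0. The activation function is the
standard two-phase form: a raised half-sine from activation onset to
1.5·T_max (so e = 1 exactly at T_max, the time to end-systole),
followed by exponential relaxation with time constant τ. Atria
activate at the start of the cycle; ventricular activation is delayed
by a PR-like interval of 0.16 of the cycle length, and the atrial
T_max is set to that interval divided by 1.5 so atrial systole
completes exactly at ventricular onset at any heart rate. (A fixed
atrial T_max of ~0.09 s would violate that alignment away from one
specific rate; the alignment is the constraint we kept.)

Each vascular bed is a characteristic impedance Rc in series with the
outflow valve, an arterial compliance Ca drained through the
peripheral resistance Ra into a venous compliance Cv, which returns
blood to the downstream atrium through a venous resistance Rv. Valves
are ideal diodes in series with a small resistance (0.005 mm Hg·s/mL,
hemodynamically negligible). Reported aortic and pulmonary-artery
pressures are taken at the catheter site between the valve and the
arterial compliance: P = P_Ca + Rc·Q_valve while the valve conducts.

### Compression assist

The device applies a trapezoidal epicardial pressure waveform added
identically to both ventricular pressures (uniform biventricular
assist; atria receive nothing): linear rise (0.10 s) to a systolic
plateau of `amplitude − offset`, a plateau hold, linear decline
(0.05 s) to a constant negative diastolic level of `−offset`, held for
the rest of the cycle. Inflation triggers 0.02 s after ventricular
activation onset and, by default, the decline completes at 1.5·T_max.
The shipped settings are `dcc19` (amplitude 23, offset 4 → plateau
+19 mm Hg) and `dcc30` (amplitude 34, offset 4 → plateau +30 mm Hg).
Holding suction for the entire diastole is a deliberate idealization
of the real device, which deflates only briefly.

## Integration

A fixed-step classical Runge–Kutta scheme advances the eight
compartment volumes; the nominal step of 0.5 ms is rounded so that an
integer number of steps tiles one cycle exactly, which makes beats
strictly periodic and runs bit-for-bit reproducible. The right-hand
side is pure volume bookkeeping over the resistor/diode network, so
total volume is conserved to rounding (≪10⁻⁶ of the stressed blood
volume per beat). Beats are integrated until the start-of-beat volumes
change by less than 0.05 mL between consecutive beats (cap 200 beats);
a step-halving check on the converged state moves mean aortic pressure
by <0.1 mm Hg. The initial state places each chamber at its passive
volume for a nominal filling pressure and splits the remaining
stressed volume over the vascular compartments; any distribution
converges to the same cycle. When the assist is switched on in an
experiment, integration restarts from the converged unassisted state —
this mirrors device activation in vivo and avoids large cold-start
transients in the strongly assisted right ventricle. Warm-start states
are always rescaled to the parameter set's stressed blood volume,
since total volume is conserved by the integrator.

## Calibration

Heart rate is copied from the targets. The free parameters (stressed
blood volume; Rc, Ra, Ca of both beds; the four chamber elastances;
ventricular T_max and τ) are fitted by bounded least squares on their
logarithms, with residuals weighted by the acceptance tolerances
(pressures ±2 mm Hg inclusive, cardiac output ±0.05 L/min, ejection
fraction ±2 percentage points). The first attempt starts from an
analytic guess (resistances from mean pressure drops over flow,
compliances from stroke volume over pulse pressure, elastances from
end-systolic pressure over the implied end-systolic volume); further
seeded restarts jitter that guess. The accepted fit is re-simulated
from a cold start before the verdict is issued. An unreachable target
set returns `accepted=False`, never a silent success. Elastance bounds
are physiological (LV 0.3–12, RV 0.5–10 mm Hg/mL); without the RV
lower bound the optimizer can reach a degenerate dilated-RV minimum
that matches the pressures but has unphysiological assist behaviour.

## The ovine base parameter set

Passive (EDPVR) constants, venous compliances and return resistances
are fixed properties of the base set (`dccsim.presets.ovine_base`),
because passive chamber stiffness does not change acutely under
esmolol: the same constants must serve the healthy baseline and the
heart-failure fits. They were chosen during model development so that

- the LV passive curve passes ~15 mm Hg at ~72 mL (the HF operating
  point implied by the target EF, CO and HR) with local stiffness
  ~0.9 mm Hg/mL;
- the RV passive curve passes ~13.5 mm Hg at ~47 mL with a large
  pressure scale (β = 4.5 mm Hg), which keeps the RV end-systolic
  reserve small in HF (fitted E_es ≈ 2 mm Hg/mL) so that uniform
  biventricular assist does not congest the pulmonary bed, while the
  curve remains compliant enough at baseline filling pressures for the
  healthy stroke volume;
- the systemic venous reservoir is large (40 mL/mm Hg, ~1 mL/mm Hg/kg
  for an adult sheep), so venous pressure, and with it venous return,
  is stable when cardiac output rises under assist;
- the atrial kick is weak in HF (RA E_es 0.15 mm Hg/mL as fitted
  starting point) and strengthens substantially in the baseline fit —
  the mechanism by which end-diastolic ventricular filling exceeds the
  mean venous pressure in the healthy state.

These are modelling choices, not measurements; the calibrated
quantities (afterloads, elastances, stressed volume, timing) are the
contract, and the fit criteria — every pressure within ±2 mm Hg — are
enforced before any prediction is made.

## Analysis conventions

- Systolic/diastolic pressures are beat extrema of the catheter-site
  signal; mean pressures are trapezoidal beat averages.
- PCWP is proxied by mean pulmonary venous pressure, CVP by mean right
  atrial pressure.
- End-diastole is the instant of maximal ventricular volume, applied
  identically with and without assist; end-systole is the instant of
  maximal native chamber elastance ratio P_chamber/(V − V0) with the
  assist term removed before forming the ratio (the total-pressure
  ratio keeps rising briefly after peak elastance under assist and
  under-reads the ESPVR shift). The reported end-systolic pressure is
  the measured, assist-inclusive one.
- ESPVR sweeps rerun the loop at five stressed-blood-volume levels
  (±20%), the closed-loop analog of a vena-cava occlusion, and fit a
  line through the end-systolic points; stroke work is the enclosed
  loop area (−∮P dV); PVA adds the end-systolic triangle to (V0, 0).
- Effect sizes are elementwise differences of the assisted and
  unassisted summary panels of the same calibrated parameter set.
- Cohort emulation draws independent truncated-normal target profiles
  (±3 SD, positivity, systolic ≥ mean ≥ diastolic by redraw) from the
  published mean ± SD summaries; no covariance between metrics is
  published, so none is modelled — a stated fidelity limit.
- t-tests are classical two-sided Student tests (pooled-variance
  unpaired, difference-based paired), α = 0.05, no multiple-testing
  correction; zero-variance inputs return p = 1 (zero mean difference)
  or the limiting p = 0 with a degeneracy flag.

## What the synthetic conditions do and do not show

The packaged target fixtures are the published cohort means; per-sample
device settings and per-animal parameter values are not public, so
reproduction is at the mean level. Passing tests show that the model
family plus the stated calibration protocol reproduces the validated
mean effect profile and the PV-loop analysis; they do not show
per-animal predictive accuracy, and the cohort sampler's independence
assumption understates the correlation structure of real hemodynamic
panels.

## Known limitations

- No pericardium, no septal ventricular interaction, no baroreflex;
  the assist waveform is perfectly ECG-synchronous.
- The exponential EDPVR saturates at −β below V0, so passive recoil is
  weak at very low volumes; the diode network and the decline of the
  assist waveform are what terminate ejection under strong assist.
- RVEDP is read at the post-kick volume maximum and is sensitive at
  the few-tenths-of-a-mm Hg level to atrial timing choices.
- Metrics that depend on pulmonary pulsatility (PASP/PADP) are the
  least constrained by the model structure, consistent with their
  being the only metrics the in-vivo comparison flagged.
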