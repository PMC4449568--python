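# Methods

## The intracranial circuit

The simulator implements the classic lumped-parameter model of cerebral
hemo- and hydro-dynamics as a linear electrical analog. The vascular path
runs P_a —R1— P1 —R2— P2(=P_c) —Rpv— Pv —Rdv— P_vs —Rve— P_cv, with
compliances C1, C2 (arterial segments) and Cvi (proximal veins) referenced
to the intracranial pressure node P_ic, Cic (craniospinal compartment) and
Cve (extracranial veins) referenced to ambient pressure, and the CSF loop
P_c —Rf— P_ic —Ro— P_vs (formation from the capillaries into the CSF
space, outflow into the sinus). Default constants (resistances in
mmHg·s/ml, compliances in ml/mmHg): R1 = 2.4, C1 = 0.03, R2 = 3.64,
C2 = 0.06, Rf = 2380, Ro = 526, Rpv = 0.88, Cvi = 0.46, Rdv = 0.614,
Rve = 0.16, Cve = 2.34, Pcv = 4 mmHg, Cic = 0.95.

All elements are linear and time-invariant. The published model's
nonlinear craniospinal elastance, collapsible bridging veins and
autoregulation feedback are deliberately out of scope: the constant-
parameter circuit is exactly the setting in which the simple-resistance
reduction is derivable, and it is the configuration the validation uses.
Note an inconsistency carried over faithfully from the source
parameterizations: the circuit uses Ro = 526 while the SR estimator's
printed constant is R_o = 523; the difference moves the estimate by
< 0.03 mmHg at physiological capillary pressures.

### Integration

The circuit is a 5-state LTI system C·dx/dt = −G·x + B·u with inputs
u = (P_a, P_cv + offset). Rather than a generic stiff ODE solver, the
simulator discretizes it exactly on the uniform sample grid
(first-order-hold matrix exponential, `scipy.signal.cont2discrete`), then
runs the five modal recursions as IIR filters. For inputs that are
piecewise linear between samples this is exact to rounding, it is
unconditionally stable despite the ~3-orders-of-magnitude stiffness the
CSF resistances introduce (Rf·Cic ≈ 2×10³ s against vascular time
constants of ~0.1 s), and it simulates a 45-s trial in well under a
millisecond — which is what makes the 200-subject null-calibration study
practical. A test cross-checks the traces against an independent
charge-balance formulation integrated with `solve_ivp`/BDF at rtol 1e-8.

The initial state is the resistive steady state of the time-averaged
input over the first ~5 s. Initializing at the instantaneous first sample
(an arbitrary point of the pulse) would displace the slow CSF mode by up
to ~1 mmHg, and with its ~10-minute time constant that error does not
relax within a trial; it would instead appear as a spurious monotone ICP
drift across the analysis windows. For constant inputs both definitions
coincide.

## The SR estimator

Below the 0.2 Hz cutoff the compliances carry no current and the circuit
reduces to the two-stage resistive model in the README. The reduction is
exact at DC: the DC-equivalence test drives the pipeline with constant
signals and matched constants (R_a = R1 + R2 = 6.04, P_vs set to the
network's sinus-node pressure) and reproduces the resistive network's
P_ic to ~1e-11 mmHg. With the printed defaults (R_a = 6, fixed
P_vs = 6 mmHg) the estimator carries a small bias away from the
P_a ≈ 100 mmHg operating point where those round numbers are exact — at
mean ABP 80 mmHg the fixed venous-sinus pressure alone contributes
~0.35 mmHg.

### Low-pass filtering

`lowpass_dc` is a 4th-order Butterworth applied forward-backward
(zero-phase, unit DC gain). The record is extended at both ends with its
own mean over 3/cutoff (15 s at the default 0.2 Hz) before filtering.
Reflection padding — the usual default — mirrors entire pulses around the
boundary sample, which biases the extracted trend near the edges by an
amount that depends on where in the cardiac cycle the record happens to
start; because the evaluation protocol's first rest window abuts t = 0,
that bias is common-signed across trials and corrupts the paired test's
calibration. Mean padding instead relaxes the trend toward the record's
DC level: window means are unbiased, at the cost of a boundary-relaxation
zone (~3/cutoff at each end) inside which refiltering is not exactly
idempotent.

### Beat processing

Beat onsets are found by peak-picking the derivative of the 0.5–10 Hz
band-passed signal with a 0.3-s refractory period; the detection threshold
is 0.4× the median height of refractory-spaced candidate peaks (robust to
isolated noise spikes), and each onset is placed at the pre-upstroke
minimum of the raw signal. Per-beat features follow the end-diastolic
convention: systolic = in-beat maximum, diastolic = value at the next
onset, mean = sample mean over the beat; the trailing incomplete beat is
dropped. The ABP→CBFv time shift is the median over matched beats of the
systolic-peak time difference, positive when the peripheral pressure lags
the Doppler velocity, and is applied as P_MCA(t) = P_r(t + τ).

## The comparator estimators

**PI regression.** Gosling's pulsatility index per beat mapped through
ICP = 5.305·PI + 4 (coefficients as published for this protocol). Scale
invariance of PI makes the method blind to proportional CBFv changes —
the mechanistic reason it under-detects VM episodes.

**Two-element model.** Q = (P_MCA − P_ic)/R_a + C_a·dP_MCA/dt with ICP
constant over a window (default 60 s, configurable down to one beat; the
45-s trial examples use 5 s so the method can resolve the maneuver at
all). Per beat: (i) C_a by no-intercept regression of Q on dP/dt over the
top quartile of dP/dt, where the compliance branch dominates; (ii) R_a
from two instants of equal dP/dt, where compliance currents cancel — for
every sample the crossings of its derivative value elsewhere in the beat
are located by linear interpolation and the pair with maximal flow
separation is used (discrete-sample matching under a coarse tolerance
leaves an R_a error of several percent, which a 15 ml/s mean flow
amplifies to several mmHg of ICP); (iii) beat ICP = mean(P) −
R_a·mean(Q − C_a·dP/dt); (iv) C_a re-estimated once with the resistive
flow (P − P_ic)/R_a subtracted, since the first-pass regression is biased
upward by the resistive current (~25% for physiological waveforms). dP/dt
is computed on the full record so beat-boundary samples keep central
differences. On data generated by the model itself the procedure returns
C_a and R_a to ~1e-4 relative error and ICP to < 1e-3 mmHg; tests assert
the 10%/1 mmHg level across 20 seeds.

## The synthetic waveform generator

Each ABP beat is a Gaussian systolic upstroke (σ = 45 ms) into an
exponential diastolic runoff, joined continuously, with the per-beat
offset chosen so every beat averages to the configured mean pressure.
Defaults emulate a healthy adult at rest: 45-s records at 100 Hz, heart
rate 70 bpm with 3% beat-interval jitter, mean ABP 90 mmHg, pulse
pressure 40 mmHg, additive measurement noise 1 mmHg (ABP) and 1 cm/s
(CBFv). Three stochastic components supply the slow variability real
recordings have: an Ornstein–Uhlenbeck ABP baseline process (σ = 2 mmHg,
correlation time 10 s; the Mayer-wave/vasomotion band), a respiratory
baseline oscillation (0.25 Hz, 3 mmHg amplitude, random phase), and an
independent OU process on CBFv (σ = 1 cm/s) representing cerebral
vasomotion and probe drift not shared with systemic pressure. The OU
components are demeaned per record so configured means are preserved
exactly. All randomness flows from a single integer seed;
identical configuration gives bit-identical output.

A Valsalva trial (45 s; maneuver over 15–30 s) adds a ramped offset
(1-s linear ramps) to the central-venous source of the circuit — the
electrical expression of the raised intrathoracic pressure — and
optionally to systemic ABP. Reference CBF and ICP come from simulating
the circuit with the generated ABP; CBFv = CBF/α plus noise. The passive
network guarantees the true ICP averages higher during the maneuver for
any positive venous offset; at the default 10 mmHg offset roughly a third
of the rise appears promptly (capacitive coupling through the venous
compliances) with the remainder creeping in on the slow CSF time scale,
so the 10-s VM analysis window sees a ~3 mmHg true elevation.

What the generator does **not** emulate: the four-phase systemic
hemodynamics of a real Valsalva response, respiratory/PCO₂ coupling to
cerebral tone, autoregulation, measurement artifacts beyond additive
noise, and any radial-to-cerebral transit delay (generated pressure *is*
the cerebral pressure, which is why the model-recovery studies pass
τ = 0 instead of estimating a shift). Passing tests therefore demonstrate
internal consistency of the estimators against the circuit model under
realistic noise — not clinical accuracy against invasive ICP, which no
synthetic study can establish.

## The evaluation protocol

Trials are fixed at 45 s: rest [0, 15) s, maneuver [15, 30) s, recovery
[30, 45) s. The first 5 s of the maneuver and the first 10 s of recovery
are excluded as transition periods, leaving the VM analysis window
[20, 30) s and the late-rest window [40, 45) s. Phase means use the
initial rest window (uncontaminated by recovery) against the VM analysis
window; the late-rest mean is computed and reported but not used in the
test by default. Per-beat series are resampled by previous-value hold (a
beat belongs to the window containing its onset). The per-subject test is
a one-tailed paired t-test of VM > rest over the trials,
t = mean(d)/(sd(d)/√n), df = n−1, significance at p < 0.05; all-zero
differences return the symmetric-null point (t = 0, p = 0.5) while
nonzero zero-variance differences are reported as a degenerate case
rather than an infinite statistic.

## Problem sizes and numerical choices

The validation studies run at deliberately modest scale: 20 recordings of
60 s at 100 Hz for the simulation-RMSE study, 20 trials per subject for
the discrimination experiment, 200 simulated subjects for the
null-calibration study. 100 Hz (rather than kHz-rate acquisition) is
sufficient because every estimator here consumes either the sub-0.2 Hz
trend or per-beat features; the sampling rate is configurable throughout.
Steady-state solves use dense linear algebra on the 5-node conductance
matrix (current residuals < 1e-9 ml/s). Beats whose two-element fit is
degenerate (no valid instant pair, or non-positive identified resistance)
are skipped and logged; trials where an estimator fails entirely are
dropped from that estimator's summary with the reason recorded. File I/O
uses plain `time_s,value` CSV only — a deliberate choice to keep the
interchange format device-independent and diffable; the time grid must be
uniform to 1%.
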