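# Methods

## Virtual-patient physiology

The patient model is the classic two-glucose-compartment structure with
three remote insulin actions (transport/uptake `x1`, disposal `x2`, EGP
suppression `x3`), a single plasma-insulin pool and a first-order gut
compartment for enteral carbohydrate. The exact kinetics model inside the
clinical controller this package emulates is not public; the form used here
is declared fully in `iculoop.patient` and is the model family standard in
glucose-control simulation. Nominal parameters (per minute / per kg):

| parameter | value | meaning |
|---|---|---|
| V_G | 0.16 L/kg | glucose distribution volume |
| k12 | 0.066 | inter-compartment transfer |
| F01 | 0.0097 mmol/kg/min | non-insulin-dependent uptake |
| EGP0 | 0.0161 mmol/kg/min | endogenous production at zero insulin action |
| V_I | 0.12 L/kg | insulin distribution volume |
| k_e | 0.138 | insulin elimination |
| k_a1..3 | 0.006 / 0.06 / 0.03 | action activation rates |
| S_IT/S_ID/S_IE | 1.8e-3 / 2.9e-4 / 1.8e-2 | insulin sensitivities |
| gut τ | 40 min | enteral appearance delay |

The sensitivities are roughly one third of healthy-adult literature values:
critically ill subjects are insulin resistant, and with this scaling steady
insulin requirements at 7 mM come out near the 2–4 U/h infusion rates
reported for ICU cohorts. All values are implementation choices, not
transcriptions.

Two structural simplifications matter for interpretation. `F01` is constant
rather than glucose-dependent and there is no renal glucose spill, so the
open-loop dose–response is steeper than in richer simulators: a fixed
insulin rate only slightly below requirement lets glucose climb far, and one
slightly above pulls it low. This makes the control problem harder, not
easier, and is conservative for testing safety rules. Second, glucose state
components are clipped at zero after each integrator step (with a logged
warning) instead of using a stiff solver; at the default 1-minute RK4 step
the trajectory matches a 1-ms Euler oracle to < 0.01 mM over 6 h, so the
clip only ever engages in deliberately extreme scenarios.

### Cohort generation

`make_cohort` samples weight, BMI, APACHE II, a 46% diabetes rate, log-normal
jitter (CV 0.15–0.2) on rates/volumes/sensitivities, and a smooth sinusoidal
insulin-resistance modulation (amplitude ≤ 0.35, period 4–12 h, clamped to
[0.2, 3]). Each subject's entry glucose ~N(10.8, 1.5) mM (clipped to
8.2–13.8) and basal insulin rate ~U(1.5, 4.0) U/h are sampled first, and a
common multiplier on the three sensitivities is then solved by bisection so
the basal rate exactly maintains the entry glucose at the reference feed
(7.5 g CHO/h). The generator therefore guarantees a hyperglycemic,
insulin-resistant cohort whose steady requirements match reported ICU
infusion rates; this anchoring is what makes the comparator arm hover high
rather than over-control.

What the generator does **not** emulate: glucose-dependent uptake
saturation, renal thresholds, drug–glucose interactions beyond a generic
steroid episode (×1.5 resistance for 12 h in ~33% of subjects), parenteral
nutrition, or circadian hormone structure beyond one sinusoid. Passing
trials here show the control logic is sound under this model class, not that
clinical performance is guaranteed.

## Sensor model

Interstitial glucose follows plasma with a first-order 15-minute lag
(integrated exactly per step). The displayed value is
`gain · G_isf + N(0, σ)`, floored at 1.1 mM; the gain starts near 1
(SD 0.05), drifts linearly (SD 0.004/h) and is reset by one-point
calibration `gain ← ref / G_isf`, clamped to [0.7, 1.3]. Offset-free
one-point calibration is the simplest scheme consistent with a
single-reference recalibration and keeps the fixed point testable. Readings
are withheld for the first 60 minutes (warm-up) and during Poisson outages
(1/day, log-normal ~10 min), giving total unavailability of the order of
tens of minutes per 48 h. The noise SD default (0.70 mM) is the value
returned by `tune_noise_to_mard(7.0)`: bisection on a seeded 48-h simulation
against hourly references with 3-hourly calibrations, targeting the 7%
median relative absolute deviation reported for subcutaneous sensing against
arterial blood; the corresponding median absolute deviation is ≈0.5 mM. The
tuning trace is a deterministic two-sinusoid plasma profile whose slopes are
representative of controlled ICU traces; lag and drift contribute ≈3% MARD
before noise.

## Controller

The internal model is the population parameter set at the patient's weight
(six states; no gut compartment — the algorithm receives no nutrition
information). Each 5-minute cycle:

1. advance the internal model one step under the previous command plus the
   flux correction `F_c`;
2. innovation `e = G_obs − Ĝ`; nudge `Q1` by `α·e·V_G·w` (α = 0.7) so
   forecasts start near the measurement;
3. `F_c ← exp(−dt/30 min)·F_c + K_f·e` with `K_f = 0.30` mmol/min per mM;
4. `b_est ← clamp(b_est + K_b·e·dt, 0, 50)` with `K_b = 0.010` U/h per
   mM·min.

`b_est` enters the model as an insulin-input offset: predictions use
`u_eff = max(0, u − b_est + b_ref)`, where `b_ref` is the closed-form
population requirement at the setpoint. At equilibrium this forces
`b_est` to equal the patient's true steady requirement (the recovery tests
measure ≤ 7% error after 24 h of constant conditions; the acceptance bound
is ±20%). The `K_b` value follows from a small-signal analysis of the
two-timescale loop: with the standing `F_c` gain `K_f/(1−exp(−dt/τ_f))`,
`K_b = 0.010` gives `b_est` an effective time constant near 12 h.

Insulin is chosen by brute-force grid search (`{0, 0.05, …, 50}` U/h) over a
90-minute forecast with unit stage weights; `λ_u = 18·0.3² = 1.62` makes a
1-U/h move cost as much as a sustained 0.3-mM offset. The grid argmin is
verified against a 10×-finer brute force. Dextrose is reactive-predictive:
if the insulin-free 40-minute forecast dips below 4.5 mM, dose
`K_d·(4.5 − Ĝ_min)` mL/h of 20% dextrose, capped at 200. `K_d = 300` was
chosen during in-silico safety tuning (the clinical system was likewise
tuned in simulation before use): with a weaker rescue gain a rapid glucose
fall during a feeding interruption, seen through the 15-minute sensor lag,
could reach 3.8 mM before countermeasures bit; at 300 no reference sample
below 4.0 mM occurs across eight independently seeded 12+12 trials.

Interpretation choices: "insulin suspended below 1.2 mM of the target" is
read as strictly `G_obs < G_target − 1.2` (5.8 mM at the 7.0-mM setpoint);
horizons are fixed at 90/40 min from the printed 1–1.5 h and 30–40 min
ranges; fallback dosing holds the latest reference value between hourly
samples. Calibration requests map the latest sensor/reference deviation
linearly to an interval (≤2% → 6 h, ≥20% → 1 h) and drop to 30 min below
3.5 mM sensor glucose.

## Comparator protocol

The sliding scale is a nine-row lookup from blood glucose to infusion rate
(0 to 6 U/h) with physician-notification flags. Printed bands are contiguous
only at 0.1-mM resolution, so values are rounded half-up to one decimal
before lookup (a band "7.1–8.5" covers [7.05, 8.55)). The top row is read as
> 20.0 mM. A virtual nurse applies the hourly arterial value and holds the
rate; an optional deterministic escalation (+1 row after two consecutive
values > 12 mM, default off) stands in for physician-prescribed scale
alterations. Discretionary boluses are out of scope.

## Trial engine

Subjects are enrolled sequentially and assigned by Taves-style minimization
over four binary factors (APACHE II > 12, entry glucose > 10 mM,
BMI > 28, diabetes), cut near the emulated cohort medians, with fair-coin
ties; once an arm reaches its quota the remainder go to the other arm so a
12+12 layout is exact. Each subject runs a 1-minute physiology loop for up
to 48 h: per-minute sensor updates, 5-minute control cycles (closed loop) or
hourly nurse cycles (sliding scale), hourly reference samples (analyzer
noise SD 0.1 mM), and controller-scheduled calibration draws logged
separately so the hourly outcome series keeps an exact 60-minute cadence.
Everything is a pure function of (config, seed) via spawned NumPy
SeedSequences; records reproduce byte-identically.

## Outcome battery

Time-in-range metrics integrate the piecewise-linear interpolation of the
hourly reference series with analytically solved band crossings, so
below/within/above partition 100% exactly (a sample-counting mode exists for
sensitivity analysis — interpolation was chosen because the original
outcome software is unpublished). Hyper/hypoglycemic episodes are maximal
runs of consecutive out-of-range samples (≥15, ≥17, <4.0 mM). Sensor
accuracy pairs each reference with the nearest available sensor value within
5 min and reports MAD, MARD, and % within 20%. Group comparisons use a
tie-aware Mann–Whitney U (exact by enumeration of all assignments when both
groups ≤ 9, two-sided `p = 2·min(P(U≤u), P(U≥u))`; otherwise a normal
approximation with tie and continuity corrections) and a pooled-variance
unpaired t test for the per-subject glucose SD, which is reported as
mean (SD) while other endpoints are median (IQR).

## Problem sizes

Default analyses use 12 subjects per arm for 48 h at 1-minute physiology
steps (the scale of the emulated study); oracle suites use 6-h trajectories
for integrator comparisons, 100 random controller states for the optimizer
check, and exhaustive enumeration up to 7+7 for the exact test. A full
12+12 trial runs in about half a minute on one CPU.

## Known limitations

- The kinetics model and all nominal parameters are declared stand-ins; no
  claim is made about the clinical controller's internal equations or cost.
- Closed-loop time-in-target here (≈70–85%) exceeds what was observed
  clinically (≈54%): synthetic patients lack unmodelled disturbances
  (transport, procedures, drug boluses, sensor artefacts) and the virtual
  comparator nurse never deviates from protocol.
- Minimization factor weights of the original allocation software are
  unreported; unweighted Taves assignment is used.
- The exact p-value enumerates C(n1+n2, n1) assignments and is intended for
  trial-sized groups (≤ 9 per arm).
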