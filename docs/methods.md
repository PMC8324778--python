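# Methods

## Model

Thrombin generation in plasma is treated as a balance between one source
and three sinks. Writing T for free thrombin (nM), P for prothrombin and
[AT]_t, [α2M]_t for the free inhibitor levels at time t (minutes):

    dT/dt        = −dP/dt − d(T-inh)/dt
    d(T-AT)/dt   = k_AT  · [AT]_t  · T
    d(T-α2M)/dt  = k_α2M · [α2M]_t · T
    d(T-MS)/dt   = k_MS · T
    [AT]_t       = [AT]_0 − T-AT(t),   [α2M]_t = [α2M]_0 − T-α2M(t)

The model assumes well-mixed kinetics, irreversible complex formation,
and no direct AT effect on the upstream prothrombinase other than the
phenomenological PCmax transform described below. The first-order
channel k_MS aggregates losses not attributable to either inhibitor; it
is excluded from the conversion inversion by default (the inversion uses
only the two second-order channels) and the forward simulator follows
whatever setting the inversion used, so round trips close. The impulse
decay simulator always carries all three channels.

The pseudo-first-order summary of a plasma's inhibitory potential is the
thrombin decay capacity TDC = k_AT·[AT]_0 + k_α2M·[α2M]_0 + k_MS. Two
closed-form limits anchor the numerics: with inhibitor consumption
disabled an impulse decays as T(t) = T₀·e^(−TDC·t), and a constant
conversion rate R plateaus at T = R/TDC.

## Parameters

| parameter | unit | default | role |
|---|---|---|---|
| k_AT | nM⁻¹·min⁻¹ | 3.0·10⁻⁴ | thrombin–antithrombin rate constant |
| k_α2M | nM⁻¹·min⁻¹ | 1.0·10⁻⁵ | thrombin–α2M rate constant |
| k_MS | min⁻¹ | 0.01 | first-order miscellaneous loss |
| fibrinogen slopes | (g/L)⁻¹ | 0 | optional linear fibrinogen modifiers of k_AT/k_α2M |
| γ | — | 0.4 | AT→PCmax dose effect, s(a) = 1 + γ(1−a) |
| integrator step | min | 0.01 | fixed-step classical RK4 |
| smoothing windows | samples | auto | local-quadratic (Savitzky–Golay) |

The rate constants are configuration, not fitted quantities: they ship
as documented placeholders at physiological magnitudes (a normal plasma
with [AT]₀ ≈ 2400 nM and [α2M]₀ ≈ 3000 nM then has TDC ≈ 0.76 min⁻¹,
matching measured decay capacities of ~0.7), are stored in a versioned
YAML file, and are echoed into every result object. All correctness
properties of the package hold for whatever constants the configuration
supplies.

## Conversion extraction (inverse problem)

The conversion rate is assembled per sample as
−dP/dt = dT/dt + k_AT·[AT]_t·T + k_α2M·[α2M]_t·T, with the depletion
integral for [AT]_t advanced by a trapezoidal predictor–corrector along
the measured grid (this makes the accumulated T-AT exactly the
trapezoidal integral of its rate, so the mass balance
PCtot = T-AT + T-α2M (+ T-MS) + terminal free thrombin closes to
rounding on clean records).

Noise handling is adaptive. The record's noise SD is estimated robustly
from second differences (MAD/0.6745/√6). Below 0.2 nM the record is
treated as clean: no smoothing, a fourth-order central difference for
dT/dt, and an integral-consistent boundary closure so the derivative's
trapezoidal integral reproduces the endpoint difference exactly. At or
above 0.2 nM a 9-point quadratic Savitzky–Golay smoother is
applied to the thrombin series, its central difference taken, and one
further 9-point pass applied to the assembled rate. The split exists
because the two regimes have opposite error budgets: on clean records a
3-minute window biases the narrow control conversion pulse (≈3% on peak
quantities), while on noisy records an unsmoothed derivative is useless.

Negative rate excursions are clipped to zero after smoothing and the
clipped mass is reported. The rate is additionally zeroed outside the
contiguous positive region around its maximum ("main-pulse trimming",
switchable): without it, rectified baseline noise adds a systematic
+4–5% to PCtot over a 60-minute record; the trimmed mass is reported
alongside. Records whose final free thrombin exceeds 2% of peak are
flagged as incompletely decayed.

## Forward simulation and the in silico AT experiment

The forward model integrates dT/dt = rate(t) − sink(T) with fixed-step
RK4 (0.01 min; the system is non-stiff at physiological rates and a
fixed step makes outputs bit-reproducible; halving the step moves pools
by <0.05%). The conversion rate is interpolated by monotone cubics
(PCHIP) — linear interpolation loses ~0.1–0.3% of a narrow pulse's area
and visibly blunts its peak. Runs extend until free thrombin falls below
0.1 nM after the pulse or 90 min, so ETP is not truncation-biased, and
are resampled to a 0.1-minute output grid (computed curves carry no
assay sampling limit).

The AT titration extracts the conversion curve once at native AT, then
for each fraction a of the schedule (1.0, 0.9, …, 0.05, 0.025):

1. transforms the pulse by amplitude × s(a) and time ÷ s(a), which
   multiplies PCmax by s(a) and conserves PCtot exactly (a residual
   resampling error of ≤0.1% is renormalised away);
2. forward-simulates with [AT]₀ scaled by a;
3. extracts the TG parameters of the simulated curve.

s(a) defaults to 1 + 0.4·(1−a); any non-increasing function with
s(1) = 1, s ≥ 1 can be supplied (e.g. a tabulated dose–response).
γ = 0.4 reproduces the expected ≈1.7-fold peak-height gain at 50% AT in
haemophilia-like samples. Restoration is judged against a control
reference band of mean ± 2 SD per parameter (≥5 controls required).

**Known limitation — time-to-peak at deep AT reduction.** Lowering AT
both compresses the conversion pulse (peak earlier) and weakens the
sink (peak later, because thrombin keeps accumulating while any
conversion continues). Below roughly 50% AT the second effect wins for
wide patient-like pulses and simulated time-to-peak drifts *later* by
up to ~1 min per titration step, even as peak height and velocity index
keep rising monotonically. No physically plausible γ removes this while
keeping the peak-height dose response realistic, so time-to-peak should
not be treated as monotone over the full titration range in this model
family.

## Synthetic cohort generator

The generator emulates a case-control study at the 1 pM (default) or
5 pM tissue-factor trigger: 27 controls and 26 patients classified by
FVIII (severe < 0.01, moderate < 0.05, mild < 0.40 IU/mL; controls
≥ 0.85). Per subject it draws, from truncated normal group
distributions: FVIII (bounded inside the severity class, so labels and
classification always agree), fibrinogen, α2M (3000 ± 600 nM, an adult
reference range), a thrombin decay capacity, and PCtot. The AT level is
derived from the drawn TDC by inverting the TDC formula, so generated
cohorts reproduce the target inhibitory-capacity distributions by
construction (controls 0.712 ± 0.089, patients ≈ 0.52 min⁻¹).

The conversion pulse is a gamma-density pulse
rate(t) = PCtot·γ_pdf(t − t₀; k=4, θ) — smooth, unimodal, with
closed-form PCtot and PCmax = PCtot·C(k)/θ. PCmax couples to FVIII
through a saturating Hill curve (floor 24, amplitude 228.4, half-point
1.07 IU/mL at 1 pM; unbiased lognormal jitter, CV 0.25), calibrated so
control and pooled-patient PCmax means land near 169 and 27 nM/min.
Pulse onsets (controls 3.6 ± 0.8 min, patients 2.5 ± 1.2 min) are
calibrated so control lag times come out near 4.6 min. θ is clamped to
[1.5·dt, span/q₀.₉₉₉₅] so every pulse is resolvable on the grid and
decays within the record. The TG curve is the forward simulation of the
pulse at native AT plus i.i.d. Gaussian noise (default SD 2 nM) on a
20-second grid over 60 minutes. Ground truth (true pulse, PCtot, PCmax,
clean curve, noise metadata) is stored beside every sample and consumed
only by tests and scoring. Seeds are split per sample index, so cohort
size changes do not reshuffle earlier subjects.

What the generator does **not** emulate: raw fluorescence and
calibrator wells, α2M amidolytic carry-over in the measured signal,
substrate depletion, inner-filter effects, or real within-patient pulse
shape variability (the gamma family is a stated stand-in). Consequently
a passing recovery test shows the inversion is correct for curves that
obey the model, not that the model captures every feature of real CAT
data. One deliberate consequence: with PCtot and TDC pinned to their
group targets, the model *determines* ETP at ≈1000–1100 nM·min for
controls — higher measured ETPs in real cohorts include assay effects
outside this model, so ETP is not a calibration target here, and
patient-group peak height/ETP are emergent rather than calibrated.

## Statistics

Two-group comparisons use the two-sided Mann–Whitney U test: for
combined n ≤ 12 the permutation null is enumerated exhaustively
(tie-safe, two-sided p as twice the smaller tail, capped at 1); larger
samples use the normal approximation with continuity and tie
correction (null type-I error ≈ 0.04–0.05 at α = 0.05). Multi-group
comparisons are Kruskal–Wallis with tie correction against the
chi-square reference; all-tied inputs return p = 1 with a degeneracy
flag rather than an error. Correlations are Spearman's rank coefficient
with exact permutation p for n ≤ 10 and the t-approximation above. No
multiple-testing correction is applied by default (a Holm adjustment
can be layered by the user); two-sided tests throughout, as the
conservative default. Summary tables report mean ± SD per group, a
control-vs-pooled-patients p per parameter and an across-severities p,
excluding missing values per parameter with counts.

## Numerical choices and degenerate inputs

- Areas: trapezoidal rule; threshold crossings: linear interpolation.
- Lag time: first crossing of one-sixth of peak height by default; the
  threshold is configurable as an absolute level or a peak fraction
  (conventions differ between laboratories and the choice is reported).
- All-zero curves yield peak 0, ETP 0 and undefined (NaN) lag and
  time-to-peak; velocity index is NaN whenever time-to-peak ≤ lag.
- ETP integrates the raw (unclipped) signal so zero-mean noise cancels
  instead of rectifying; the result is floored at 0.
- Curves shorter than 10 samples or 15 minutes are rejected for
  analysis; thrombin below −5 nM (configurable) is rejected as
  non-physical rather than treated as noise.
- Time grids must be strictly increasing; smoothing assumes a uniform
  grid and falls back to resampling through a uniform working grid
  otherwise.

## Problem sizes

Default test and reproduction runs use the study-sized 53-subject
cohort on a 181-point grid, 20 forward/inverse round trips, full
14-level titrations of all 26 patients, and 2000 null replicates for
the type-I calibration; the whole suite completes in about two minutes
on one CPU.
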