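# Methods

This note documents the models, conventions and numerical choices behind
`gaitrel`, and what the synthetic data can and cannot establish about real
recordings.

## Sensor and frame conventions

Six sensors per horse: `LF_mc`/`RF_mc` on the metacarpi, `LH_mt`/`RH_mt` on
the metatarsi, `L_tibia`/`R_tibia` on the tibiae (hock motion).  Each sensor
reports a 3-axis gyroscope (deg/s) and accelerometer (g) at 102.4 Hz.  The
sensor frame is right-handed: x = lateromedial (sagittal-plane rotation about
x), y = craniocaudal (coronal rotation about y), z = proximodistal; gravity
is (0, 0, −1) g at zero tilt, so a sagittal tilt θ gives an accelerometer
reading (0, −sin θ, −cos θ).  Retraction is the **positive** sagittal
direction: the stride zero point — maximal retraction of the left-hind
metatarsus — is a maximum of the integrated sagittal angle.

## Limb-cycle waveform

Each segment's sagittal angle over one stride is a two-arc piecewise cosine:
a rising cosine half-arc from the protraction minimum to the retraction
maximum and a falling half-arc back, joined with zero slope at both extrema
(C1).  This family has closed-form extrema placement and an exact
peak-to-peak range, which is what the ground-truth oracles need; a pure
sinusoid is available via `SessionProtocol(waveform="sinusoid")`.  A
fundamental-plus-harmonic sum was considered and rejected because it cannot
place the two extrema independently of the range in closed form.  The gyro
channel is the analytic time derivative of the angle; the accelerometer
reports gravity rotated by the instantaneous tilt (no linear-acceleration or
hoof-impact transients — see Limitations).

A session is: 10 s standstill (gravity calibration), a walk block, an
acceleration ramp whose stride duration interpolates linearly from walk
(1.1 s) to trot over `ramp_strides` strides, `n_trot_strides` steady trot
strides, a deceleration ramp and a trailing walk block.  Walk uses four-beat
lateral-sequence phasing {LH 0, RF 25, RH 50, LF 75}%; trot uses the
programmed phases (defaults LF 63.097, RF 13.654, RH 49.460% relative to the
LH zero point, stride 0.731 s — treadmill population values of sound
warmblood horses at 3.3 m/s).  Sensor noise is additive i.i.d. Gaussian per
sample (defaults: gyro 2 deg/s, accel 0.02 g — representative MEMS noise at
this rate), plus an optional constant gyro bias to exercise drift handling.
Seeding is hierarchical (`SeedSequence` spawning, one child per sensor), so
identical inputs give bit-identical sessions.

All limb segments share one within-cycle timing template (retraction at
own-cycle 0%, protraction at 94.778%, the value whose recoded image is the
published 5.222%).  With identical shifted shapes, circular
cross-correlation recovers the programmed phases exactly; per-limb event maps
may deviate from the template, at the cost of a small phasing bias.  Two
consequences are deliberate and documented rather than hidden: the simulator
does not reproduce the ~18% metacarpal protraction / metatarsal retraction
timings seen in real recordings (those imply segment-specific waveform
shapes, which would break exact phase recovery), and the measured retraction
event is structurally ≈0% for every limb, so the two retraction variables
carry no between-horse signal in end-to-end studies.

Drawn horse profiles (`simulate_horse_profile`) perturb the population means
with independent Gaussians whose defaults are field-level between-horse
spreads (e.g. stride 0.022 s, phases 0.7–1.1%, hock ROM ≈ 3°).  The drawn
protraction arc is clipped to [5, 95]% of the cycle: a narrower swing arc
spans < 4 samples at 102.4 Hz and cannot be integrated accurately (the
trapezoidal ROM error then exceeds 2%; Simpson integration was tried and is
worse on this C1-kinked waveform).

## Extraction

* **Calibration** — tilt from the mean accelerometer vector over the
  standstill window (≥ 1 s required; |a| < 0.5 g rejected), gyro bias from
  the mean gyro.
* **Integration** — cumulative trapezoid of the bias-corrected rotation
  velocity.  Drift is removed per stride by subtracting the line through the
  angle values at the two stride boundaries, which cancels a constant-bias
  ramp exactly and leaves a periodic signal untouched.
* **Segmentation** — maxima of the linearly detrended LH sagittal angle,
  found with a prominence threshold (25% of the signal span) and a two-pass
  minimum separation of half the median period; boundary times are refined
  to sub-sample precision by parabolic interpolation.  Fewer than two events
  is an error.
* **Window selection** — the longest contiguous run of strides whose
  stride-duration coefficient of variation is ≤ `cv_threshold` (default
  0.05), with edge strides deviating > 4% from the window median trimmed
  (this is what excludes ramp strides); fewer than `min_strides` (default 5)
  steady strides is an error, reproducing the minimum-five-strides rule.
  Manual ranges are validated against the same rules.
* **Representative stride** — argmin over strides of the summed squared
  difference against all other strides in the window, pooled over the six
  sensors' resampled velocity cycles; ties go to the lowest index.
* **Limb phasing** — circular cross-correlation of 100-point resampled
  lateromedial velocity cycles against the LH reference, with parabolic
  sub-grid interpolation of the correlation peak.  The reference maps to
  exactly 0; a zero-variance cycle is an error.
* **Temporal events** — an angle extremum coincides with a velocity zero
  crossing, so events are located on the window-mean velocity cycle at the
  crossing adjacent to the largest velocity excursion and refined by
  extrapolating the shallow (near-linear) side of the crossing to zero.  The
  naive argmax of the angle cycle is biased by 1–3% of the stride here: the
  apex opposite the swing spike is extremely flat, and linear interpolation
  through the ~4-sample spike leaks it across grid points.  All events are
  re-referenced to the measured LH retraction crossing (the zero point),
  which cancels any residual common boundary bias; with this chain the
  noise-free round trip recovers phases and events to well under 1% of the
  stride, which grid-resolution reporting cannot achieve.  Protraction is
  stored recoded: values above 50% map to `100 − p` (98→2, 96→4, 94→6).
* **ROM** — per-stride max − min of the detrended angle, with the extremum
  value refined by a parabola fitted on the flatter side of the apex (a
  two-sided parabola overshoots at a kinked apex); hock ROM from the tibia
  sensors, cannon ROM from the metacarpal/metatarsal sensors; the variable is
  the mean over the window.  Hock symmetry = |L − R| / mean(L, R) × 100
  (absolute difference; the sign is not reported).
* **Gait check** — phasing is classified as trot (RF within 20% of the LH
  zero point, LF within 20% of RH, RH within 10% of half a stride), walk
  (four events evenly spaced, gaps 25 ± 10%) or unknown; extraction refuses
  windows that are not trot.

## Reliability statistics

The response model per variable and surface is the additive two-way crossed
random-effects ANOVA `Y_ijk = μ + α_i + β_j + ε_ijk` (evaluator α, horse β,
repetition pooled with interaction into ε).  Sums of squares are the
standard balanced decomposition; `df_error = n − 1 − (I−1) − (J−1)`.

Variance components come in two modes.  `paper` divides the mean-square
differences by J (=10) and I (=6) — the published divisors, retained verbatim
for fidelity; `balanced` uses the expected-mean-square divisors I·K (=18) and
J·K (=30), which make the estimator consistent (the divisor choice matters:
at a true ICC of 0.9 the paper-mode estimate is biased downward).  Negative
component estimates are truncated to zero before any ratio, standard
practice for ANOVA estimators.  ICCs and VPCs are the ratios given in the
README; `vpc_horse ≡ icc_inter` by construction and the VPC triplet sums to
one whenever the total variance is positive; zero total variance raises an
error (reported as NaN with a note in batch reports, which complete anyway).

The evaluator-experience model nests evaluator in type (the only
design-consistent reading of a between-evaluator factor crossed with horses):
`F = MS_Type / MS_Evaluator(Type)` on (T−1, I−T) degrees of freedom.  Under
Gaussian effects this is an exact F test; simulation confirms the 5% level
(type-I error within [0.03, 0.07] over 1000 null tables).  No
multiple-testing correction is applied across the 19 variables, matching the
original analysis.  Descriptives are mean, sample SD (n−1), median and IQR
with linear-interpolation quantiles (the original software's quantile rule
is unknown; this choice is configurable at the numpy level).

`simulate_variable_table` draws tables directly under the response model;
its default variances (0.9, 0.05, 0.05) place the design in the
high-reliability regime the instrument operates in.  Within-horse repetition
spreads are not separately published, so these defaults are package choices.

## Study orchestration

Per surface: one profile and one session per horse (per-surface population
stride durations 0.731/0.707/0.698 s for treadmill/soft/hard; the
hard-surface speed was not recorded in the field protocol, so the
soft-surface natural speed 3.51 m/s is reused), J·K = 30 blinded items
(zero-padded sequential ids after a seeded shuffle), I × 30 = 180
extractions, unblinding, reliability report.  Evaluator behaviour is
emulated by a per-(evaluator, item) seeded jitter of the analysis window
inside the steady region — a modelling stand-in for unrecorded human window
choices, not a claim about them.  `identical_evaluator_windows=True` forces
every evaluator to the same choice, a degenerate design in which the
evaluator variance component is exactly zero and ICC_inter = ICC_intra.  All
child seeds derive from the root seed via `SeedSequence` spawn keys; the same
configuration reproduces byte-identical report files.

Default problem sizes (25 steady trot strides per session, 10 horses, 3
surfaces; 200-seed parameter-recovery batches and 1000-table calibration
runs) keep a full study run around ten seconds and the entire test suite
under a minute while leaving the Monte-Carlo error well inside the assertion
tolerances.

## What the synthetic data does and does not show

Passing the end-to-end tests shows that the extraction chain recovers known
kinematics from signals with the study's sampling rate, session structure,
noise level and drift, and that the statistical estimators recover known
variance components from tables generated under the assumed model.  It does
not validate the chain against real horses: the simulator has no linear
accelerations, hoof-impact transients, soft-tissue artefacts, sensor
misalignment or gait irregularities; limb waveforms share one timing
template; evaluator variation is a seeded jitter rather than human judgement;
and the retraction variables are structurally uninformative (above).  The
published between-horse spreads are used as generator defaults, but the
generated tables are not a reproduction of the published per-variable
ICC/VPC values, which depend on the unreleased recordings.

## Known limitations

* Temporal percentages are reported at sub-grid precision, not quantized to
  the instrument's apparent 2% grid.
* The `paper` variance-component divisors are reproduced as published even
  though they are not the expected-mean-square divisors; whether they are
  intentional cannot be resolved from the text, so both behaviours sit
  behind the `mode` flag.
* The hock symmetry index inherits the relative errors of two ROM estimates
  through a difference ratio; for horses with near-identical left/right ROM
  its relative error is unbounded even when both ROMs are recovered to ~1%.
  Tests therefore bound its absolute error (2 percentage points).
* Windows whose stride-duration CV passes the threshold but which are walk
  are rejected rather than re-searched; a session whose longest steady run
  is walk fails extraction by design.
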