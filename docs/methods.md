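# Methods

## The analysis problem

Five within-subject emotion conditions (neutral, happy, relaxed, sad, fear)
are compared on a large catalog of balance, posture and gait parameters
measured while a participant stands on a force plate and then walks between
two stations 4.5 m apart. Because emotion effects on single motion
parameters are weak, the analysis has two arms: a per-parameter screen
(permutation repeated-measures ANOVA over 229 parameters) and a multivariate
arm (classifying the condition from the whole parameter vector). This
package implements both arms plus a synthetic study generator with ground
truth, so every stage can be validated quantitatively.

## Synthetic study generator (`synthcap`)

The generator is a study emulator, not a biomechanical simulator. Its
components and defaults:

* **Roster** — 24 subjects, 10 male, one trial per subject × condition; by
  default 3 relaxed and 1 fear trial are dropped (116 trials), mirroring the
  recording losses of the emulated experiment. Subject anthropometry: leg
  length ~N(0.89, 0.04) m clipped to [0.75, 1.05] (the trochanter marker
  height defines leg length exactly); baseline gait and sway parameters are
  drawn per subject (between-subject CV ≈ 15–20%), which induces the
  positive within-subject correlation across conditions that the
  repeated-measures design exploits.
* **Postural sway** — centre of pressure per axis is a stationary
  Ornstein–Uhlenbeck process about a locus: stationary SDs default to
  6.0 mm (AP) and 4.5 mm (ML), time constant τ = 0.25 s. τ controls both
  sway velocity and the Monte-Carlo error of a 30-s sample SD (≈ √(τ/T) ≈
  8%); recovery tests compare seed-averaged ratios for this reason.
* **Weight shifts** — Poisson events (default 2 per 30 s) that move the COP
  locus along a per-trial palette of three stance loci (centred,
  left-loaded, right-loaded; ML spacing 4.5–7.5 cm) with a 0.6 s
  constant-velocity ramp. The palette guarantees ground-truth locus
  separability at any shift rate; the first two shifts always visit distinct
  loci. Shifts also lean the trunk (≈3° frontal, ≈2.2° sagittal bump), so
  posture channels genuinely contain transitions.
* **Gestures** — Poisson wrist excursions (default 1 per 30 s; 0.4 s rise,
  1.2 s hold, 0.4 s fall, ~0.3 m vertical) with a small forward trunk lean.
* **Gait** — an alternating-step planner: step length 0.78·L, step time
  0.55·√(L/0.89) s, double-support fraction 0.10 of the stride, first step
  scaled 0.6. Each step's timing, length and height carry lognormal jitter
  (CV 2.5%, the stride-variability range reported for healthy adults), plus
  8 mm lateral placement noise; swing trajectories are monotone Hermite
  profiles whose lift-off/landing speeds are ≈2× the pelvis speed, so the
  projected-distance extremum used for event detection falls exactly at the
  scheduled contact and is not displaced by zero-phase smoothing. The pelvis
  follows a monotone (PCHIP) path through the mid-feet anchors; participants
  stop ~0.35 m past the station-B marker (the seat), so full gait cycles
  continue through the trim point. The turn at station A is a stationary 1 s
  yaw.
* **Forces** — vertical force = body weight (+0.4% noise); plate moments are
  constructed from the COP path (Mx = COPy·Fz, My = −COPx·Fz, surface
  origin), so COP recovery is exact up to noise. The plate unloads across
  the first two steps; ground truth records the 50%-body-weight crossing.
* **Emotion effects** — per-condition multiplicative deltas on
  {sway SDs, sway velocity (implemented as τ/m²), posture-angle SD,
  wrist–hip SD, step length, step duration, weight-shift rate, gesture
  rate}. `null()` is the identity (type-I studies); `moderate()` uses
  literature-scale effects (≈±10–30%); `strong()` (≈±40–70%, distinct
  signature per condition) is the validation preset for classification
  sanity. Trial-to-trial parameter jitter is lognormal with CV 3%.

What the generator does **not** emulate: joint kinematics/muscle dynamics,
soft-tissue artifact, marker occlusion patterns, camera noise correlation,
or any real-data idiosyncrasy of specific participants. Passing tests
therefore demonstrate that the pipeline recovers what it is designed to
measure under controlled conditions — not that the emotion effects of real
data are detectable.

## Feature extraction

Processing order per trial: cubic gap filling (gaps ≤ 100 frames; boundary
gaps are errors) → zero-phase 2nd-order Butterworth (10 Hz markers, 20 Hz
force; the forward–backward pass makes the gain at the cutoff 0.5) →
trimming 0.5 s before the sacrum first comes within 0.5 m of station B →
force/marker synchronization by polyphase resampling (1000→120 Hz) → phase
segmentation. The standing window is the first 30 s after movie onset
*intersected with* "ends 5 s before plate off-load" (both constraints,
conservatively). Off-load = vertical force below 50% body weight sustained
0.2 s; the turn = pelvis anterior velocity reversal sustained 0.3 s.

**Gait events.** Heel strike = local maximum of the hip(trochanter)-to-heel
displacement projected on the instantaneous direction of progression;
toe-off = local minimum of the projected hip-to-toe displacement (the
coordinate-based convention for overground data; a Euclidean-distance
minimum would fall mid-swing instead). Peaks are gated by 0.4 s minimum
separation, 2 cm prominence and a rolling-max pelvis-speed gate (0.25 m/s
over ±0.25 s) that suppresses spurious extrema while standing or turning.
The first toe-off of a bout that starts from rest has no prominence as a
minimum (it ends a long plateau), so the first step is anchored at the first
heel strike near plate off-load and its toe-off recovered as the onset of
toe movement — the kinematic analogue of identifying the first steps with
the force plate. Gait-initiation step k spans its toe-off to the next
toe-off of either foot; walking step duration is the contralateral-to-
ipsilateral heel-strike interval, stride ipsilateral-to-ipsilateral, stance
= heel strike → ipsilateral toe-off, double support = heel strike →
contralateral toe-off, and the "double-support distance by stance duration"
is the sacrum's projected progression over double support divided by stance
time. Step-level parameters are sampled at every landing with a preceding
contralateral contact; cycle-level parameters need a full same-side cycle —
on a 4.5 m walk one side often has a single full cycle, so its cycle-SD
entries are flagged missing rather than fabricated.

**Transition removal.** COP (and each posture channel) is clustered by mean
shift (bandwidth 2 cm for COP, 5 cm for wrist–hip distances, 2° for
angles); within each cluster a density pass flags sparse samples as
transitions. The density pass computes DBSCAN's exact noise set (non-core
points not within eps of a core point) with eps = bandwidth/4 and
min_samples = 0.25 s of samples, then dilates the flagged set by 0.25 s to
cover the slow shoulders of each ramp. eps = bandwidth/4 (rather than /2)
is required for 120 Hz data: at realistic weight-shift ramp speeds
(5–10 cm/s) a 1 cm eps would make mid-ramp samples core points and
transitions would never be flagged. Cluster statistics are count-weighted
averages of the per-cluster means and SDs — variability *about* each locus,
not inflated by locus separation. Every balance/posture parameter is
emitted in full / clustered / transition variants.

**The 229-parameter registry** is shipped as editable CSV data
(`emogait/data/feature_registry.csv`) and reconciled against a systematic
expansion: balance 37 (12 statistics × 3 variants + locus count), standing
posture 36 (5 channels × 3 variants × mean/SD + step width and base of
support), gait initiation 26 (2 steps × 5 parameters × raw/normalized +
first-step swing speed/width + total duration), walking gait 100 (2 sides ×
12 parameters × mean/SD × raw/normalized + overall walking speed), walking
posture 30. Normalization: lengths / L, times / √(L/g), speeds / √(gL)
(g = 9.81 m/s²), with leg length estimated as the mean trochanter height
during quiet standing. Missing data are flagged NaN, never zero.

## Permutation statistics

The screening test permutes condition labels independently within each
subject — exact under the within-subject null and enumerable on tiny
designs (the test suite checks exact agreement with full enumeration up to
2⁶ permutations). F is the one-way repeated-measures statistic; since
within-row permutations leave row means and the total SS invariant, the
permuted F reduces to the permuted between-condition SS, which vectorizes
(10,000 permutations of a 24 × 5 table in milliseconds). P-values use the
add-one correction; subjects with missing cells are dropped listwise per
feature. Post hoc pairwise tests are paired t statistics with sign-flip
permutation, BH-FDR adjusted across the 10 condition pairs of one feature
(no correction is applied across the 229 features). The two-way mixed
design tests gender by permuting gender labels across subjects and the
interaction by within-subject permutation of the interaction F. The
parametric F values are cross-checked against `pingouin` in the tests; the
permutation machinery is authored here.

`sensitivity_power` simulates the design's detectable effect size: normal
repeated-measures data with unit within-condition variance split into a
subject component (ρ = 0.5) and residual, condition means with SD = Cohen's
f. At f = 0.23, n = 24, k = 5, α = 0.05 the simulated power is ≈ 0.80,
matching the noncentral-F value (λ = n·k·f²/(1−ρ) ≈ 12.7, df 4/92).

## Classification

Stratified 80/20 trial split with largest-remainder per-condition counts
(deterministic per seed). Pipelines: train-fit median imputation
(all-missing features kept as constants) → z-scoring → classifier.
Hyperparameters are exposed in config with common defaults (k = 5;
unlimited tree depth, min-leaf 2; C = 1; RBF γ = scale; poly degree 3).
As in the emulated design, the five trials of a subject may span train and
test; a subject-grouped split is deliberately *not* the default so the
evaluation matches the study it models. Metrics follow the standard
definitions; macro averages are unweighted class means; ROC is one-vs-rest
from class scores (probabilities where available, decision values for the
SVMs); Gini importances are normalized impurity decreases of the fitted
tree.

## Numerical choices and degenerate inputs

* Permutation p-values are never 0 (add-one correction) and comparisons use
  a 1e-12 tie tolerance.
* `rm_anova_f` returns 0 (not NaN) when both condition and error SS vanish,
  and +inf when only the error SS vanishes.
* Cluster statistics require ≥ 10 samples per group; smaller groups yield
  flagged-missing statistics. Clusters retaining fewer than `min_samples`
  non-transition points are dissolved into the transition set.
* COP samples with Fz below 20 N are invalid (NaN) and excluded from
  clustering and statistics.
* SDs across gait cycles use ddof = 1 and need ≥ 2 samples; ties in step
  parameters are broken naturally by the generator's step-to-step
  variability (without it, frame-quantized durations produce heavily tied
  permutation distributions and conservative p-values).

## Known limitations

* The generator's turn is a stationary yaw; events during the turn are
  suppressed by the speed gate rather than modeled.
* Transition-variant parameters exist only when transitions occur, so their
  complete-case subject counts are small in quiet studies; the screen
  reports them as untestable rather than imputing.
* The classification arm at full study scale is validated against
  *injected* effects; no claim is made about the accuracy attainable on
  real recordings.
* C3D input requires the optional `ezc3d` dependency; the TSV dialect is
  the primary format.
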