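# Methods

This note documents the models and procedures implemented in `vrgaze`,
the defaults chosen where the design was genuinely open, and what the
synthetic-data tests do and do not establish about real recordings.

## Study design emulated by the generator

`vrgaze.simulate` emulates a two-group VR eye-tracking study: an ADHD
group (default n = 37) and a typically developing control group
(n = 36) each perform 13 task scenarios. A scenario has an instruction
phase (default 10 s; gaze parked near the instructing character at
azimuth 0°, elevation −5°, with small re-fixation saccades) and a 90 s
execution phase in which gaze alternates between fixations and saccades
while scanning a scene populated with task-relevant objects, irrelevant
objects, and non-object surfaces (floor band, teleport waypoints). Gaze
is recorded nominally at 90 Hz in the head frame together with the head
orientation quaternion, and data loss is injected in geometric bursts
at a group-dependent rate. Analysis follows the convention that only
execution-phase events count.

### Calibration to printed group statistics

The group parameters are the published summary statistics: fixation
duration 317 (36) / 309 (30) ms, saccade duration 57 (8.3) / 67 (10.1)
ms, saccade amplitude 5.44 (1.4) / 6.29 (1.7)° for the ADHD / control
groups, where the parenthesised values are interpreted as
between-participant SDs of participant means. Three mechanisms make the
cohort reproduce these numbers *exactly as realized sample statistics*
rather than only in expectation:

1. **Standardized between-participant effects.** Participant-level
   targets are `mean + sd_between · z`, where the z-vector is drawn
   standard-normal and then standardized to exact sample mean 0 and
   sample SD 1 (ddof = 1). Published group cells are summaries of the
   observed cohort, so the synthetic cohort is conditioned to match
   them; with plain i.i.d. draws the grand fixation mean of 37
   participants would wander with SE ≈ 36/√37 ≈ 5.9 ms, i.e. ~2% of the
   target, defeating percent-level calibration checks. Vectors implying
   a participant mean outside the admissible filter window are redrawn
   (deterministically under the cohort seed).
2. **Truncated-normal within-participant distributions with
   mean-corrected location.** Within a participant, fixation durations
   and saccade amplitudes are drawn from normal distributions truncated
   to the plausibility-filter windows ([100, 1000] ms; [0.75, 60]°),
   with the location solved by bracketing + Brent root finding so the
   *truncated* mean equals the participant's target
   (`calibrate_truncated_mean`, relative tolerance 10⁻³). Because draws
   already respect the windows, the downstream filters remove
   essentially nothing from ground truth and post-filter means equal
   the targets.
3. **Main-sequence saccade durations re-centered per participant.**
   Durations follow `dur = α_p + 2.2 ms/° · amplitude + ε`,
   ε ~ N(0, 8 ms), with α_p chosen so the expected duration equals the
   participant's target. Durations are clipped to [22.5, 299] ms and to
   the shortest duration keeping a raised-cosine saccade of that
   amplitude under the 36 000°/s² acceleration cap; these clips act
   several SDs from the mean, so their bias is negligible (< 0.01 ms).

Free parameters not fixed by published numbers, chosen once: within-
participant SDs (fixation 80 ms, amplitude 2°, saccade duration 8 ms),
main-sequence slope 2.2 ms/°, instruction duration 10 s, head motion
±20° sinusoidal yaw at 0.1 Hz during execution (static during
instruction), tracker noise 0.1° (the headset's stated accuracy is
0.5°; 0.1° reflects sample-to-sample jitter rather than static offset),
data-loss rates 6% (ADHD) vs 3% (control) with mean burst length 5
samples. The five task-performance measures are independent clipped
normals with group offsets of 0.35 SD in the published direction of
effect (ADHD: lower total score, task efficacy and navigation efficacy;
higher controller motion and total actions) — a deliberately modest
separation, keeping the performance-based classifier clearly weaker
than the eye-feature classifier, as observed in practice.

### Scanpath geometry

Fixation positions follow a great-circle random walk: each saccade
moves by its drawn amplitude along a uniformly random heading, re-aimed
toward the scene center whenever the step would leave the safe domain
(|az| ≤ 55°, |el| ≤ 26°). Saccade amplitude is therefore exactly the
great-circle angle between its endpoint fixations. Object labels are
assigned post hoc by AOI containment, so fixations land on objects at
the rate implied by AOI coverage; an optional
`relevant_fixation_offset_ms` lengthens fixations on relevant objects
(default 0 to protect calibration).

Rendering: fixations are a stationary world direction plus isotropic
tangent-plane Gaussian noise; saccades interpolate along the great
circle with raised-cosine progress (smooth, monotone, peak velocity
π/2 × mean velocity). The world direction is re-expressed in the head
frame with the inverse head quaternion, so head compensation downstream
is genuinely exercised; during fixations the simulated gaze is
world-stationary (vestibulo-ocular behaviour).

## Event detection

`vrgaze.events` implements the adaptive velocity-threshold detector:

* world mapping via quaternion rotation; azimuth/elevation from the
  world direction; invalid gaps ≤ 2 samples interpolated on the sphere,
  longer gaps split the trace into segments, and events adjacent to an
  interior split are discarded (their true extent is censored);
* velocity per component by the moving-window estimator
  `v_n = (x_{n+2} + x_{n+1} − x_{n−1} − x_{n−2}) / (6Δt)` (window 5;
  shorter stencils at segment edges), with azimuth rates scaled by
  cos(elevation) so both components are true angular rates;
* per-scenario thresholds `η_c = λ σ_c` with the median-based robust
  spread `σ_c = sqrt(median(v_c²) − median(v_c)²)` and λ = 6. Note this
  estimator equals 0.6745 σ for Gaussian noise — it is a robust scale,
  not a consistent SD estimator; λ = 6 is calibrated to it;
* saccades are runs of ≥ 2 samples with `(v_az/η_az)² + (v_el/η_el)² > 1`;
  runs closer than 40 ms are merged; complementary runs are fixations.
  Event duration is (run length) × Δt, so fixations and saccades tile
  the valid timeline. Saccade amplitude uses the samples just outside
  the run (they sit inside the flanking fixations, giving nearly
  unbiased endpoints); fixation position is the spherical centroid and
  its amplitude the maximal angular deviation from it; peak
  acceleration is the largest |Δspeed|/Δt around the run.

At 90 Hz the suprathreshold run systematically overshoots the true
saccade extent by a fraction of a sample per side (velocity-window
smearing, partially offset by sub-threshold saccade tails). Measured on
calibrated synthetic cohorts this leaves recovered saccade durations
~+13% and fixation durations ~−3% relative to ground truth — the
quantization penalty of a 90 Hz tracker, within the package's stated
recovery tolerances (5% fixation/amplitude, 15% saccade duration). A
boundary-trimming variant was evaluated and rejected: it overcorrects
(saccade durations −20%).

Filters: saccades outside 22–300 ms (lower bound = 2 sample intervals,
floored to whole ms), below 0.75° amplitude, or above 36 000°/s² peak
acceleration are removed, as are fixations outside 100–1000 ms.
Filtering is idempotent and order-independent (a conjunction of
per-event predicates); removals are counted per rule.

## Features

Per participant × scenario: mean fixation duration, saccade duration,
saccade amplitude over execution-phase filtered events (means over
empty sets are missing, never zero), event counts, invalid-sample
percentage, and NSS. Grand means are participant-weighted: mean over
participants of the mean over that participant's scenario means. The
classifier matrix is one column per feature × scenario
(3 × 13 = 39 by default).

NSS z-scores the saliency map over all cells (population SD) and
averages the bilinearly interpolated z-value at fixation centroids
(an all-samples mode would be a trivial extension of the same code
path); fixations outside the map domain are skipped. The map is static
per scene — dynamic (per-frame) saliency is out of scope, so synthetic
NSS hovers near zero by construction unless fixations are deliberately
aimed at hotspots.

Ambient/focal time course: events are binned by onset into 1-s bins
from execution start (partial final bin kept). Per bin: mean fixation
duration, fixation count, mean saccade amplitude, and the proportion of
saccades whose two flanking fixations share an object label — saccades
flanked by non-object (floor/wall/waypoint) or unassigned fixations are
excluded from the denominator, and the proportion is missing when the
denominator is empty.

Head metrics: total rotation angle is the sum of successive quaternion
geodesic angles (2·arccos|⟨q_i, q_{i+1}⟩|); mean rotation speed is the
average per-step angle/Δt.

## Group statistics

* `ranksum_z`: Mann–Whitney U with tie-corrected normal approximation,
  reported as |Z| with a two-sided p (no continuity correction, matching
  the closed form Z = |U − n₁n₂/2| / √(n₁n₂(n+1)/12) for tie-free
  data); an exact permutation mode enumerates all assignments for small
  groups. The normal approximation tracks the exact p to ~0.02 at
  n = 8/8 but degrades for n ≤ 4 per group — use `exact=True` there.
* `lmm_group_contrast`: linear mixed model fit by maximum likelihood
  (statsmodels MixedLM; ML, not REML, because fixed effects are
  compared), likelihood-ratio χ² between the model with and without the
  tested term, df = fixed-parameter difference. One random intercept
  uses the natural grouping; several (e.g. participant and scenario
  order, which are crossed) enter as variance components under a single
  all-encompassing group. Singular or non-converged fits are flagged
  but still reported. Under a simulated null the LRT holds its nominal
  5% level (checked at 200 replicates).
* `effect_phi`: φ = √(χ²/N) with N = participants in the model. This
  reproduces published pairings such as (χ² = 128.6, N = 63) → 1.43 and
  (3.93, 63) → 0.25; one published saccade-duration cell
  (χ² = 17.95 → φ printed 0.57, formula gives 0.53) is inconsistent
  with this definition — the formula is documented rather than tuned to
  the exception.
* `bh_fdr`: Benjamini–Hochberg step-up adjustment, applied within each
  reported family (one table = one family). The adjustment is monotone,
  capped at 1 and order-preserving; it is *not* idempotent as a map
  (re-adjusting adjusted values inflates them further), which is a
  property of the standard procedure, not of this implementation.

## Classification

Pipeline per outer fold: standardize → PCA → SVM, all fit on the
training fold only; hyperparameters (components {2, 5, 10, 20} clamped
to the inner-fold sample count, kernel ∈ {linear, RBF},
C ∈ {0.1, 1, 10, 100}, γ ∈ {scale, 0.01, 0.001}) grid-searched in a
stratified inner loop maximizing AUC. The outer loop is a seeded
stratified tenfold split; reported: per-fold and mean AUC,
fold-averaged ROC on a common FPR grid, confusion percentages at the
default zero decision threshold, and per-fold chosen hyperparameters.
`bootstrap_compare` resamples participants with replacement 30 times
(same resample for both feature sets), evaluates both classifiers per
resample, and applies an unpaired two-sided t-test across the two
30-value AUC samples (df = 2·30 − 2 = 58). Bootstrap resampling places
duplicated participants on both sides of CV splits; that optimism is a
known property of bootstrap-CV and affects both classifiers equally.

On synthetic cohorts calibrated to the published group statistics, the eye-feature classifier
reaches mean AUC ≈ 0.8 (the saccade-duration effect, ~1.1 SD, carries
most of the signal) while the performance-measure classifier stays near
chance-to-moderate — the ordering, not the absolute values, is the
meaningful synthetic result.

## What the synthetic tests do not show

The generator produces exchangeable scenarios (no scenario difficulty
effects, no scenario × group interaction, no temporal drift within a
scenario), independent performance measures, isotropic stationary
tracker noise, and a single static scene and saliency map for all
scenarios. Passing calibration/recovery tests therefore validates the
*pipeline mechanics* — geometry, detection, filtering, aggregation,
statistics, CV hygiene — not the ecological structure of real child VR
data (skewed/heteroscedastic features, scenario effects, VOR
imperfections, blinks with partial-validity edges, dynamic saliency).
Real-data mixed-model χ² values and AUCs are not reproduced and are not
claimed.

## Problem sizes used by the shipped checks

The acceptance script simulates the full 37 + 36 × 13-scenario design
(~0.5 M ground-truth events), renders and re-detects the control group
(~4.2 M samples), and completes in about a minute on one CPU. The test
suite uses smaller cohorts for unit-level properties, 200 replicates
for the LMM type-I-error and permutation-null checks, and 20 seeded
full-size cohort repetitions for the classifier-ordering property.
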