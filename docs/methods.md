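# Methods

This note documents the models and design choices behind `blockfc`: what the
simulator generates and why, how each analysis stage is defined, and what the
test suite does and does not establish about real data.

## Session design

A session consists of `n_runs` runs of a block design: 20-s task blocks
alternating with 20-s rest, sampled at TR = 1000 ms.  Conditions are the
crossing of four tapping sequences of increasing bimanual coordination demand
(*unimanual*, *synchronous*, *alternating*, *unbalanced* — the left finger
absent, simultaneous, phase-shifted by half a period, or at half pace) with
four right-finger speeds (1–4 Hz).  Defaults give 8 repetitions per condition
= 128 task blocks over 8 runs (16 blocks/run, one per condition).  Each run
opens with 5 discardable lead volumes plus one full rest period, so the first
block keeps a complete 12-s rest window after volume discard; a default run
is 665 volumes, 660 after discard.

Counterbalancing: the session order is `reps` cycles of a seeded base
permutation of the 16 conditions, each cycle rotated by `round(16/reps)`
positions.  This pins every condition's mean serial position within one block
of the grand mean, which is what matters for confound-free linear contrasts
over the session; it does not balance first-order carry-over effects.

## Tapping logs

Right-finger presses occur at the nominal pace with Gaussian timing jitter
(default SD 20 ms), clipped at 40% of the half-period so that jitter alone
can never reorder hands in the alternating sequence.  Paired left presses
(synchronous/unbalanced) share their partner's jitter plus an asynchrony term
clipped to ±80 ms, so an error-free log always satisfies the 100-ms
simultaneity criterion.  Errors are injected by the mechanism each scoring
rule detects:

* unimanual — a wrong-hand (left) press at a uniform random time;
* synchronous/unbalanced — one left press delayed by U(120 ms, min(300 ms,
  0.8 × local inter-press interval)); injected positions are kept
  non-adjacent so that each injection scores exactly one error under the
  matching procedure;
* alternating — an extra same-hand press inserted mid-gap in the combined
  press stream.

Default per-press error probabilities scale with sequence difficulty (0.02,
0.05, 0.08, 0.12), giving the linear error-rate increase over coordination
demand that the behavioral contrasts are meant to detect.  The injected count
per block is stored, and the test suite asserts scored == injected exactly.

Error scoring pairs presses globally greedily by ascending |Δt| (ties toward
the earlier right press), each press used at most once; matched pairs with
|Δt| > 100 ms plus unpaired presses count as errors.  For the unbalanced
sequence the expected-simultaneous right presses are every other one starting
from the first.  Global (rather than left-to-right sequential) greediness
makes the scored count robust to chain displacement when one press is
delayed past its neighbour.

Actual speed is 1/mean(inter-response interval) of the right-finger presses;
blocks with fewer than two right presses yield NaN, never 0.  The error-rate
denominator is the expected press count (pace × duration); both choices are
estimator conventions, and the mean-IRI estimator is deliberately the
simplest consistent one.

## ROI time-course model

Each ROI i in each run is

```
y_i(t) = baseline_i
       + Σ_c beta_i(c) · (boxcar_c ⊗ h)(t)
       + Σ_pairs λ_pair(c(t)) · g · s_block(t) · [i ∈ pair]
       + gains_i · n(t)
       + AR(1) noise (φ = 0.3)
```

with h the two-gamma HRF (peak 5 s, undershoot 15 s, ratio 6, length 32 s,
unit area so a long block's plateau equals beta), `s_block` a zero-mean
unit-variance Gaussian signal low-pass filtered below 0.15 Hz, restarted at
each block onset and active from onset until 2 s past block offset (a
hemodynamic-lag allowance that keeps the steady-state window fully covered
while leaving the next block's rest window untouched), and n(t) the eight
nuisance traces (bounded-random-walk motion ×6, polynomial-drift-plus-spikes
white matter, two-sinusoid ventricle at 0.05 Hz aliased-cardiac and 0.30 Hz
respiratory).  Baselines default to 100 so amplitude 1 ≈ 1% signal change.

Default effect schedules (the paper-style qualitative orderings):

* beta(left M1) rises with speed and falls mildly with coordination demand;
  beta(right M1) is zero during unimanual (right-hand-only) tapping;
* coupling λ on the left–right M1 pair rises with coordination demand
  (sequence-major) and mildly with speed.

The 16 λ values are not arbitrary: they are chosen so the *expected*
steady-state Fisher z of the 16 conditions is evenly spaced over
z = 0.25 … 2.05, by inverting r = (λg)²/((λg)² + σ²) with coupling gain
g = 3.0 and design σ = 0.45 (noise SD 0.3 plus evoked-plateau variation).
The spacing matters because a condition mean over 8 blocks of 12-sample
windows has an irreducible Fisher-z standard error of ≈ 1/√(9·8) ≈ 0.12;
with evenly spaced targets at 0.12 gaps, the rank ordering of the injected
coupling is recoverable with Spearman ρ > 0.9 in every seed (empirically
min ρ = 0.95 over 40 seeds), which the recovery suite asserts per seed.  The
cost is that top conditions reach within-block correlations (r ≈ 0.96) higher
than typically observed in vivo; the simulator is calibrated for ordering
recoverability, not for matching empirical group means.

## Preprocessing

Fixed order per run — (1) discard the first 5 volumes (T1 saturation), with
block onsets re-indexed accordingly; (2) high-pass by regressing out a GLM
Fourier basis (intercept, linear trend, sine/cosine pairs at 1…`n_cycles`
cycles per run; default 3 per ~11-min run ≈ 0.0045 Hz cutoff); (3) OLS
nuisance regression against the demeaned 8 traces plus intercept, residuals
exactly orthogonal to every retained regressor, collinear regressors dropped
with a warning.  Both filtering steps restore the series mean so percent
signal change stays well-defined.  Re-ordering the stages changes results
and is rejected unless explicitly overridden.  Slice-time and rigid-body
motion correction are assumed already done upstream; motion exists here only
as regressor traces.

## ROI definition

The localizer GLM regresses every voxel on boxcar ⊗ HRF task predictors plus
nuisance regressors and an intercept; the t statistic of the mean task effect
is thresholded one-sided at p < 0.001 (positive t = activation; "most
significant" is read as largest positive t).  Suprathreshold voxels are
grouped by 6-connectivity; the component whose center of gravity lies nearest
the seed coordinate (Euclidean, in mm when an affine is supplied, else voxel
units) is chosen, and its top-20 voxels by t (ties broken by flat voxel
index, for determinism) form the ROI; smaller components are returned whole
with an `undersized` flag.  ROI time courses are unweighted voxel means.

## Windows and block measures

Windows are half-open `[onset+start, onset+end)` on the volume grid, so the
printed durations are literal sample counts at TR = 1 s: 26 (full task,
[+2, +28)), 12 (steady state, [+10, +22)), 12 (rest, [−12, 0)).  Sub-TR
onsets are rejected rather than interpolated.  Per block and ROI pair the
sample Pearson r is computed in each window and Fisher-transformed with |r|
clipped at 1 − 1e−7; zero-variance segments give NaN with a logged reason,
as do blocks whose windows cross a run boundary.  Activation level is
100·(steady-state mean − rest mean)/rest mean against the block's own
preceding rest window; a non-positive rest mean gives NaN.

## Statistics

All inference is fixed-effects; group scope concatenates subjects' blocks
with per-subject intercepts and claims nothing beyond the sample.

* **Polynomial contrasts.**  The block measure is regressed on the full set
  of orthonormal polynomial codes of the dimension's levels; the tested
  term's F is the full-vs-reduced SSE ratio, computed explicitly so that the
  degenerate cases are well-defined: no between-level signal → F = 0, p = 1;
  zero residual with a nonzero effect → F = ∞, p = 0.
* **Midpoint-threshold classification.**  Threshold = midpoint of the
  unimanual and bimanual class means, estimated in-sample (a held-out
  variant is a matter of subsetting the table and is deliberately not the
  default, matching the descriptive use of the statistic).  The positive
  side of the threshold is fixed a priori (`direction="greater"`, since
  bimanual blocks raise both measure families); with the fixed side the
  chance level on null data is exactly 50%, which the suite verifies over
  1000 replicates.  An `"auto"` mode picks the side of the larger class
  mean; note it inflates null balanced accuracy to ≈53% at 32-vs-96 blocks.
  Significance is a Welch two-sample t-test — the classes are unpaired and of
  unequal size, so no paired test exists for this contrast; the choice is
  recorded in the result metadata.
* **Criterion validity.**  Pearson r between the block measure and the
  block's actual tapping speed, tested through simple linear regression, per
  bimanual sequence and subject.
* **Measure-comparison ANOVA.**  The two measures are z-scored within
  measure (they live on different scales), stacked long, and fit by
  full-factorial OLS with Type-II sums of squares; the F tests of interest
  are the measure × speed and measure × coordination interactions.
* No multiple-testing correction by default (uncorrected p values are
  reported); a Bonferroni option exists for scans over many connections.

## What the simulator does not emulate

No scanner physics, geometric distortion, or image-displacing head motion
(motion is only a regressor trace); no spatial normalisation (coordinates are
taken as already in the target space); no physiological non-stationarity
within runs beyond the modelled nuisance traces; shared signals are strictly
block-locked, whereas real coupling fluctuates at rest too.  Passing the
recovery suites therefore shows that the estimators are correct and
well-calibrated under the stated generative model, not that real sessions
carry effects of this size.

## Problem sizes and numerics

The default test suite simulates full 128-block sessions (8 runs × 665
volumes, 4 ROIs); the recovery suite runs 20 seeded sessions; the chance
level uses 1000 replicates of 128 null blocks; localizer fixtures are
20×20×10×420 grids.  These sizes run the whole suite in well under a minute
on one CPU.  All randomness flows through `numpy.random.SeedSequence` keyed
by the user seed, so every artifact is bit-reproducible; least-squares fits
use `numpy.linalg.lstsq`, and near-zero sums of squares are snapped to the
exact degenerate F values rather than left to floating-point 0/0.
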