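# Methods

This note documents the models and numerical choices behind `gaitpose`:
what the synthetic gait generator does and does not emulate, how each
processing stage works, which defaults matter, and what passing the test
suite does and does not establish about real recordings.

## The measurement problem

A single RGB camera views the sagittal plane of a walkway at 720×520 px
and 100 Hz; a pose estimator (BODY_25 layout) returns 25 2D keypoints
with confidences per frame. Spatiotemporal gait parameters must be read
off these keypoint trajectories despite three characteristic defects of
single-camera pose estimation: pixel jitter, missing keypoints (reported
as the sentinel (0, 0) with confidence 0), and occasional left/right
identity switches of the whole leg, because the two legs of a sagittally
viewed walker overlap twice per stride. Pixels convert to meters through
a single scale obtained from two marks a known distance apart (e.g. a
0.1 m tape on the walkway); the camera model is orthographic — with the
camera several meters from the walkway plane, perspective error across
the capture volume is small relative to the noise floor and is out of
scope.

## Synthetic trial generator

The generator (`gaitpose.simulate`) produces keypoint streams whose
ground truth — event times, noise-free trajectories, injected
degradations — is known exactly.

**Gait model.** Each foot alternates a strictly stationary foot-flat
stance with a swing that advances the heel by one stride length along a
smoothstep profile `3u² − 2u³` (C¹, zero forward velocity at both ends —
its closed form makes oracle values computable by hand). Swing heel
clearance follows `sin²(πu)` with a peak of 0.09 × stature, a realistic
mid-swing heel rise; this vertical separation is what makes left/right
identity recoverable while the heels cross in x. The mid-hip advances at
the profile's gait speed with a ±1 cm fluctuation at two cycles per
stride and rides over the midpoint of the two heels. Vertical positions
follow a fixed body template scaled to stature; upper-body keypoints are
static offsets from the mid-hip (arm swing is out of scope). Hemiparetic
asymmetry enters through per-side step lengths and stance/swing times;
both sides share one stride time, so
`cadence = 120/stride_time` and
`gait_speed × stride_time = step_lengths summed` hold exactly and are
enforced as profile invariants. The contralateral IC is placed midway
inside the admissible double-support window, so every ground-truth
sequence satisfies strict alternation and double support.

**Degradations** (defaults in parentheses) are applied after projection:
whole-leg left/right swaps in geometric runs (2 % of frames, mean run 3),
Gaussian pixel noise (2 px), per-keypoint missing runs (2 % of cells,
runs up to 8 frames, sentinel (0, 0)/confidence 0), and clipped-normal
confidences (0.85 ± 0.08). A fixed seed makes the output bit-identical.

**Cohorts.** `CohortSpec` draws per-participant baselines for five free
parameters — gait speed (0.55 ± 0.15 m/s), cadence (85 ± 10 steps/min),
paretic step fraction (0.52 ± 0.04), and per-side stance duties
(0.62/0.68 ± 0.025) — values typical of post-stroke inpatients walking at
self-selected speed. Per-condition values add optional fixed condition
effects, a within-subject draw (speed SD 0.05 m/s, cadence SD 3), and the
responder model: each participant gets one designated best condition
(no-AFO with probability 0.10, each spring 0.225) receiving +0.11 m/s and
+8.79 steps/min; the generator resamples the within-subject draws until
the designated condition truly has the highest gait speed, so "best"
recovery is testable. Draws are rejected outside physiological bounds
(including stride length ≤ 1.4 m, which also keeps a trial inside the
camera field; faster walkers are rendered with fewer strides).
`simulate_cohort_outcomes` returns the true outcome table directly — the
fast path used for statistical calibration — while `simulate_cohort`
renders every trial as keypoint frames.

One consequence worth knowing: the population mean best-minus-no-AFO
difference is *diluted* by participants whose best condition is no-AFO
(their difference is identically zero, ~10 % of the cohort). For gait
speed this dilution is almost exactly cancelled by argmax-selection bias
(≈ +0.01 m/s), so the recovered mean difference sits at the injected
0.11 m/s; for cadence there is no selection on the outcome and the
recovered mean difference is ≈ 0.9 × 8.79 ≈ 7.9 steps/min.

## Preprocessing

Order is fixed and recorded in provenance metadata: swap correction →
gap interpolation → low-pass filter → unit conversion. Swap correction
runs first because an uncorrected switch masquerades as a huge excursion
that would poison any interpolation or filtering.

**Left/right switch correction.** Frame labels are modeled as a two-state
sequence (identity/swapped) scored from the heel coordinates: each frame
contributes the constant-velocity prediction error of the two assigned
heel tracks (second difference, first difference when an anchor is
missing), each label change costs a boundary penalty, and each frame
spent in the swapped state costs a small per-frame penalty. The
minimum-cost path is found exactly by dynamic programming. Both penalties
are expressed as multiples (5.0 and 0.7) of the trial's own heel-track
noise floor (half the median identity-state emission), so the corrector
adapts to the estimator's pixel noise. The per-frame term deserves
emphasis: a *constant* wrong labeling of a long stretch has exactly the
same continuity cost as the correct one — the two tracks merely exchange
names — so only the prior that genuine switches are rare and brief makes
the labeling identifiable. This is also why greedy frame-by-frame
trackers are unreliable here: one wrong call while the heels cross (or
while a switch boundary hides behind missing data) lets them follow the
wrong legs self-consistently for hundreds of frames. A final guard
re-examines any surviving swap stretch of ≥ 20 frames (far beyond a
plausible estimator switch) against the identity labeling. At the
validation conditions (1 px noise, 5 % switch frames) the corrector fixes
> 99.9 % of injected frames with zero false relabelings over 53 seeds; at
2 px noise short switches that begin and end within a heel crossing are
sometimes left uncorrected (~80 % of frames corrected), which downstream
event detection tolerates.

**Gap interpolation.** Interior missing runs of ≤ 10 frames are filled
per coordinate with a least-squares cubic fit over up to 10 valid frames
on each side. A classic interpolating spline forced *through* every
noisy anchor rings badly (≥ 10 px excursions inside a 6-frame gap at 2 px
noise, which after filtering fabricates sustained phantom foot motion);
the local least-squares cubic keeps the third-order model, averages the
anchor noise away, and is exact to machine precision on noise-free or
polynomial data. Leading/trailing runs are never extrapolated; longer
gaps stay masked and are excluded from filtering and detection.

**Filtering.** Every coordinate is filtered with a 4th-order Butterworth
low-pass at 6 Hz, applied forward-backward. Zero-phase application is the
standard choice in gait analysis because phase lag would shift every
event time; the effective magnitude is the squared 4th-order response
(the −3 dB point moves below 6 Hz, design order stays 4). The discrete
response matches the bilinear-prewarped closed form
`|H| = (1 + (tan(πf/fs)/tan(πfc/fs))^8)^(-1/2)`, squared for
forward-backward. Sub-6 Hz content (the trunk) passes essentially
unchanged (mid-hip error < 1 mm on noise-free input); the foot
trajectories lose their sharp stance-swing corners (~1 cm locally) —
an unavoidable property of filtering a C¹ trajectory at 6 Hz, shared by
any pipeline that uses this filter.

## Event detection

Walking direction is the sign of the net mid-hip displacement (error if
below 0.2 m). Per side, IC candidates are local maxima of
`direction × (ankle_x − midhip_x)` and TO candidates local minima of
`direction × (bigtoe_x − midhip_x)` (knee fallback when the ankle is
masked), with candidates closer than 0.4 s merged (larger extremum wins)
and candidates within 0.3 s of the trial edges discarded as unreliable.

These extrema have flat tops: around IC the ankle and mid-hip briefly
move at similar speeds, so under noise the argmax jitters by up to
±0.1 s. The extremum therefore only *locates* the stride; the event
*time* is the persistent stillness transition of the contact landmark —
for IC the first instant the heel speed drops below threshold and stays
below for ≥ 0.08 s, for TO the last instant the big toe was at such a
rest — searched within ±0.25 s of the peak (walking back along a
stillness run if the peak lands inside one). Candidates must also show
real swing motion on the correct side of the event (mean speed ≥ 1.5 ×
threshold in the adjacent 0.12 s), which rejects noise wiggles whose
"foot" never moved. Speeds are Savitzky–Golay derivatives (0.11 s window,
quadratic): a plain central difference at 100 Hz has noise of the same
order as the threshold itself. The stillness threshold is 0.5 × the
median mid-hip speed — scale-free across walking speeds — calibrated on
noise-free simulated profiles to make IC and TO timing bias symmetric
and ≤ ~5 ms; isolated speed-noise spikes are suppressed by a 5-frame
median filter before thresholding.

Detected events are repaired to strict per-side alternation. Two
same-kind events in a row are either duplicates of one true event (close
together: stronger signal wins) or the footprint of a missed opposite
event; in the latter case the survivor is chosen so remaining pairings
stay phase-true (the later IC, the earlier TO), and the bridged phase
this leaves is excluded later by a duration filter (±50 % of the per-side
median). Implausibly short stance/swing pairs are dropped as spurious.
Ground-truth sequences must pass strict validation (alternation, events
in range, contralateral IC strictly inside every stance); detected
sequences validate leniently — isolated double-support violations mark a
local detection hole and are only fatal when more than 30 % of stances
show them, which indicates a structurally broken detection rather than a
hole. Events are reported at frame resolution (0.01 s at 100 Hz).

## Spatiotemporal parameters

Computed over the window from first to last pooled IC so speed and
cadence cover the same strides. Gait speed is |mid-hip displacement| /
duration. Cadence averages `120/Δt` over every three successive
alternating ICs, with windows whose span deviates > 30 % from the median
excluded (they bridge detection holes). Step length at each IC is the
anterior heel-to-heel distance (ankle fallback), negative values
retained; stance and swing times are per-side interval means. Paretic /
nonparetic labels come from trial metadata. Closure
(`speed × stride_time ≈ step lengths summed`) holds within 5 % on
simulated trials and is asserted as a property test.

## Study statistics

The best condition is the per-participant argmax of gait speed over the
five conditions (exact ties break toward no-AFO, then ascending
stiffness, and are logged); its row is duplicated as a sixth level.
Routing per outcome: Shapiro–Wilk on each condition at α = 0.05; all
compatible with normality → one-way repeated-measures ANOVA with subject
blocking (statsmodels `AnovaRM`), otherwise Friedman's tie-corrected χ²
(scipy). The routing can be overridden per outcome to reproduce a fixed
published assignment. Post hoc: Wilcoxon signed-rank on all 15 pairs —
zeros dropped (classic convention; exposed), exact null distribution for
≤ 12 untied nonzero differences, tie-corrected normal approximation
otherwise — with Holm step-down correction (statsmodels `multipletests`)
and effect size r = |z|/√n over the total pairs, banded at 0.3/0.5. Each
independent statistical primitive is cross-checked in the tests against a
hand-rolled oracle: brute-force sums of squares for the ANOVA F, the rank
closed form for Friedman, full 2ⁿ sign enumeration for the exact
Wilcoxon p, and the literal step-down definition for Holm.

Two calibration properties are verified by simulation: with zero
condition effects the omnibus rejects at 5 % ± 2 % over 500 cohorts
(measured on the five real conditions — the argmax-derived best level is
by construction not null and would inflate any test it enters), and the
+0.11 m/s designated-best effect at n = 32 is selected for every
participant, significant after Holm correction in ≥ 80 % of 200 cohorts,
and recovered at 0.11 ± 0.02 m/s. The report always carries the caveat
that the best level is statistically dependent on its source conditions.

## Problem sizes and reproducibility

Simulated validation uses 6-stride trials (~9.5 s at 100 Hz) and, for
study-level calibration, outcome-level cohort draws (n = 32 × 5) rather
than rendering every keypoint stream — the keypoint path is exercised
end-to-end by the trial-level experiments and a full rendered cohort
test. All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; identical seeds give bit-identical streams.

## Limitations

The generator is a validation instrument, not a gait model: feet are
rigid and foot-flat (no heel/forefoot rocker), arms do not swing, the
camera is orthographic, stride-to-stride variability is limited to the
periodic fluctuation plus measurement noise (within-participant
stride-length CV in real hemiparetic gait is larger and autocorrelated),
and degradations are statistically stationary, unlike real pose-estimator
failures that cluster at occlusions. Passing the suite therefore shows
the pipeline recovers parameters under the *modeled* failure modes at
realistic magnitudes; it does not certify accuracy on any particular
camera or patient population. Joint kinematics and kinetics are out of
scope, as is real-time operation.
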