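# Methods

## The test and its data model

The visual tracking test is encoded as data (`StimulusSchedule`): an
ordered list of stimulus events, each with an onset, a normalized screen
position on a 16:9 canvas (origin bottom-left), a movement direction
(left/right/up/down relative to the previous position), a stage (1–3), a
colour, and distractor flags. Defaults follow the clinical protocol the
package re-implements: stage durations 55/60/60 s and, per stage, 40 left,
40 right, 30 up and 30 down stimuli, giving 420 events over 175 s. Stage 1
carries no distractor flags, stage 2 only visual ones, stage 3 visual and
auditory (each drawn with probability 0.2 per event; distractors annotate
conditions only and never alter the reference signal). Ten colour periods
chain so that each period's background colour is the next period's stimulus
colour — the hidden rule behind the CGD question.

The protocol source states trajectory shapes ("square and z") but neither
event timing nor geometry. Design choice: events sit on two vertex levels
per axis (square template: x ∈ {0.2, 0.8}, y ∈ {0.25, 0.75}) and alternate
along each axis, which makes direction labels consistent with displacement
signs by construction and forces balanced left/right and up/down counts.
Onsets are uniformly spaced within each stage with ±10 % seeded jitter.
Whether the original stimuli jumped or glided is unstated; the jump model
is an implementation choice, and the geometry is configurable.

The reference calibration signal is the piecewise-constant trace an ideal
tracker would produce: each channel steps to the new stimulus coordinate at
the sample `floor(onset · rate)`.

## Synthetic cohort generator

`simulate_subject` produces 500 Hz two-channel recordings. Per channel
(horizontal gaze driven by left/right stimuli, vertical by up/down):

- each stimulus is tracked independently with probability `p_track`;
  a tracked saccade starts after a Gaussian latency (mean 200 ms, sd
  50 ms, clipped at 0) and moves the gaze to the stimulus coordinate with
  a raised-cosine rise of 40 ms;
- untracked stimuli leave the gaze unchanged — the low tracking rates the
  statistic is designed around (~28–32 %) imply most stimuli go unanswered;
- between saccades the gaze relaxes exponentially toward screen centre at
  1.2 s⁻¹. This re-fixation drift is what keeps consecutive same-axis
  targets distinguishable: without it, a tracked stimulus whose coordinate
  the eye already occupies would produce no recordable movement at all;
- spontaneous non-task saccades (2/min per channel, ±0.1 jumps clamped
  strictly inside the stimulus span) stress the matcher;
- the recorded signal adds a random-walk baseline drift (per-sample sd
  3·10⁻⁴), white noise (sd 0.01), and, on the vertical channel, blink
  artifacts: 200 ms positive raised-cosine pulses of amplitude 0.3 at
  10/min.

The truth log lists exactly the tracked stimuli (movement time, direction,
magnitude, landing coordinate). Tracking decisions are drawn from a
dedicated random stream in event order, so cohorts generated at different
`p_track` from one seed share common random numbers and tracked sets are
nested — the basis of the monotonicity test.

Group defaults mirror the published group statistics: tracking
probabilities 0.278 / 0.286 / 0.321 and colour-rule report probabilities
0.0462 / 0.45 / 0.3902 for drug-free ADHD / treated ADHD / controls, with
cohort sizes 53 / 39 / 36 (128 recordings). The simulator emulates the
*statistical* structure the analysis assumes — step-like saccades, drift,
noise, blinks, group-dependent hit rates — not the corneo-retinal dipole
physics, EMG/EEG crosstalk, head motion, or amplitude calibration of real
EOG. Passing tests therefore demonstrate internal consistency of the
pipeline under those assumptions, not clinical validity on real
recordings, whose raw amplitudes and noise levels the protocol source
never characterizes (all noise scales are exposed in the profile).

## Preprocessing

Order: downsample → normalize → SSA denoise → segment; every step is pure.

- **Downsampling** 500 → 20 Hz: zero-phase 8th-order Butterworth at 8 Hz
  (0.8 × the 20 Hz Nyquist) then decimation by 25. Zero-phase filtering
  preserves event timing for the matcher; non-integer rate ratios are
  rejected rather than resampled.
- **Normalization**: per-channel min-max to [0, 1]; a constant channel
  maps to zeros with a warning.
- **SSA**: trajectory-matrix embedding (window L = 20 samples = 1 s at
  20 Hz), SVD, reconstruction from the smallest leading component set
  holding ≥ 95 % of squared-singular-value energy, diagonal averaging.
  The series is mean-centred before embedding and the mean restored
  afterwards: on an uncentred [0, 1] signal the DC offset alone absorbs
  ~95 % of the energy and the criterion would keep a rank-1, step-free
  reconstruction. With all L components kept the reconstruction equals
  the input to ~1e−8 relative (completeness identity).
  SSA runs on whole channels by default. A per-section mode exists but
  concatenating the non-adjacent time intervals of one direction section
  creates seam discontinuities that the detector would read as saccades,
  so it is opt-in.
- **Segmentation**: each stage's timeline is tiled into the four direction
  sections (12 total); a section owns the half-open interval from each of
  its events' onsets to the next onset, horizontal directions read channel
  1 and vertical directions channel 2.

## Event detection and matching

The saccade detector thresholds the first difference of a cleaned channel
at max(6 × MAD, 0.05 normalized units); contiguous same-sign crossings
form one event (time = peak difference, magnitude = net level change),
same-sign events within 150 ms merge. Two artifact guards follow:

- **echo suppression**: zero-phase filtering and SSA truncation leave a
  small opposite-sign overshoot (~10 % of the step) right after large
  saccades; an opposite-sign event within 150 ms at ≤ 30 % of its
  predecessor's magnitude is dropped;
- **blink rejection**: a blink shows as opposite flanks of comparable size
  ≤ 250 ms apart with near-zero net displacement; such pairs are dropped.
  The window sits below the minimum inter-stimulus gap (~0.31 s under the
  default layout), so genuine opposite-saccade pairs are never eaten.

The detector thresholds and guards were calibrated against the simulator's
truth logs (hit rate ≈ 0.92, false events ≈ 0.10 per true saccade under
group-default profiles), closing the generate→detect→match loop: cohorts
simulated at tracking probabilities 0.278/0.321 recover group-mean weighted
scores within ~1 percentage point.

Matching is an exact maximum bipartite matching (SciPy's Hopcroft–Karp)
between same-direction stimuli and events, compatible when
|t_event − t_stimulus| ≤ 500 ms and, if a position tolerance is given,
when the landing-position estimate lies within it. A greedy
earliest-deadline scan would be optimal for pure time windows but not once
the position constraint breaks the interval structure, hence the exact
matcher; tests verify it against a brute-force augmenting-path oracle.
The pipeline default matches on time and direction only
(`pos_tol=None`): position estimates read off a min-max-normalized trace
are offset by drift and blinks, so a finite tolerance (default 0.15 when
enabled) is opt-in.

## Features and summary arithmetic

Per subject: the weighted RSOT score, the binary CGD response, and HFD
(kmax = 8, a common biosignal default; length-normalized curve lengths,
dimension = −slope of ln L(k) on ln k) plus the Hjorth triple, each per
stage and channel on the denoised normalized 20 Hz signal — 26 entries.
Per-stage channel means are also emitted for group summary layouts, since
the published summaries do not state whether channels were averaged.

Percentages are reported to two decimals (half-up); internal math is
unrounded. The bundled published summaries are internally inconsistent at
the last digit — some rows derive from already-rounded cells, others from
unrounded means — so each recomputed quantity follows the chain its source
row used: cell success rates from mean counts (checked at 0.025 points,
the rounding error of two-decimal counts over references of 30–40),
direction accuracies as means of rounded cells, the group average from the
unrounded chain, and weighted scores from the rounded direction
accuracies. All reproduce exactly at two decimals.

## Classification

Hyperparameters are unstated in the protocol source; defaults are
CART/Gini with unlimited depth, RBF SVM with C = 1 on standardized
features, and k = 5 Euclidean k-NN on standardized features (k = 1 is
ruled out because the published resubstitution k-NN accuracy is far below
100 %). "No validation" is read as resubstitution — train and score on
the full table — the only reading consistent with its inflated published
column. Folds are stratified and shuffle with the scheme seed; CV accuracy
is the plain fold mean. The three-group task treats post-treatment rows as
independent (no subject pairing is described in the source). The published
absolute accuracies (89.13 %, 80.47 %) depend on the undeposited clinical
recordings and are not reproduction targets; the package instead verifies
separability properties (permutation-null comparisons, resubstitution
optimism in aggregate) on synthetic cohorts.

## Problem sizes and numerical choices

Tests use the full 175 s schedule where the claim demands it (parameter
recovery at 30 subjects/group; bootstrap CIs from 2000 resamples) and a
structurally identical 35 s layout (8/8/6/6 per stage) where only the
mechanics matter. The matcher oracle runs 1000 random instances of up to
10×10. Degenerate inputs fail loudly: empty schedules, constant channels
(zero Hjorth variance), too-short series for SSA/HFD, zero reference
counts, single-class label sets, and unbalanced direction counts are all
rejected with explicit errors.

## Known limitations

- The stimulus geometry/timing model is a reconstruction; only stage
  durations, direction counts, colour-rule structure and the 16/9
  weighting are fixed by the protocol source.
- Landing-position matching is implemented but secondary; with min-max
  normalization a calibrated gain/offset model would be needed for
  positions to be trustworthy on realistic drift.
- The simulator's independence assumptions (per-stimulus Bernoulli
  tracking, channel-independent gaze) ignore sequential attention effects
  and oblique saccades.
- Group classification accuracy on synthetic cohorts reflects the
  simulator's effect sizes, not clinical effect sizes.
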