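# Methods

This note records the models, parameter choices and numerical conventions
behind `oculopipe`, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Signal model and preprocessing

A recording is a sequence of samples T, X, Y, A (timestamp in ms,
horizontal and vertical gaze in screen pixels, pupil area in camera pixel
counts) at a uniform rate, nominally 500 Hz, interleaved with event
messages.  Trials are cut between trial-start and trial-end stamps and
re-based so that stimulus onset is time zero; event stamps are rounded to
the sample step (ties round down — an arbitrary but deterministic
convention).  Timestamp glitches are repaired onto a strict uniform grid:
duplicates are dropped (first kept) and gaps up to 100 ms are filled by
linear interpolation of X, Y, A with the filled samples flagged invalid.
Longer gaps are real data loss and are never fabricated.

Pixels become degrees of visual angle through the exact per-axis
arctangent mapping with the origin at screen center, rightward/upward
positive.  The mapping is invertible to < 1e−9 px, which the generator uses
in reverse.

**Smoothing (position).**  All filtering uses a zero-phase moving average:
a boxcar of width *w* run forward then backward, with odd-reflection edge
padding of length 3(w−1).  This is the simplest filter that treats saccade
and fixation samples identically and adds no phase lag.  The default width
is **w = 3 samples (6 ms at 500 Hz)**, scaled as `round(3·rate/500)` at
other rates.  The width matters more than it looks: a forward-backward
boxcar attenuates the peak of a raised-cosine velocity profile by
σ²π²/D² (σ² the filter variance, D the saccade duration), which for w = 5
is ~6% at 2° amplitude — enough to visibly depress the small-amplitude main
sequence — while w = 3 stays below ~2.5% across 2–15° and still suppresses
pixel noise.

**Velocity.**  Central differences, `v_i = (x_{i+1} − x_{i−1}) / 2Δs`, with
two-point differences at the ends; speed is the Euclidean norm of the two
smoothed velocity components.  Smoothing precedes differentiation.

**Drift re-referencing.**  Video trackers drift between calibrations.  For
each drift segment the modal gaze position during the final 500 ms of the
fixation period (samples with speed < 50 °/s, pooled over the segment's
trials) is subtracted from X and Y.  The mode uses a 0.1° histogram over
±5° with exactly sign-symmetric bin edges; ties go to the bin nearest zero,
then the more negative; the reported offset is the mean of the samples in
the modal bin (so a noiseless fixation is recovered exactly).  Offsets are
applied per segment, not per trial — a per-trial variant would also absorb
genuine fixation biases, which we prefer to keep measurable.

## Blink detection

1. `A300 = A / mean(A | A > 10) × 300` fixes the non-zero mean of each
   trial's area at 300 arbitrary units (samples ≤ 10 are loss or near-loss
   and are excluded from the mean but still scaled).  A trial with no
   sample above 10 is fully lost and classifies as Eye Loss.
2. The slow area trend (arousal, luminance adaptation) is modelled by
   taking a copy of A300, replacing samples that are implausible
   (|sVEL| > 1000 units/step, or A300 outside [200, 400]) with linear
   interpolation between flanking plausible samples (edge regions extend
   the nearest plausible value), and smoothing the copy with a 50-point
   zero-phase boxcar.  `Aflat = A300 − model + 300`; re-centring on 300
   keeps the fixed loss thresholds meaningful.  sVEL is the 3-point
   zero-phase smooth of the per-step central difference of A300, and its
   threshold scales as 500/rate at other sampling rates.
3. Loss intervals are maximal runs with `Aflat < 250` or `Aflat > 350`
   (the upper tail catches mascara-type artifacts and is recorded as
   `tail = high`); runs closer than 20 ms merge.
4. The eyelid perturbs the area signal before and after the actual loss, so
   each interval is expanded to the full blink extent using saVEL (3-point
   smooth of |central difference|): the threshold is mean + 2.5 SD of saVEL
   over samples ≥ 50 ms from any loss, floored at 2 units/step, and the
   extent walks outward while saVEL exceeds it, capped at 100 ms per side.
   The saVEL kernel spreads a step edge over ~3 samples, so even an
   instantaneous dropout's extent can exceed its loss bounds by up to 6 ms.
5. Full-extent duration categorizes the loss: < 50 ms tracker dropout,
   50–500 ms blink, > 500 ms other interference.  The bounds are
   config-exposed; the stereotypical-blink range follows the blink
   literature.

## Saccade detection and event resolution

The detection threshold per trial is `max(20 °/s, μ + 2.5σ)` over
fixation-epoch samples with speed below a fixed 50 °/s ceiling (noisier
trials thus demand faster movements); fewer than 50 qualifying samples
falls back to the 20 °/s floor with a warning.  A saccade is a maximal
supra-threshold run of at least 10 ms (`ceil(0.010·rate)` samples); onset
is the first sample of the run and offset the first sub-threshold sample
after it.  Events are measured on the smoothed trace: start/end position,
amplitude (net Euclidean displacement), angle, duration, peak velocity,
and peak acceleration (maximum central difference of speed — "acceleration"
is otherwise conventionless).

**PSO merging.**  A following event closer than 40 ms with amplitude in
[0.5°, 5°] and smaller than its predecessor is a post-saccadic oscillation
lobe and is absorbed, iteratively left-to-right.  Merging moves the
endpoint to where the oscillation settles — trading duration accuracy for
endpoint accuracy, which the paired endpoint-error comparison quantifies.
The pre-merge offset (the first threshold crossing) is retained on the
record as the *core* offset.

**Boomerang splitting.**  Two opposed saccades can fuse into one
supra-threshold event.  An event is a boomerang iff (i) its initial and
final 10 ms displacement directions differ by > 135°, (ii) both lie within
45° of the two opposed task locations, and (iii) it is metrically abnormal:
path length > 1.5× net amplitude, or duration > 1.5× the nominal
main-sequence duration at its amplitude.  All three probes use the core
segment — judging them on a slosh-extended event makes ordinary PSO-merged
saccades look like boomerangs.  The nominal duration model
(2.4 ms/° + 47 ms by default) linearizes the kinematic family the
synthetic generator produces and must be recalibrated for a different
population.  The split point is the deepest speed nadir strictly between
the two largest velocity peaks, with a 10%-of-max prominence floor on peak
picking so sample noise on a lobe's crown cannot pose as a second peak;
events meeting the criteria but lacking an interior nadir are only
flagged.  Each half is re-measured as an independent record.

**Blincades.**  Events overlapping a refined blink extent are tagged; they
remain usable for behavior (trial classification) but are excluded from
kinematic fits.  The classic artifact — an upward loss-overlapping event
followed by a downward event, either within 40 ms or bracketing the same
blink (the gap between them is the loss itself, so a pure time cut can
never fire) — resolves by net start→final displacement: < 2° is a blink,
both events removed; ≥ 2° combines them into one blincade whose trajectory
is treated as linearly interpolated.

**Main-sequence Z-scores.**  Peak velocity vs amplitude and vs duration are
fit cross-sectionally per block with a least-squares cubic B-spline with
four interior knots at amplitude quantiles (effective df = 8 — a
near-smooth, low-flexibility fit; the realized knots are recorded in the
run metadata).  Records with missing kinematics, boomerang involvement or
blincades are excluded from the fit but still scored.  Z = residual / SD of
clean-fit residuals; blocks with fewer than 30 clean saccades get missing
scores.  The exclusion cut 3.29 is the two-sided standard normal critical
value at p = 0.001; a record must pass on **both** scores (the conservative
reading of an unstated combination rule; config-exposed).

## Pupillometry

Only trials whose FIX+GAP window is quiet qualify: no saccade above 2°,
mean gaze within 2° of fixation, and under 200 ms of data loss.  On the raw
area (pixel counts — all pupil metrics are homogeneous of degree one in
area): baseline = mean over 150–200 ms post-FIX; minimum and its time over
the 1200 ms FIX epoch excluding lost samples (a nadir is never read off
interpolated data); final size = mean over the last 50 ms before stimulus
onset; response onset = first sample of the earliest 20 ms window (after
200 ms) whose every sample deviates from baseline in one direction by more
than 1.96 baseline SDs — a deterministic operationalization of "significant
deviation" that needs no distributional machinery; constriction/dilation
velocities are extrema of the 3-point-smoothed area derivative on the
appropriate sub-intervals.  `constriction = baseline − min`,
`dilation = final − min` hold as exact identities.

## IPAST trial classification

Timing windows relative to stimulus onset: anticipatory [−110, 89] ms,
express [90, 139] ms, regular [140, 800] ms, late (800, 1000] ms.  Late
responses classify the trial but are excluded from latency summaries (both
published bounds are kept, with separated roles).  The first *viable*
saccade — amplitude ≥ 2°, launched within 2° of fixation, onset in
[−110, 1000] ms, blincades included — drives categories.  The decision
order runs from data quality outward, so rare diagnoses cannot be masked by
common ones:

1. **Eye Loss** if more than 50% of the FIX+response epochs are lost;
2. **Never Fixated** if gaze never dwells within 2° of fixation for a
   continuous 200 ms during FIX (samples inside blink extents do not count
   against fixation);
3. **Fixation Break** if gaze leaves the fixation window before FIX offset
   and does not return; a transient break that recovers sets a lapse flag
   and defers to the subsequent behavior;
4. anticipatory-window responses → the four anticipatory categories by
   condition and direction;
5. [90, 1000] ms responses → correct / direction error by condition and
   direction (toward vs away from the stimulus, by horizontal displacement
   sign);
6. **Random Saccade** if the first movement's direction is > 45° off both
   horizontal target axes;
7. **No Saccade** if fixation held and nothing viable occurred.

Unresolvable trials (missing event stamps, stage failures) land in the
reserved **Not marked** bucket; a failing trial never aborts the session.
Session statistics: ANTI error rate = regular-window ANTI direction errors
/ all ANTI trials; error ratio = the same numerator / (correct + error ANTI
trials); non-compliance = (No Saccade + Random Saccade + Never Fixated) /
all trials; fixation-break and anticipatory rates over all trials.  With
zero denominators rates are reported missing rather than zero.

## The synthetic generator

The generator emulates the IPAST timeline (1000 ms ITI, 1000 ms FIX, 200 ms
gap, stimulus at ±10°, 3200 ms trials, 500 Hz) and, in `freeview` mode,
unstructured saccade sequences with log-uniform amplitudes on [2°, 16°]
(natural viewing is dominated by small saccades).  Components:

- **Saccades**: raised-cosine velocity profiles with peak velocity
  `Vp = V∞(1 − e^(−A/A₀))` (defaults V∞ = 500 °/s, A₀ = 12°) and duration
  D = 2A/Vp from the amplitude integral.  Because the profile's takeoff
  slope is zero, ground truth annotates the *scoreable* onset — where the
  noiseless speed crosses the 20 °/s floor — alongside the profile start;
  onset-timing accuracy is measured against the former.
- **PSOs**: a damped sinusoid (20 Hz, 30 ms decay) along the saccade
  direction, starting at 80% of the saccade's duration, with displacement
  amplitude ∝ `slosh_gain` (0–1) to emulate the wide inter-individual range
  of iris mobility.
- **Boomerangs**: two opposed saccades overlapped at 60% of the first's
  duration with a 30% same-signed vertical fraction.  The curvature is what
  keeps the speed supra-threshold through the reversal (~50 °/s at the
  junction): a purely horizontal reversal passes through zero velocity and
  the detector would see two events on its own.
- **Blinks**: a 30 ms area ramp to zero, 50–150 ms loss, 30 ms recovery,
  optionally with the up/down gaze artifact (3° eyelid sweep).  Ground
  truth stores both the loss interval and the full ramp-to-ramp extent.
- **Pupil response**: raised-cosine constriction (default 80 units,
  commanded onset 300 ms post-FIX, nadir at 600 ms) followed by a
  quarter-sine dilation (40 units by stimulus onset) on a slow sinusoidal
  drift (5 units) with additive noise (SD 0.5 units).  The dilation's
  prompt takeoff mirrors recorded pupil traces, where re-dilation follows
  peak constriction without a plateau; it also keeps the nadir
  well-defined against noise.  Per-trial truth is measured off the
  noiseless curve with the same window definitions the metrics use.
- **Tracker drift**: a constant offset per 40-trial drift segment
  (SD 0.3°/axis), plus white gaze noise (default SD 0.05°).
- **Behavior mix**: per-trial category plans (correct, direction error with
  corrective saccade, anticipatory, fixation break, no-saccade, random,
  never-fixated, eye-loss) with probabilities roughly shaped like a healthy
  adult cohort; SRTs drawn from [150, 400] ms (regular) and [−90, 60] ms
  (anticipatory), deliberately clear of the classification boundaries.

What the generator does **not** emulate: pink/drift gaze noise and
microsaccades during fixation, oblique task saccades, luminance-driven
pupil dynamics, binocular disparity, vergence, head motion, and real
tracker loss patterns (partial occlusions with biased rather than zero
area).  Passing tests therefore demonstrate algorithmic correctness under
controlled, labelled conditions — not clinical-grade performance on messy
recordings.

## Validation metrics and problem sizes

The acceptance script and test suite use: a 100-trial IPAST session
(noise SD 0.05°) for detection recall/precision and onset timing; 125
free-viewing trials (~500 saccades, slosh 0.6) for the paired PSO
endpoint-error comparison and for false-split counting; a 200-trial
all-boomerang session for split recovery; 25 constructed trials per
blincade case; 1000 IPAST trials for classification agreement; 250 IPAST
trials (~200 eligible) for pupil parameter recovery; and 150 slosh-free
free-viewing trials for main-sequence recovery.  The main-sequence check is
parametric: the fitted spline evaluated at each detection's measured
amplitude against that saccade's generative peak velocity, binned over
2–15° — a same-abscissa curve comparison would conflate fit quality with
the detector's inherent ~4% amplitude bias at 2° (threshold crossings cut
the profile tails).  All sizes run in well under a minute on one CPU.

## Known limitations

- Saccade duration is deliberately overestimated when PSOs are merged; a
  model-based separation of eye and iris motion would recover both endpoint
  and duration and is out of scope here.
- The boomerang duration-abnormality probe depends on a population-level
  duration model; with the wrong model the direction probes still guard
  against false splits, but recall of subtle boomerangs drops.
- The ">350" upper-tail excursions of `Aflat` are treated as loss like the
  lower tail (direction recorded); labs whose mascara artifacts should not
  void data can raise the upper threshold in config.
- Microsaccades below the 20 °/s floor and smooth pursuit are out of scope.
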