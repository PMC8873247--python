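# Methods

## Signal model and working rate

All analysis runs at 62.5 samples/s, the transmission rate of typical
pulse-oximeter front ends. At this rate the constants of the pipeline
are integer sample counts: the 1.2 s detector window is 75 samples, the
16 ms window stride is 1 sample, and the 0.32 s decode region is 20
samples. Records at other rates are polyphase-resampled (anti-aliased
on the way down, `scipy.signal.resample_poly`).

PPG velocity (vPPG) and acceleration (aPPG) are *forward first
differences*, not centered ones. The choice is deliberate: it makes the
telescoping identity `sum(vPPG) = PPG[-1] − PPG[0]` exact, which in turn
makes the beat-level invariants (segment values summing to the net
normalized excursion) exactly testable. Within an analysis window, vPPG
slot *i* covers the sample interval [i, i+1]; the last slot of each
window has no difference inside the window and is zero-padded.

## Fiducial detection

Six identical networks (two hidden layers of 124 rectified units, 21
outputs; 269 units in total per network) each localize one target — O,
S, W, Z, noise-region start, noise-region end — in the central 0.32 s of
the sliding window. All six consume the same 210-value encoding:

* 75 PPG samples, min-max scaled to [0, 1] per window (a flat window
  maps to 0.5, with zero flags);
* 75 vPPG samples, scaled the same way;
* 60 binary peak flags: 4 channels (PPG max, PPG min, vPPG max, vPPG
  min) × 15 location bins over the central region, one-hot per channel.

The 21 outputs are decoded argmax-style as 20 one-sample (16 ms)
position bins plus one "absent" class. Scaling per window makes the
encoding exactly invariant to affine amplitude transforms of the raw
signal, so detector behavior cannot depend on sensor gain or offset.

Because the window slides one sample at a time, each sample of the
record is covered by up to 20 windows. Per-window decisions are merged
by voting: a position is accepted when at least 50% of its covering
windows vote within ±1 bin of it, ties broken toward the position with
the most raw votes and then the larger summed confidence. The W
sequence is then constrained to beat intervals of 0.4–2.0 s (heart rate
30–150 bpm); of two W candidates closer than 0.4 s the weaker-supported
one is dropped. Beats are assembled around each W (O within 0.5 s
before, S within 0.55 s after, Z between S and the next W) and marked
abnormal when O or S is missing or the beat overlaps a noise interval.
Noise start/end votes are paired in temporal order into half-open
intervals; an unmatched start (end) extends to the record's end
(beginning). The first 28 and last 27 samples of a record lie outside
every window's central region and are undetectable by construction;
evaluations of detector agreement are restricted to the coverable
region.

Training uses scikit-learn's `MLPClassifier` (adam, learning rate
7e-4, batch 192, early stopping on a 10% validation split with patience
80, at most 1000 epochs, fixed seeds). All six networks see identical
inputs; only the target labels differ. Hyperparameters live in
`TrainingConfig` / the YAML config, not in code; they were chosen on
held-out windows during development. With ~6000 labeled windows drawn
from 18 synthetic recordings of 9 subjects, held-out exact-bin accuracy
is ≈0.96 for W (the steep-upstroke point, the easiest and the one used
for beat splitting) and ≈0.87–0.93 for the other fiducials — the same
ordering and range the six-detector approach reports on real data.
Window diversity, not window count, is the binding constraint: at a
fixed budget, windows subsampled from more subjects train better
detectors than contiguous windows from few records. Exact-bin accuracy
is noise-limited — sensor noise moves the *observable* single-window
velocity argmax off the noise-free truth by ±1 sample in a third of
windows, and the network recovers most but not all of that gap by
integrating the whole upstroke shape.

A rule-based oracle detector (`oracle_detect`) serves clean signals and
evaluations: W = prominent peaks of smoothed vPPG at least 0.4 s apart,
S = PPG maximum after W, O = end of the pre-upstroke non-positive
velocity run (a raw argmin is unstable on the nearly flat diastolic
tail), Z = first prominent vPPG peak after S.

## Beat normalization

Beats are split W-to-W (half-open, so boundary samples are never double
counted). W rather than O anchors the split because it is the most
reliably detected fiducial. Each accepted beat is min-max normalized to
[0, 1], differentiated (×100 → percent of beat amplitude per sample),
and partitioned into 10 contiguous index blocks — block *i* holds
indices [⌊iL/10⌋, ⌊(i+1)L/10⌋), remainder samples accruing to later
blocks; no interpolation or time-warping. The block means are the 10
segment values; a measurement's summary is their per-segment mean and
sample SD (n−1) over accepted beats. The ×100 scale puts segment values
in the ±10 range conventional for this statistic. Fewer than 30 beats
leaves a summary below analysis grade — segment SDs are large relative
to between-group differences, so only averages over ≥30 beats are
stable.

Quality rule: a measurement whose abnormal beats *exceed* 10% of all
beats (strict inequality — exactly 10% passes) is flagged and the CLI
exits with status 2, requesting re-measurement.

## References and comparison

An individual reference is, per segment, the mean and sample SD of one
subject's (typically 5) session means; a group reference is the mean
and sample SD across subject-level reference means. Within-measurement
(beat-to-beat) SDs deliberately do not enter reference SDs: references
describe how *summaries* vary between sessions or subjects, which is
the level at which new summaries are compared. References with any zero
SD are flagged unusable rather than silently regularized.

Comparison: z per segment, mean|z| overall; classification between two
references picks the smaller mean|z| (ties, which have measure zero in
practice, break toward the first reference and are flagged). For ROC
analysis the score is negated mean|z| (individual mode) or the mean|z|
difference (group mode), so that larger = more positive; AUC is
trapezoidal and equals the Mann–Whitney pairwise-concordance
probability with ties counted ½ — a dual-route identity the tests check
exactly.

The per-segment group test uses the pooled standard error
√(SD₁²/n₁ + SD₂²/n₂) and a *one-tailed* Student-t critical value at
α = 0.05 with df = 7, the convention of the motivating study (its
printed critical value, 1.895, identifies both the tail and the df);
both α and df are configurable in `GroupDifferenceModel.fit`. With the
published group statistics (n₁ = 8, n₂ = 7), only segments 4 and 5 —
the phases carrying the reflection wave — are significant.

## Synthetic data

**Waveform level.** A beat is a gamma-shaped systolic pulse
p(t) = (t/tₚ)ᵏ·exp(k(1 − t/tₚ)) (sharpness k ≈ 4–8, peak at fraction
tₚ ≈ 0.18–0.26 of the beat), plus 0–3 Gaussian reflection waves, plus a
linear diastolic runoff (default 0.3 of the systolic amplitude at the
peak, decaying to zero at the next onset) that keeps diastole sloping
downward so the onset foot stays a sharp, localizable corner. Ground
truth fiducials are computed by brute force on the noise-free composite
signal: S = beat argmax, W = argmax of the first difference, O = the
pre-upstroke minimum, Z = the first prominent (>0.2% of amplitude)
first-difference peak after S, absent when no reflection produces one.
Recordings concatenate beats with per-beat heart-rate draws
(N(HR, HR_sd), clipped to 30–150 bpm), add baseline drift (2% of
amplitude at 0.08 Hz) and white sensor noise (default 0.5% of
amplitude — transmitted pulse-oximeter signals are front-end filtered
and clean), and optionally inject motion artifacts (4–10 Hz band-limited
bursts at 2–5× amplitude, 0.5–1.5 s) and dropouts (constant rail), all
recorded as ground-truth intervals.

Two archetypes encode the demographic contrast the method targets:
`group1` (young, healthy) draws a prominent early reflection wave
(0.4–0.7 of systolic amplitude, delay 0.42–0.50 of the beat) and
sometimes a second late one; `group2` (older, on antihypertensive
medication) draws a small late reflection (0–0.25, delay 0.52–0.62) and
a less sharp pulse. This separates the mid-cycle segments (4–5)
directionally, as in the published table. The waveform generator is not
calibrated to reproduce that table's numbers — its job is to exercise
detection and normalization with exact ground truth.

**Segment-table level.** For testing the comparison stage at study
scale, dataset summaries are drawn directly from the published group
statistics: subject means ~ N(group mean, between-subject SD), a
session-level deviation per dataset, and per-beat noise (beats per
dataset uniform in 31–48). Defaults, fixed a priori: beat-to-beat SD
1.6 segment units (15.1% — the midpoint of the observed 8.8–21.4%
relative-deviation band — of the ~10.6 peak segment magnitude);
session-level SD 1.0, chosen between the dataset-mean standard error
(~0.25) and the within-group between-subject spread (~1.4–2.0), the
regime in which a subject's waveform drifts day-to-day by about as much
as subjects within a group differ — matching the qualitative finding
that individual identification is error-prone while group
identification is near-perfect. Both subject- and session-level
deviations put half their variance (ρ = 0.5) on a single shared
across-segment factor: waveform changes are coherent shape changes, not
independent per-segment noise. Marginals are unaffected (the published
SDs are still recovered); the factor makes subject templates within a
group genuinely overlap. At the default seed the simulated study
(8 + 7 subjects, 5 reference sessions, 353 tests split 150/203 with the
study's per-subject counts) gives group AUC ≈ 0.99 and individual
AUC ≈ 0.89; across cohort draws group AUC varies roughly 0.92–0.99.

What the generator does *not* model: respiratory modulation, HR-phase
coupling of reflection timing in seconds (delays scale with the beat),
waveform aging beyond reflection amplitude/timing, correlated sensor
noise. Passing tests therefore demonstrate the pipeline's correctness
and its behavior under the stated statistical structure, not clinical
performance on real recordings.

## Numerical and interface choices

* Degenerate inputs are errors, not NaNs: constant beats (zero
  amplitude), single-class ROC inputs, zero pooled SE, references with
  zero SD.
* Sample SDs use n−1 throughout.
* CSV dialect: one sample per line with a `rate=` header; integer
  samples round-trip bit-identically. WFDB support is a minimal
  self-contained reader for single-channel format-16 record/header
  pairs.
* Detector banks serialize to a versioned JSON archive (weights,
  classes, config, held-out accuracies); reloading reproduces
  predictions exactly.
* Determinism: every stochastic operation takes a seed; trained
  detectors, generated cohorts and experiment results are bit-stable
  under fixed seeds (thread pools pinned to 1 during training in tests
  and the acceptance script).
* Problem sizes in tests and the acceptance script — 40 s recordings,
  ~6000 training windows, 9-subject training cohorts, 353-test
  identification cohorts — are the package's default study conditions;
  they keep full runs in the minutes range while preserving every
  qualitative property checked.

## Known limitations

* The detectors are trained and validated on synthetic waveforms only;
  applying them to real PPG requires retraining on labeled real data.
* O and Z localization is intrinsically coarser than W and S (flat
  onset corner, broad reflection hump): the oracle agrees with ground
  truth within ±1 sample for ≥99% of W and S points but only within ±2
  samples for O and Z.
* Motion-artifact onsets are detected approximately; band-limited
  bursts ramp up gradually, so corrupted measurements are caught
  primarily through the abnormal-beat fraction rather than exact
  boundary localization (dropout boundaries, by contrast, localize
  well).
* Group differences rest on 2 of 10 segments; the comparison makes no
  diagnostic claim, only a similarity statement between a measurement
  and a reference population.
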