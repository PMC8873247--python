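# ppgnorm

Heart-rate-phase normalization and statistical comparison of
photoplethysmogram (PPG) waveforms.

A fingertip PPG is easy to measure remotely but hard to analyze
automatically: the waveform changes with heart rate, differs between
people, and is regularly corrupted by motion artifacts and sensor
dropouts. `ppgnorm` implements a pipeline for telemedicine-style PPG
that turns every ≥30 s measurement into a fixed-length statistical
fingerprint and compares fingerprints across days, people and
demographic groups:

1. **Detect** the fiducial points of every heartbeat — onset O, systolic
   peak S, the maximum-upstroke point W (peak of the PPG velocity,
   vPPG = first difference), and the reflection-wave velocity peak Z —
   plus noise-region boundaries, using six small feed-forward networks
   (2×124 hidden units, 21 outputs each) that scan 1.2 s windows shifted
   16 ms at a time, cross-verified by majority voting over the ~20
   windows covering each sample. A deterministic rule-based detector is
   available for clean signals.
2. **Reject** measurements in which more than 10% of heartbeats are
   abnormal (noise overlap, missing fiducials, implausible beat
   interval), requesting re-measurement.
3. **Normalize** each W-to-W beat: min-max amplitude scaling,
   differentiation (×100, percent of beat amplitude per sample), and
   reduction to 10 segment values — the mean vPPG over each decile of
   the cardiac cycle. A measurement becomes per-segment mean ± SD over
   its ~31–48 accepted beats.
4. **Compare** a measurement *m* against a reference (M, SD) — built per
   subject across sessions, or per group across subjects — via
   per-segment z-values and their mean magnitude:

       z_i = (m_i − M_i) / SD_i,    mean|z| = (1/10) Σ |z_i|

   Small mean|z| means the measurement matches the reference. Group
   differences are tested per segment with
   t = (M₁ − M₂) / √(SD₁²/n₁ + SD₂²/n₂), and identification performance
   is quantified with ROC curves / AUC.

Because no public dataset of this kind exists, the package includes a
first-class synthetic generator (`ppgnorm.synthetic`) at two levels:
waveform recordings (gamma-shaped systolic pulse + reflection waves +
drift, noise, artifacts, dropouts, with exact ground truth) and
segment-table cohorts drawn from published two-group segment statistics
(8 healthy young adults vs 7 older subjects on antihypertensive
medication).

## Worked example

```python
import numpy as np
from ppgnorm import synthetic as syn, beatnorm as bn, compare as cmp, detector as det

# A clean 40 s synthetic recording from a young-healthy-archetype subject
profile = syn.draw_subject_profile("group1", np.random.default_rng(5))
rec, truth = syn.generate_recording(profile, 40.0, seed=50, subject_id="s01")

# Fiducials (rule-based detector) -> beats -> 10-segment summary
report = bn.analyze_record(rec, det.oracle_detect(rec))
print(report.summary.n_beats, report.summary.remeasure_flag)
print(np.round(report.summary.means, 2))
```

prints

```
56 False
[15.85 -5.9  -3.94  3.73 -5.68 -6.56 -2.64 -1.37 -0.77  3.17]
```

— 56 accepted beats, no re-measurement requested; the steep upstroke
dominates segment 1, the early reflection wave lifts segment 4, and the
decay phases are negative.

Comparison against individual references, on the simulated study-scale
cohort (15 subjects × 5 reference sessions, 353 test measurements):

```python
cohort = syn.simulate_identification_cohort(seed=0)
ref = cmp.build_individual_reference(cohort.reference["s01"])
own = next(t for t in cohort.tests if t.subject_id == "s01")
other = next(t for t in cohort.tests if t.subject_id == "s15")
print(cmp.z_values(own, ref).mean_abs_z)    # 0.522  (matches the reference)
print(cmp.z_values(other, ref).mean_abs_z)  # 1.565  (a different subject)

grp = cmp.identification_experiment(cohort.reference, cohort.tests, cohort.groups, "group")
ind = cmp.identification_experiment(cohort.reference, cohort.tests, cohort.groups, "individual")
print(grp.auc, ind.auc)                     # 0.989, 0.894
```

Assigning a measurement to its demographic group is near-perfect
(AUC 0.989) while identifying the individual, whose day-to-day waveform
drifts as much as subjects within a group differ, is distinctly harder
(AUC 0.894) — the ordering the method shows on clinical data.

The two-group comparison is exposed statsmodels-style:

```python
res = cmp.GroupDifferenceModel.from_statistics(
    syn.GROUP1_SEGMENT_MEANS, syn.GROUP1_SEGMENT_SDS, 8,
    syn.GROUP2_SEGMENT_MEANS, syn.GROUP2_SEGMENT_SDS, 7).fit()
print(res.summary())
```

```
Per-segment group comparison of normalized PPG velocity
  group 1: n = 8    group 2: n = 7    t_crit (one-tailed, alpha=0.05, df=7) = 1.895

 seg           M1±SD1           M2±SD2    SD12        t  sig
   1   10.589±1.955    10.333±2.394    1.139    0.225
   2    0.049±1.592     1.846±2.086    0.969   -1.855
   3   -4.449±1.802    -3.467±1.137    0.768   -1.278
   4   -2.028±1.692    -3.655±0.918    0.692    2.353  *
   5   -1.685±1.386    -3.792±0.595    0.539    3.908  *
  ...
```

Only segments 4 and 5 — where the reflection wave lands — separate the
groups significantly.

A `ppgnorm` command-line tool wraps the pipeline: `ppgnorm simulate`,
`train-detector`, `analyze` (exit status 2 when re-measurement is
requested), `compare`, `evaluate`, `report`; see `ppgnorm --help`.

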