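# pupilload

Pupillometry-based cognitive workload analysis: the Index of Pupillary
Activity (IPA) computed per eye from binocular pupil recordings, mean and
absolute between-eye difference indicator channels with within-participant
z-standardization, fixation precision and accuracy scoring, and a JZS
Bayes-factor pairwise comparison battery across task conditions — plus a
seeded synthetic-data generator that emulates the study signal structure
so the whole pipeline is testable without eye-tracker recordings.

It is written for researchers who analyse binocular pupil-diameter
exports (per-sample timestamp, left/right diameter in mm, gaze position,
validity flags, nominally 300 Hz) segmented into labelled task conditions:
a fixation task, six graded difficulty levels of a spatial-thinking test,
and a closing fixation task.

## The method

**IPA.** For a segment's pupil series d(t), take the level-2 detail
coefficients of a Symlet-16 discrete wavelet transform (periodized,
coefficients scaled by 1/2), keep the modulus maxima of the coefficient
magnitudes, threshold them with the scaled universal threshold

    lambda = Factor · sigma_hat · sqrt(2 ln n),     Factor = 0.8,

where sigma_hat is the standard deviation of the sparse maxima sequence
and n the number of coefficient positions, and count the survivors. The
IPA is that count divided by the segment duration (events/second) — a
light-robust rate of abrupt pupil dilations that indexes cognitive
effort.

**Channels.** Per segment: left, right, their mean, and |L − R|. The
difference channel tests the reduced-autonomic-variability hypothesis —
both pupils act more "in phase" under load, so smaller differences mean
higher effort. Channels are z-standardized within participant across all
segments to control inter-individual range differences.

**Inference.** Pairwise condition contrasts are paired designs on
per-participant condition means: JZS Bayes factors with a Cauchy(0, r = 1)
prior on the standardized effect delta (directed tests via the
half-Cauchy), posterior mean effect sizes with central 95% credible
intervals, and the conventional anecdotal/moderate/strong/very
strong/extreme evidence bands (boundaries 3, 10, 30, 100 and
reciprocals).

## Worked example

```python
import numpy as np
import pupilload as pl

rng = np.random.default_rng(3)
diffs = rng.normal(0.5, 1.0, size=30)      # paired A - B differences

t, n = pl.paired_t(diffs)
bf = pl.jzs_bf(t, n, r=1.0)
es, (lo, hi) = pl.posterior_effect_size(t, n, r=1.0)
print(f"n = {n}, paired t = {t:.3f}")
print(f"BF10 = {bf:.2f}  ES, Bayes = {es:.2f} [{lo:.2f}; {hi:.2f}]")
print(pl.classify_evidence(bf))
```

prints

```
n = 30, paired t = 2.649
BF10 = 3.01  ES, Bayes = 0.46 [0.09; 0.83]
moderate_H1
```

i.e. the data are three times likelier under a real difference than under
the null (moderate evidence), and the posterior mean standardized effect
is 0.46, shrunk toward zero from the sample effect t/sqrt(n) = 0.48 by
the wide Cauchy prior.

Stage by stage on a synthetic 10 s pupil segment with 1.5 dilation
transients per second (`python examples/01_compute_ipa.py`):

```
samples:               3000 at 300 Hz (10.00 s)
detail coefficients:   750 (level-2 band)
candidate maxima:      229
universal threshold:   0.03232 (Factor = 0.8)
events above lambda:   17
IPA:                   1.701 events/s
generated event rate:  1.700 events/s (ground truth)
```

The noise maxima fall below the threshold; the surviving events are the
generated transients, so the IPA recovers the designed rate.

The `examples/` directory holds one short script per capability
(IPA stages, cohort simulation, Bayes comparisons, the full pipeline);
each prints what it computes and what the numbers mean. The same flows
are available from a thin CLI:

```bash
pupilload demo --out demo_out --seed 7       # simulate -> analyze -> report
pupilload simulate --preset workload --n 30 --seed 7 --out data/
pupilload analyze --samples data/samples.csv --segments data/segments.csv --out run/
pupilload report --out run/
```

The report lists per-condition indicator profiles and the eight-pair
comparison battery (fixation-task fatigue contrast plus the directed
demand ladder) with evidence markers: `*` per grade for H1, `'` per
grade for H0.

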