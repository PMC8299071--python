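# Methods

## The indicator

The Index of Pupillary Activity (IPA) treats abrupt, transient pupil
dilations as the unit of cognitive work. For a pupil-diameter series
d(t) sampled at 300 Hz, one segment's index is computed as:

1. **Wavelet detail.** A two-level discrete wavelet transform (Symlet-16,
   periodized boundary) of d; the level-2 detail coefficients c_k isolate
   the transient band. Coefficients are divided by 2^(levels/2) (= 2),
   the per-level scaling of the open-source reference arithmetic.
   Coefficients below 1e-12 times the signal's amplitude scale are floored
   to exactly zero so that a constant series yields exactly zero events
   rather than float-residue counts; the floor is proportional to the
   signal scale, which preserves amplitude-scale equivariance.
2. **Modulus maxima.** Positions where |c_k| is a local maximum
   (strict against the left neighbour, non-strict against the right, so a
   two-sample plateau keeps its first index; boundaries one-sided) mark
   candidate transients.
3. **Universal threshold.** lambda = Factor × sigma_hat × sqrt(2 ln n),
   with n the number of coefficient positions and sigma_hat the standard
   deviation of the sparse modulus-maxima sequence (the reference
   implementation's estimator; the textbook MAD-of-detail/0.6745
   alternative is selectable, as is a base-2 logarithm). Factor = 0.8 is
   the calibration that brings the IPA closest to the commercial index it
   imitates; it multiplies the threshold and is exposed in configuration.
4. **Event rate.** The IPA is the number of maxima with |c_k| ≥ lambda,
   divided by the segment duration (t_last − t_first), in events/second.

Properties that follow and that the test suite enforces: scaling the
series by a > 0 or adding a constant leaves the event count unchanged;
the count is monotone non-increasing in Factor; a constant series gives
exactly zero.

The minimum segment length is 4 × the wavelet filter length
(128 samples, ~0.43 s at 300 Hz); below this, periodic-extension
artifacts dominate the detail band and the segment becomes missing.

A practical property worth knowing: the *noise floor* of the IPA (events
counted on pure measurement noise) depends on segment length, because
lambda grows like sqrt(ln n) while the maxima distribution does not. With
Factor = 0.8 the threshold under-kills white noise, so short segments
show a higher noise-event rate than long ones. When genuine transients
dominate sigma_hat the floor collapses to ~0 and the measured rate tracks
the true rate for any segment length; the synthetic-data generator is
parameterised in that regime (see below).

## Indicator channels and standardization

Per segment, the IPA is computed separately per eye. Four channels are
derived: left, right, their mean, and the absolute between-eye difference
|L − R|. The difference channel operationalises the reduced-autonomic-
variability idea: under higher load the two pupils act more "in phase",
so the difference is expected to *decrease* with demand.

Z-standardization happens within participant, per channel, across all of
a participant's segments (both fixation tasks plus all 60 items), with
the n−1 denominator. This removes inter-individual differences in the
indicator's range while preserving the condition ordering (z is affine
invariant). The default reading of a "standardized difference value" is
z(|L−R|); the alternative |z(L)−z(R)| is available via `diff_mode`.
A constant channel (zero spread) becomes missing, never zero: zeros would
mimic "no pupillary activity", which is a different claim.

Per-condition values are unweighted means over the segments of a label;
segments lost to blink damage are excluded, not zero-filled.

The difference channel carries a sampling caveat: |L − R| has positive
expectation from finite-segment noise alone, scaling roughly with
1/sqrt(segment duration). Contrasts between conditions of very different
segment lengths (a 54 s fixation task versus ~10 s items) are therefore
partly duration artifacts; contrasts between items of similar length
(e.g. neighbouring levels) are clean. This is a property of the measure,
not of the implementation, and it is why the null-preset generator
equalises item durations across levels.

## Auxiliary measures

**Accuracy** per difficulty level counts 1 for a correctly solved
*possible* item; impossible items never enter numerator or denominator.
An unanswered possible item (timeout) scores 0 — the conservative choice.

**Fixation precision** is the per-coordinate standard deviation (n−1) of
gaze residuals around the active cross position, pooled over the nine
cross presentations of one fixation task (only the 3 s cross phases;
the preceding announcement squares are excluded). The pipeline also runs
the undirected equality test of precision between the two fixation tasks,
the task-engagement check that licenses a fatigue interpretation of any
fixation-task contrast.

## Bayesian comparisons

Paired condition contrasts reduce to one-sample t designs on
per-participant differences. The default Bayes factor places a
Cauchy(0, r = 1) prior on the standardized effect delta under H1 and the
Jeffreys prior on the variance (the "JZS" construction). Implementation:

- The two-sided BF10 uses the inverse-gamma(1/2, 1/2) scale-mixture form
  of the Cauchy prior, leaving a one-dimensional integral with an
  elementary integrand; it is evaluated by adaptive quadrature in log
  space relative to the null likelihood, so the ratio never overflows.
  Absolute tolerance 1e-12, relative 1e-10.
- The posterior of delta is the noncentral-t likelihood times the prior
  on a grid with a node placed exactly at zero, refined by doubling until
  the posterior mean changes by < 1e-6 (grid capped at 16385 points).
  The likelihood itself is evaluated through the chi scale-mixture
  integral rather than library special functions, which lose accuracy
  and speed at the large noncentralities Bayes-factor integrands visit;
  agreement with the special-function route is ~1e-10 absolute in the
  regime where both are reliable.
- Directed ("greater"/"less") hypotheses use the half-Cauchy prior,
  computed as 2 × BF10 × posterior sign mass. Because sign masses come
  from the same zero-anchored grid, bf10(greater) + bf10(less)
  = 2 × bf10(two-sided) holds exactly, and bf10(greater; data)
  = bf10(less; −data) by symmetry.
- Effect sizes are posterior means with central 95% credible intervals
  (2.5%/97.5% quantiles of the gridded posterior); directed analyses
  truncate the posterior to the hypothesised half-line.

Evidence categories use the conventional bands: anecdotal (BF10 in
(1, 3] for H1, [1/3, 1) for H0), moderate (> 3 / < 1/3), strong
(> 10 / < 1/10), very strong (> 30 / < 1/30), extreme (> 100 / < 1/100).
BF10 = 1 exactly is assigned to the H0 side (logged); the report renders
one marker symbol per grade, '*' for H1 and a prime for H0.

The default comparison plan is the eight-row battery: fixation task 2 −
fixation task 1 (undirected; the fatigue contrast), then the directed
demand ladder a−fix1, a−fix2, b−a, c−b, d−c, e−d, f−e. Directions are
"greater" for the mean channel (more demand, more events) and flipped to
"less" for the difference channel (more demand, more binocular
synchrony). No multiple-testing adjustment is applied; BFs are reported
per pair. Pairs missing a participant's value drop that participant only;
pairs with n < 2 or zero-variance differences are flagged, not computed.

## The synthetic-data generator

No recordings ship with the package; the generator produces cohorts with
the statistical structure the analysis assumes, plus a ground-truth
manifest sufficient to recompute every designed quantity independently.

One signal is

    d(t) = baseline + drift·t + hippus + Σ shared events
           + Σ eye-specific events + noise

with blinks inserted as invalid runs in both eyes (diameter forced
non-positive, validity flags cleared). The coupling parameter rho splits
both the Poisson event stream and the noise variance into a shared and a
per-eye component; at rho = 1 with fully shared noise both eyes are
sample-for-sample identical and the difference channel is exactly zero.

Default signal parameters, chosen once as a realistic 300 Hz video-
pupillometry regime and then frozen:

| parameter | default | rationale |
|---|---|---|
| baseline | 3.5 mm (participant sd 0.4) | typical indoor pupil diameter |
| drift | −0.02 mm/min | slow fatigue-related constriction |
| hippus | 0.05 mm at 0.2 Hz | spontaneous low-frequency oscillation |
| event amplitude | 0.4 mm | clear dilation transients |
| event width | 33 ms (Gaussian, sigma = width/6) | ~10 samples; energy lands in the level-2 detail band |
| noise | 0.008 mm RMS | precise research-grade tracker |
| blinks | 0.15 Hz, 150 ms | task-attenuated blink rate |

The event amplitude / noise ratio matters: with sigma_hat dominated by
event maxima the universal threshold sits far above the noise-maxima
distribution for any segment length, so the detector counts designed
events and nothing else, and a no-effect design analyses as null. Smooth
Gaussian bumps (not steps) are used so detectability reflects genuine
transients rather than discontinuity artifacts.

Sessions follow the study layout: nine 3 s announcement squares each
followed by a 3 s fixation cross on a 3×3 screen grid (54 s per fixation
task; gaze scattered around the active position, sd 15 px), three blocks
of 20 items (two neighbouring difficulty levels per block, five possible
and five impossible items per level, shuffled within block), a 1 s
pre-item cross before every item, and a closing fixation task. The
practice trials before each block contribute no analysed segments and
are not emulated. Item durations are log-normal (sigma 0.4) with
level-dependent medians 4/5/6/7/8/10 s, truncated at the 60 s response
window — plausible response times for two-alternative cube comparisons,
deliberately unequal so duration normalisation is exercised. Item
correctness is Bernoulli with per-level probabilities; the preset uses
the published per-level accuracy means (.95/.93/.86/.80/.73/.43).

Participant heterogeneity: a baseline offset (sd 0.4 mm), a shared event-
rate offset (sd 0.3 Hz, general responsiveness) and a participant ×
condition rate jitter (sd 0.35 Hz), all Gaussian, rates floored at
0.05 Hz.

Two presets define the study conditions:

- **workload**: fixation tasks at 1.0 events/s, all six levels at 1.8
  (mean channel separates fixation from test, levels from each other
  not); coupling 0.3 at fixation, 0.7 at the one-transformation levels
  (a, b), 0.9 at the two-transformation levels (c–f), so the difference
  channel drops where a second mental transformation step appears. The
  two fixation tasks are identical by design (no event-rate fatigue
  effect). The designed fixation-versus-level-a paired effect works out
  to delta ≈ 1.3–1.5 on the mean channel — a deliberately large designed
  effect, sized by a power analysis so that the 18-of-20-replications
  recovery check has adequate probability under the JZS r = 1 test at
  n = 30 (a delta of 0.8 would pass any single replication easily but
  fail an 18/20 bar roughly two runs in three).
- **null**: equal rates (1.0), equal coupling (0.5), and — important —
  equal item-duration medians (8 s) across levels, because the
  difference channel's duration-dependent noise floor would otherwise
  turn level-dependent response times into a systematic pseudo-effect.

Seeding: a master seed spawns one child seed sequence per participant
(numpy `SeedSequence.spawn`), and within a session all draws occur in a
fixed documented order; two runs from the same master seed are
byte-identical, including written files.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: pupil foreshortening with gaze angle,
luminance responses, saccade-related artifacts, tracker-specific noise
spectra, asymmetric or partial blinks, and any mechanistic pupil
dynamics. The generator validates the *pipeline*, not the physiology.

## Pipeline behaviour

Segments are half-open windows [t_start, t_end) at the nominal rate (no
resampling; timestamp jitter beyond 10% of the sample interval rejects
the segment). Interior invalid runs up to 200 ms (a typical blink) are
linearly interpolated; longer runs are bridged but flag the segment
degraded, and segments over 50% invalid are rejected — degraded and
rejected segments propagate as missing values with logged reason codes.
An eye's sample is usable iff its validity flag is set and the diameter
lies in (0.5, 10) mm.

`run_analysis` is deterministic given inputs and configuration; the
resolved configuration and a structured run log are written next to the
outputs, and `make_report` renders artifacts without recomputation.

## Problem sizes

Defaults used by the examples, tests and the acceptance script: cohorts
of 30 participants (55 where the published accuracy table is the
calibration target) at the full 300 Hz rate; 20 seeded replications for
the effect-recovery rate and 10 for the null-specificity rate; a 10^6
draw Monte-Carlo oracle for Bayes-factor verification. One cohort
simulate-plus-analyse cycle takes a few seconds on one CPU.

## Known limitations

- The semantics of the threshold calibration factor follow the
  threshold-multiplier reading; the original calibration study defines
  it only operationally, and the natural-versus-base-2 logarithm in the
  universal threshold is likewise not decidable from the published
  description (both options are exposed; defaults: multiplier, natural).
- The difference channel's duration sensitivity (above) makes
  fixation-versus-item difference contrasts hard to interpret on any
  data with very unequal segment lengths.
- Directed Bayes factors for very small n (df = 1) sit in a heavy-tailed
  regime where the posterior grid is wide; results are correct but
  slower, and pairs with n < 2 are refused outright.
- Generator event-rate profiles are ordinal (fixation < levels), not
  calibrated to any published indicator magnitudes, which the source
  study does not report numerically.
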