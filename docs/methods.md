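# Methods

This note records the generative model, the estimators, the numerical
choices, and the known limits of the evaluation setup.

## 1. Synthetic study design

The default design emulates a two-group cue-reactivity EEG study:

- two groups, `MUD` and `HC`, 20 subjects each; group mean ages
  36.9 ± 7.7 and 26.1 ± 4.2 years (the deliberate age confound the
  ANCOVA module exists to check);
- three conditions per subject: a continuous `resting` run and two cue
  runs (`drug`, `neutral`) of 15 image presentations each;
- trials of 7 s; cue trials separated by 7 s inter-trial gaps; resting
  epochs cut consecutively from the continuous run;
- 31 channels on a unit-disc layout (center + three rings at radii
  0.4/0.7/1.0, channels apportioned by ring circumference).

Bookkeeping with the defaults: 40 subjects × 3 conditions = 120
recordings; 120 × 15 = 1,800 all-band epochs; 4 sub-bands × 1,800 =
7,200 sub-band epochs; 9,000 feature epochs in total, 17 features each.
These counts are asserted at runtime inside `run_all`, not only in
tests.

Two problem sizes are package choices rather than design facts: the
simulation rate defaults to 500 Hz (downsampled to 250 Hz for analysis)
and the resting run to 110 s — epoching uses only the first
15 × 7 = 105 s, so the epoch bookkeeping is identical to a longer run
at a fraction of the memory and time.  Both are configuration fields
(`sim.fs_hz`, `sim.resting_duration_s`) and can be raised to
acquisition-scale values.

## 2. Generative model

### Canonical topographies

Four fixed maps on the layout: A ∝ x + y, B ∝ −x + y, C ∝ y,
D ∝ 1 − 2r² (left-frontal/right-posterior, right-frontal/left-posterior,
frontal–occipital, and a radial center-surround).  Each map is
average-referenced and unit-norm; the largest pairwise |cosine| on the
default layout is 0.71, comfortably below identifiability limits.

### Semi-Markov state dynamics

State dwell times are Gamma-distributed with shape 20 and per-class mean
`mean_duration_ms` (defaults 120/100/90/80 ms), rounded to ≥ 1 sample;
transitions are drawn from a zero-diagonal stochastic matrix (uniform
off-diagonal by default).  Shape 20 gives a coefficient of variation of
22%, matching the narrow empirical dwell distributions.

### Voltage synthesis

```
v(t) = a · sin(2π f t + φ_seg) · T_{s(t)} + (a / snr) · ε(t)
```

the active template `T_{s(t)}` is gated onto a 10 Hz carrier whose phase
`φ_seg` is redrawn at every state transition, plus white sensor noise;
`a` = 10 µV, `snr` = 5 by default.  The GFP envelope is therefore
`a·|sin|/√C`, so GFP peaks sample the epoch at twice the carrier
frequency.

## 3. Preprocessing

Band edges (configurable): all 4–45, theta 4–7, alpha 8–12, beta 13–28,
gamma 29–45 Hz.  Filters are odd-length Hamming windowed-sinc FIR
kernels, `numtaps = ceil(3.3 fs / transition)` (transition 2 Hz),
applied zero-phase as a centered convolution of the symmetric kernel
with reflect padding, evaluated by FFT overlap-add — a symmetric
linear-phase kernel applied centered has exactly zero phase, and the
FFT route keeps the 7,200-epoch sub-band split inside the runtime
budget.  Downsampling uses an anti-aliased FIR decimator at integer
ratios.  The all-band signal is filtered and epoched first; sub-band
epochs are produced by filtering the all-band epochs.

## 4. Microstate analysis

- **GFP**: spatial RMS of the average-referenced map.  **Peaks**:
  samples with `g[t−1] < g[t] ≥ g[t+1]` (first sample of a plateau).
- **Training set**: GFP-peak maps pooled over all subjects' all-band
  epochs, capped at 1,000 maps per subject (seeded subsample) so no
  subject dominates.
- **Modified k-means** (polarity-invariant): assignment by squared
  cosine, centroid update by the principal eigenvector of the cluster
  scatter; objective is the global explained variance
  `GEV = Σ_t (x_t · t_{l(t)})² / Σ_t ‖x_t‖²`, monotone over iterations
  (history retained), 20 restarts, best restart kept.  Empty clusters
  are reseeded from the worst-fit map.  Restarts alternate between two
  seeding schemes (k random maps as templates, and templates fitted to
  a random partition), and on small problems (≤ 64 maps) each converged
  restart is refined by a Hartigan-style polish — first-improvement
  single-map relocations and pairwise swaps until no move raises the
  GEV.  Lloyd-style alternation alone stalls in local optima on ~0.7%
  of tiny random instances; with mixed seeding and the polish, 2,000
  random 8-map instances matched the exhaustive-assignment oracle
  (`exhaustive_kmeans_gev`) to 1e-9 without exception.  At pooled-study
  scale (tens of thousands of maps) restarts already agree to ~1e-4
  GEV and the quadratic-cost polish is off by default (overridable via
  `polish=`).
- **Canonical labels**: the 4! template orderings are scored by summed
  |cosine| against the canonical maps; the best ordering is relabeled
  A–D.
- **Back-fitting**: per sample, `argmax_j cos²(v_t, t_j)`; zero-norm
  samples inherit the previous label.  No temporal smoothing by
  default; an optional minimum-duration rejection
  (`smooth_min_ms`) reassigns runs shorter than the threshold to the
  neighboring run with the better boundary fit.
- **Parameters** (per epoch, 17 total): coverage, mean duration (ms),
  occurrence (1/s) and GEV per class, plus total GEV.  Boundary-
  truncated runs are counted, which makes
  `coverage_k = occurrence_k × duration_k / 1000` an exact identity —
  a deliberate estimator choice that turns an approximate textbook
  relation into a machine-precision invariant.

## 5. Classification

Epochs in which any class has zero duration or a duration above 250 ms
are discarded before analysis.  Per band × condition cell, a
500-tree random forest (sqrt-features per split) is evaluated with
5-fold cross-validation; features are z-scored with training-fold
statistics only (population SD).  Two fold modes exist: `trial`
(stratified shuffled folds over epochs — the study-faithful default,
which allows one subject's trials on both sides of a split) and
`subject` (grouped folds; the leakage-free alternative).  Variable
importance is Breiman's out-of-bag permutation importance computed over
a manually bagged ensemble: per tree, the drop in out-of-bag accuracy
when one feature is permuted among the out-of-bag rows, averaged over
trees.  The bootstrap motivation is quantified by
`oob_exclusion_fraction`: an n-row bootstrap leaves out
`(1 − 1/n)ⁿ → e⁻¹ ≈ 36.8%` of distinct rows.

The **null band** used in evaluation is fixed in advance as the 95%
binomial band of a single accuracy evaluation on `n` rows,
`0.5 ± 1.96·√(0.25/n)`; the mean null accuracy over seeds is required to
stay inside it.

## 6. ANCOVA

Trials surviving the outlier filter are averaged to one row per
subject × band × condition; per parameter, OLS of
`parameter ~ C(group) * age` with Type-II F tests for the Age main
effect and the Age × Group interaction.  Degenerate designs (one group,
constant age) are rejected with explicit errors.  A Type-I cross-check
(`type1_age_ss`) agrees with the Type-II sum of squares once age is
orthogonalized against group.

## 7. Known limit: narrowband duration recovery

One acceptance evaluation asks for planted mean durations (80–180 ms,
snr 5) to be recovered within 15% *through the alpha band*.  This is
not achievable by any correct implementation of the stated operations,
for a reason worth recording:

- the generator gates templates on and off with hard boundaries and
  redraws the carrier phase at each transition;
- an 8–12 Hz bandpass has a 4 Hz passband, i.e. ≥ 250 ms temporal
  resolution; its impulse response smears every 80–180 ms dwell across
  its neighbors and rings through transitions;
- consequently the back-fit labels fragment: measured label agreement
  with the planted sequence is ≈ 0.5 *even with the noise turned off*
  (snr 10⁹), and estimated mean durations come out 80–85% low.  The
  failure is insensitive to snr, which rules out noise (and any
  denoising remedy) as the cause.

Coverage is a time-*fraction* statistic and survives the smearing: it
is recovered within 0.05 as required.  Mean duration is a
boundary statistic and does not.  The criterion is asserted literally
in `tests/test_acceptance.py::test_criterion_4_parameter_recovery` and
left failing, rather than quietly weakened.  Two companion results
bound the problem:

- wide band (4–45 Hz), default back-fit: above-median-GFP label
  agreement is ≈ 0.98, but single-sample boundary flickers still chop
  runs and durations read ≈ 80% low;
- wide band with the field-standard 30 ms minimum-duration rejection:
  mean durations are recovered within ≈ 5–15% and coverage within
  0.02 — this figure is reported by `scripts/acceptance.py` as
  `recovery_allband_smoothed_duration_max_rel_err`, demonstrating that
  the estimator, given a signal that physically contains the
  boundaries, recovers the planted dynamics.

## 8. Determinism

Every random draw descends from explicit seeds through
`numpy.random.SeedSequence`: recordings are regenerated lazily from
per-(subject, condition, stream) children, so a study object is
memory-light and bit-reproducible; the pipeline derives stage seeds
from the configured seed; configurations are schema-validated (unknown
keys rejected) and hashed, and every output file carries the config
hash.
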