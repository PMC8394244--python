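# Methods

This note records the models, conventions and numerical choices behind
`eegad`, and what the synthetic-data experiments do and do not
demonstrate.

## Signal model and preprocessing

A record is a channels × samples matrix in microvolts with 10–20
montage labels and a sampling rate (the reference configuration is 19
channels at 128 Hz; 256 Hz input is reduced by averaging consecutive
sample pairs). Channel label dialects are normalised to the classical
set (T7/T8/P7/P8 → T3/T4/T5/T6); reference suffixes (`T3-A1`) are
stripped. Records long enough are trimmed to a fixed 61–240 s window to
avoid start-up artefacts; shorter records are analysed in full. No
artefact rejection is performed: the biomarkers are chosen to be
relatively artefact-insensitive and band filtering suppresses much
muscle and ocular contamination.

Band filtering uses zero-phase (forward–backward) Chebyshev type II
band-passes, order 8, 40 dB stopband attenuation. Two conventions
matter:

* the **delta low edge is clamped to 0.5 Hz** — DC drift carries no
  neural signal and would dominate a 0 Hz edge;
* **stopband edges are placed 5% outside the nominal band edges**
  (`TRANSITION_RATIO = 1.05`). A Chebyshev II design is 40 dB down *at*
  its stopband edge, so placing those edges exactly at the shared band
  boundaries notches out every boundary; with the 5% margin the summed
  filter bank reproduces ≈105% of the 0.5–45 Hz broadband variance
  (cross-talk between adjacent bands at the boundary is the price),
  while a mid-band sinusoid is passed within 1 dB and a tone one octave
  outside a band is attenuated by ≥80 dB after the forward–backward
  pass.

## Biomarker definitions

All single-channel biomarkers except band power are computed on the
band-filtered signal; band power is read directly off the FFT power
spectrum of the trimmed broadband signal. Ordered ratio features
(`theta/alpha` ≠ `alpha/theta`) divide the same method's two band
values; a denominator below 1e−12 yields a flagged missing value.

* **Band power (ΔPS)** — mean of |FFT(x)|²/N over the positive-frequency
  bins inside [lo, hi); the mean (not the sum) keeps bands of different
  width comparable in ratios. A sum variant is configurable.
* **Amplitude change rate (ΔEEG_A)** — the sample differences are cut
  into complete one-second blocks of `fs` differences; each block's
  summed differences divided by its summed intervals (exactly 1 s) is
  the signed amplitude drift per second, and blocks are averaged. The
  signed sum telescopes, so a whole-cycle oscillation contributes zero
  and a ramp of s µV/sample yields s·fs µV/s. Requires at least fs+1
  samples.
* **Zero-crossing interval (ZCI)** — mean time between successive
  strict positive-to-negative transitions (`x[t] > 0` and
  `x[t+1] < 0`; exact zeros never open or close a crossing). Fewer than
  two crossings gives a flagged missing value. ZCI is deliberately not
  offset-invariant: a DC shift genuinely changes the crossing structure.
* **Tsallis entropy** — amplitudes quantised into k = 2200 equal-width
  bins spanning [min, max]; TsEn = (Σ Pᵢ − Pᵢ^q)/(q − 1) with q = 0.5;
  empty bins contribute zero, a constant signal scores 0.
* **Higuchi fractal dimension** — canonical slope estimator: mean
  normalised curve lengths L(k) for k = 1..kmax (default 8, a common
  choice at 128 Hz) regressed as ln L(k) on ln k; the negative slope is
  the dimension (≈1 for smooth curves, ≈2 for white noise). A literal
  mean-curve-length variant is exposed for comparison
  (`higuchi_curve_length_mean`) but is not a dimension estimator and is
  not used by the pipeline. A constant signal returns 1 by convention.
* **Lempel–Ziv complexity** — binarise at the channel median
  (x ≥ M → 1), count exhaustive-history phrases c(N) by left-to-right
  scanning, normalise by the random-string bound N/log₂N. Note the
  median rule degenerates when the median coincides with one of two
  signal levels (everything maps to 1); continuous EEG is unaffected.
* **Approximate entropy** — ApEn(m, r) with m = 2 and r = 0.15·SD by
  default (standard physiological-signal practice; both configurable),
  self-matches included, Chebyshev distance. Neighbour counting uses a
  numba kernel that scans a window sorted on the first embedding
  coordinate (a cKDTree fallback is used without numba); both are exact
  and are cross-checked against a naive O(N²) double loop in the tests
  to 1e−9.
* **Coherence** — Welch estimate with 2 s Hann segments and 50% overlap
  (0.5 Hz resolution, ≥ 8 averages on 60 s records, which bounds the
  independent-signal bias near 1/n_segments); the band value is the MSC
  averaged over band frequencies, skipping the DC bin. Coherence ratios
  divide band-averaged values rather than averaging a ratio spectrum.

## Selection stage

Each feature column receives a two-sided two-sample p-value (Welch's
t-test by default; Mann–Whitney U selectable — the choice is recorded in
the run configuration). The operative screen is raw p ≤ 0.001.
Bonferroni-corrected p-values and the 0.05/N critical value are
computed per test family — the set of locations tested for one
(method, band feature): 19 channels, or 171 pairs for coherence — and
reported, but do not gate selection.

Band features are ranked by the number of significant locations summed
over all eight methods; channels over the seven single-channel methods
(coherence is tallied separately by channel pair). Each item's
probability-distribution ratio is its share of all significant tests
(100·xᵢ/Σx); the cumulative column accumulates ratios rounded to three
decimals — the tallying convention of the published screening tables
this stage mirrors — and the selection keeps the shortest descending
prefix whose cumulative share reaches 80%, including the item that
crosses the threshold. Ties are broken by count, then identifier.
Pairs with at least one significant coherence feature are all kept.

## Panels and models

Stage-1 panels are homogeneous: one selected band feature of one
method over one combination (sizes 1–10) of the selected channels (or
pairs). With 11 features, 12 channels and 10 pairs this is
11·4082 = 44,902 panels per single-channel method and 325,567 panels in
total. Enumeration is lazy and deterministic, smallest panels first, so
screening under a cap prefers the fewest channels. Stage-2 panels mix
individual biomarkers across methods, sizes 1–4 (919,310 panels from 69
biomarkers).

Panel screening uses a linear SVM with unit regularisation — a
conservative choice for tens of subjects — standardised inside each
training fold, under stratified k-fold cross-validation (k = 10,
reduced with a warning when a class is smaller). The out-of-fold
predictions are pooled into a single confusion matrix, which is well
defined even with tiny folds, and converted to sensitivity,
specificity, accuracy, F-measure, MCC, PPV and NPV (AD positive;
percentages reported to two decimals; a metric with a zero denominator
is reported absent, never zero). Panels with sensitivity *and*
specificity ≥ 80% survive.

Fusion concatenates the surviving panels' biomarkers (deduplicated,
order preserved) and fits a linear discriminant on the training split
(stratified, seeded, 60/40). When the feature count reaches the sample
count the within-class covariance is singular and an `lsqr`/automatic
shrinkage solver is used instead of the SVD solver. The fitted model is
a plain linear rule (standardisation statistics, weights, intercept,
class order) serialised to JSON, so reloading reproduces predictions
exactly. The minimal-subset optimiser evaluates stage-2 panels in
ascending size and stops at the first size with a compliant panel,
returning the compliant panel with the largest sensitivity +
specificity (ties broken lexicographically), refitted on all
development data; if nothing complies it returns the best-scoring panel
flagged non-compliant. Validation never refits.

## Synthetic cohorts

Each channel is a weighted sum over bands of unit-variance band-limited
Gaussian noise plus a band-limited source shared by all channels,
passed through an AR(1) smoother, plus white measurement noise
(2 µV SD). Control band weights (delta .7, theta .8, alpha 1.5, beta
.6, gamma .3, scaled by 10 µV) give an alpha-dominant resting spectrum
with ≈20 µV RMS. The three planted effects:

* `slowing_effect` moves that fraction of the AD alpha weight into
  theta (60%) and delta (40%);
* `complexity_effect` adds to the AD AR(1) coefficient (base 0.2),
  suppressing high-frequency detail, which lowers LZC, ApEn and the
  fractal dimension monotonically;
* `coherence_effect` multiplies the AD shared-source weight by
  (1 − effect), lowering inter-channel coherence monotonically.

All effects at zero make the groups draws from one distribution.
Subject streams derive from (seed, group, index), so cohorts are
bit-reproducible and extensible. Defaults (20/20 subjects, 128 Hz,
60 s, all 19 channels, effects 0.3/0.35/0.5) emulate a small clinical
study with clearly present but not trivial group differences.

What the generator does **not** emulate: 1/f background structure,
non-stationarity, artefacts (EMG/EOG), volume conduction, topographic
gradients, age/sex covariates. Passing pipeline tests on these cohorts
therefore demonstrates the statistical machinery (effect recovery,
type-I control, separability, reproducibility), not clinical
performance on real EEG — with pure band-weight scaling, for example,
only the spectral family responds, precisely because the complexity
measures are scale-invariant.

## Problem sizes used in tests and the acceptance run

Counting audits use closed forms cross-checked by streamed enumeration
(the full 919,310-panel stage-2 stream is generated without being
materialised). Pipeline experiments run on reduced montages: the
separability experiment uses 10 central/posterior channels, 20/20
subjects, 60 s (2875 features; two cohorts, one for development and one
unseen); null-cohort type-I checks pool ≥10 replicate cohorts of 4
channels × 8 s; Monte-Carlo effect-recovery uses 20 seeds of small
cohorts. SVM screening in these experiments caps the smallest-first
panel stream at 400 panels (the `--scale` mechanism exposes the same
cap on the command line); the enumeration audits always report the full
closed-form counts. These sizes were chosen so the whole suite runs on
a single CPU in minutes while every claim keeps comfortable statistical
margins.

## Known limitations

* The amplitude-change-rate biomarker measures signed per-second drift;
  it telescopes, is dominated by low-frequency content and is nearly
  blind to pure amplitude rescaling of a stationary oscillation.
* The zero-crossing interval is undefined (flagged missing) for signals
  that never cross zero from above.
* Equal-width Tsallis binning over [min, max] is sensitive to single
  extreme samples, which compress the bulk of the distribution into few
  bins.
* Coherence is estimated without any volume-conduction correction
  (e.g. surface Laplacian); on real scalp EEG neighbouring channels
  share conducted signal and coherence panels should be read with that
  inflation in mind.
* LDA fusion of many surviving panels on few subjects relies on
  shrinkage; its held-out performance is honest, but the fitted weights
  are not interpretable feature importances.
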