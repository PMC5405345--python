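# Methods

`clipsim` models the perceptual similarity of short music clips (hundreds
of milliseconds) from low-level acoustic features. This note documents the
model, the synthetic-data generator that stands in for copyrighted stimuli
and unpublished behavioural data, and the numerical choices made where the
design was genuinely open.

## The model

The pipeline has three stages.

**1. Feature extraction.** Each clip is summarised by two 24-dimensional
feature sets. The timbre-descriptor (TT) set starts from an ERB-spaced
gammatone filterbank decomposition (64 bands, 26 Hz to 0.95 × Nyquist,
4th-order filters implemented as a cascade of four second-order stages for
numerical stability). Per 25 ms frame (1,102 samples, hop 551 — exact 1/2
overlap), ten spectral-shape descriptors are computed over the band-energy
distribution: the first four moments (centroid, spread, skewness,
kurtosis), slope, decrease (low-frequency-weighted slope), 95% rolloff,
flatness (geometric/arithmetic mean ratio), crest (max/mean), and spectral
variation (1 − normalised correlation of consecutive frame spectra). Each
series is summarised by its median and interquartile range (20 values);
four time-domain descriptors complete the set: energy-modulation frequency
and amplitude (maximal non-DC peak of the zero-padded FFT of the
rectified, 50 Hz-low-passed, DC-removed envelope) and the median and IQR
of the per-frame zero-crossing rate. The MFCC set holds the medians of
cepstral coefficients 1–12 (40 triangular mel filters spanning 0 Hz to
Nyquist, log power, orthonormal DCT-II; the 0th/energy coefficient is
dropped) and of their frame-to-frame first differences (ΔMFCC). The
combined set concatenates both (48 features). Frames with zero energy
yield undefined descriptors and are excluded from the summaries; an
all-silent clip is an error for the spectral set and maps the temporal
descriptors to 0.

**2. Normalization (N1–N5).** Applied per feature column before distances
are taken, never pooled across schemes: N1 identity; N2 range to [0, 1];
N3 z-scores (sample sd, L−1); N4 rank within the 16-clip test set,
x → rank(x)/L with midranks for ties; N5 rank against a reference corpus,
x → (count of corpus values ≤ x)/L′. The corpus is 4 genres × 110 songs ×
10 clips = 4,400 clips of 800 ms. All schemes are monotone, so within-
column ordering is preserved; N4 depends only on the test-set ordering.

**3. Similarity regression.** For 16 clips the m = 120 non-identical pairs
each contribute one row; the predictor for pair (i, j) and feature f is
|x_if − x_jf|, with optional meta predictors G (0 = same genre, 1 =
different) and |Δ release year|. The response y is the fraction of
participants who co-grouped the pair (lower triangle, diagonal excluded —
diagonal entries are 1 by construction and would inflate fit statistics).
The regression is partial least squares fitted by SIMPLS: components
maximise the covariance of X- and y-scores, the cross-product vector is
deflated against the orthonormalised X-loadings, and β = W*q′ maps back to
the original predictors. X and y are centered but not scaled (scaling
belongs to stage 2). The component count is k = 2 by default; seeded
8-fold cross-validation over pairs (`select_k`) is available, with ties
going to the smallest k. Predictions are not clipped to [0, 1]: the model
is linear and clipping would silently change R².

**Sparse selection.** Per bootstrap replicate, 4 clip ids are drawn *with
replacement* from the 16 and every pair touching a drawn clip is deleted
(expected retained fraction (14/16)⁴ ≈ 58.6%); the model is refit and β
recorded. Over B = 1000 replicates, the 0.025/0.975 percentiles give a CI
per feature; features whose CI excludes zero form the sparse model, refit
on all pairs with k capped at the selection size. Replicates whose
surviving matrix cannot support k components are refit with the largest
attainable k and logged, keeping B fixed. Meta predictors, when present,
participate like any column.

**Evaluation.** Model quality is the squared Pearson correlation between
predicted and observed similarities (shared variance, not 1 − SSE/SST),
with significance from the two-sided t-test with df = m − 2 (118 for 120
pairs) at α = 0.01. The grid crosses feature sets × normalizations ×
full/sparse × train/test over two stimulus sets; cross-set prediction
applies train-set coefficients to the test set's own normalized design
matrix (for N4, ranks are test-set-internal by definition, so nothing
leaks from train to test). Cells with an empty sparse selection are
reported with `n_features = 0` and an undefined R² rather than silently
falling back to the full model.

## The synthetic-data generator

Clips are parametric: a sum of harmonic partials with genre-specific
fundamental register and spectral tilt, plus band-limited Gaussian noise,
amplitude-modulated, peak-normalised to 0.9 and given 20 ms raised-cosine
fades (click-free, non-clipping; the fade shape and peak level are
implementation choices). Four genre templates (jazz, rock, pop, hip-hop)
are tuned to separate on spectral centroid, flatness, and modulation rate,
and carry the genre–decade coupling of the emulated stimulus selection
(jazz 1960–79, rock 1970–89, pop and hip-hop 1990–2000), which makes the
release-date predictor informative. Release years are drawn uniformly
within each genre's band. The two stimulus-set durations (400 ms and
800 ms) are generated independently, with no within-song pairing.

Participants are simulated by a latent model: ground-truth distances are a
weighted sum of absolute differences of (rank-normalized) generating
features, optionally plus a cross-genre increment; each participant
perturbs them with symmetric additive Gaussian noise (default sd 0.3 on
distances of order 1 — enough for graded similarities at 200 participants
while keeping the generating features recoverable) and sorts 16 items into
4 groups of 4 by local search (random equal-size start, best-improving
cross-group swaps, ties to the lowest index pair). On 8-item/2-group
instances the search attains the exhaustive optimum essentially always,
so it is a faithful stand-in for optimal constrained sorting at this
scale. Aggregating partitions gives the similarity matrix.

What the generator does *not* emulate: real music's non-stationarity
within a clip, melodic/rhythmic content, inter-participant strategy
differences, and the much higher perceptual noise of human data. Synthetic
R² values are therefore far higher than what human sorting data yield;
passing tests show the pipeline recovers planted structure, not that real
listeners behave this way.

## Numerical choices and defaults

| parameter | default | rationale |
|---|---|---|
| sampling rate | 44,100 Hz | CD-quality source material |
| frame / hop | 1,102 / 551 samples | 25 ms with exact 1/2 overlap |
| gammatone bands | 64, 26 Hz–0.95 Nyquist | common filterbank default |
| mel filters / coefs | 40 / 1–12 | most common MFCC dialect; 0th dropped |
| Δ window | first difference | simplest derivative; configurable upstream |
| k (components) | 2 | CV-selected in the emulated study design |
| B / n_drop | 1000 / 4 | percentile-CI stability / clip-deletion scheme |
| CI percentiles | 2.5 / 97.5 | 95% percentile bootstrap |
| participants | 200 | stable similarity fractions at 16 clips |
| noise_sd | 0.3 | graded but structured similarities |
| α | 0.01 | conservative correlation significance |

Degenerate inputs: constant y yields β = 0 with the mean as intercept;
constant feature columns are errors under N2/N3 (undefined) but legal
under N4 (all midranks); k beyond the rank of centered X raises with the
attainable maximum; empty bootstrap selection raises and advises the full
model. Normalization is computed once on the full test set and reused
inside bootstrap replicates (resampling happens downstream of
normalization in the pipeline order); refitting ranks per replicate is a
straightforward extension.

Scale of shipped experiments: tests exercise the pipeline at 16-clip sets
with 20–200 simulated participants, bootstrap sizes 50–1000, and a
reduced reference corpus (the full 4,400-clip corpus synthesises in a few
minutes and is exercised at scaled-down size, with the full recipe checked
by count).

## Known limitations

* The exact membership of the emulated 24-descriptor timbre set is fixed
  here as 10 spectral × {median, IQR} + 4 temporal descriptors; other
  selections from the same descriptor family are plausible.
* The participant decision model (noisy distances + equal-size local
  search) is one plausible mechanism; real sorting strategies are unknown.
* N5's insertion-rank extension assigns 0 below the corpus minimum, so N5
  output is in [0, 1] rather than (0, 1].
* Bootstrap percentile CIs on PLS coefficients are mildly anti-conservative
  under the null (~7% selection rate per feature at the 48-feature design
  size instead of the nominal 5%), a known property of percentile
  intervals on biased estimators.
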