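# Methods

`imspeech` implements a decomposition-plus-features pipeline for multiclass
imagined-speech EEG: noise-assisted multivariate empirical mode decomposition
(NA-MEMD) splits each multichannel segment into sub-band modes, six
statistics per channel per mode form the feature vector, and a
multireceptive-field CNN (MRF-CNN) classifies six balanced classes (five
imagined vowels plus rest). A wavelet-packet route and four classical
classifiers serve as comparators, and a trial-level repeated k-fold harness
evaluates everything without segment leakage.

## Preprocessing

The chain is order-fixed: resample to 250 Hz → 0.1 Hz high-pass → 59–61 Hz
order-4 Butterworth band-stop → amplitude-based trial rejection → trial-level
train/test split → windowed segmentation (1 s windows, 0.5 s step, so a 3 s
trial yields five segments).

* Resampling is polyphase (`scipy.signal.resample_poly`) with its built-in
  anti-aliasing low-pass.
* Both filters are zero-phase (forward–backward), the usual EEG convention;
  the effective magnitude order therefore doubles. The high-pass family is
  Butterworth order 4, matching the stated family of the notch.
* A 0.1 Hz corner has a ~10 s settling time, longer than an epoch, so the
  high-pass uses Gustafsson initial conditions (`filtfilt(..., method="gust")`),
  which minimize edge transients, and then subtracts the residual channel
  means exactly. On epochs much shorter than 1/cutoff the filter is close to
  pure mean removal, which is the correct limiting behaviour.
* Automatic rejection drops any trial with |sample| above a threshold
  (default ±100 µV). This is a stand-in rule: the emulated protocol rejected
  noisy trials by visual inspection without published criteria.

## Empirical mode decomposition

Univariate EMD sifts a signal by subtracting the mean of the upper and lower
natural-cubic-spline envelopes of its extrema until the detail is an
intrinsic mode function (IMF); IMFs plus residue reconstruct the input
exactly because the construction telescopes. Choices the method leaves open,
fixed here and exposed in configuration:

* **Extrema**: strict sign-change detection; a plateau counts as one
  extremum at its midpoint (deterministic tie-break).
* **Boundary handling**: the two outermost extrema at each end are mirrored
  about the first/last sample before spline fitting.
* **Splines**: natural cubic at the extended knots. Natural end conditions
  mean polynomial trends are reproduced exactly only away from the
  boundaries (end-condition error decays geometrically with knot count);
  the mirrored knots keep that error controlled where it matters.
* **Stoppage**: the envelope-amplitude criterion — sifting stops when
  |envelope mean| / envelope amplitude is below θ₁ = 0.05 on at least
  95 % of samples (α = 0.05) and below θ₂ = 0.5 everywhere — with a hard
  cap of 100 sift iterations. Decomposition stops when the residue has
  fewer than three extrema or the IMF budget (default 9) is reached.

MEMD generalizes the local mean to n-channel signals: the signal is
projected onto K quasi-uniform direction vectors on the unit (n−1)-sphere;
for each direction the full multivariate signal is spline-interpolated at
the projection's maxima and at its minima; the direction's envelope is the
average of those two curves, and the local mean is the average over
directions. All channels are sifted jointly, which is what aligns modes
across channels. Direction vectors come from a Hammersley low-discrepancy
sequence pushed through the inverse normal CDF and normalized (K = 64 by
default; a seeded Cranley–Patterson rotation makes the set reproducible).
The sifting stop rule is the univariate one applied to ‖mean‖/amplitude.

NA-MEMD prepends q independent white-Gaussian-noise channels (default q = 1)
whose variance is a fraction (default 5 %) of the mean channel variance,
runs MEMD on the (n+q)-channel composite, and discards the noise channels'
modes. The broadband noise forces the quasi-dyadic filter-bank behaviour —
on white-noise input the dominant frequency of successive IMFs decreases
strictly — and stabilizes mode alignment. q and the noise fraction are not
prescribed by the protocol this follows; 2–10 % is the range the NA-MEMD
literature recommends.

The decomposition runs jointly over all provided channels. IMF 1 (the
fastest mode) is excluded from features; IMFs 2–9 are used. When fewer than
9 IMFs emerge, the missing bands are padded with zero-signal statistics so
classifier inputs have fixed length (dropping trials instead would unbalance
folds).

## Wavelet-packet comparator

A 3-level wavelet packet decomposition with the Daubechies-2 wavelet
produces 2³ = 8 terminal sub-bands per channel, matching the eight IMF
bands. Terminal nodes are frequency-ordered (not Paley order) so node index
is monotone in band, and statistics are computed on the decimated
coefficient sequences themselves (node lengths differ from the signal
length). Boundaries use symmetric extension. Reconstruction from all eight
nodes is exact to numerical precision.

## Features

Per channel per sub-band: mean, absolute mean, variance, standard deviation,
skewness, kurtosis. Conventions: variance and standard deviation use the
n−1 normalization with variance = std² exactly; skewness and kurtosis are
the biased standardized central moments (normal kurtosis = 3, no excess
subtraction) — the defaults of the numerical environment this emulates.
Zero-variance inputs return skewness = kurtosis = 0 rather than NaN, which
doubles as the padding convention. Vectorization is channel-major, then
sub-band, then statistic, with names `ch{c}_band{b}_{stat}`; the order is a
fixed contract because the classifier's 1×k convolutions slide over it.

Features are z-scored per column using training-fold statistics only
(zero-variance columns are centered, not scaled). Whether the original
protocol standardized is unstated; standardization is on by default and
switchable.

## MRF-CNN

Four single-receptive-field branches run in parallel on the same 1-D
feature vector. Each branch is conv(1×k) → batch-norm → ReLU → average-pool,
twice, then one fully connected layer; branch outputs are concatenated into
a single softmax head. Only branch 1's first kernel (1×20) is prescribed;
the others default to an arithmetic ladder (40, 60, 80) to realize small-to-
large receptive fields. Filter counts (8, 16), pool width 4, second kernel
10 and 32 FC units per branch are desk-scale choices; all are configurable.
The phrase "ReLU follows average pooling" is ambiguous; the conventional
conv→BN→ReLU→pool reading is the default and the alternative is a switch.

Training: softmax cross-entropy, Adam at learning rate 0.001 for exactly
2000 optimizer steps ("iterations" is read as steps, not epochs; batch size,
unstated, defaults to 32), no early stopping. A 10 % held-out split of the
training fold provides the validation curve. The network is pure NumPy
(explicit forward/backward passes), so training is bit-reproducible for a
fixed seed.

Comparators: linear SVM, RBF SVM with bandwidth from a median
pairwise-distance heuristic on a 200-row training subsample
(γ = 1/(2·median²)), LDA, and k-NN with k = 4, all through scikit-learn
behind a uniform fit/predict interface.

## Evaluation

Folds are drawn over **trials**, stratified by class within participant,
before segmentation — all segments of a trial inherit its assignment, so no
segment appears on both sides of any split (asserted on every run).
Repeated k-fold defaults to 10×10. Models are fitted per participant;
accuracy is reported at segment level (the classification unit) with a
trial-level majority-vote accuracy alongside, since the original protocol
does not say which it reports. Segmentation, decomposition and feature
extraction are per-trial local operations with no cross-trial statistics,
so they are computed once and cached; only standardization and training see
fold-specific data, which is mathematically identical to recomputing
everything after the split.

The report carries per-fold accuracies, mean ± sd (the mean is the
arithmetic mean of fold accuracies), pooled confusion matrices (counts and
row-normalized), and two-sided paired t-tests on fold-wise accuracy
differences between classifiers. Zero-variance differences yield a
degenerate marker instead of a numeric p-value. Raw p-values are primary;
Holm-adjusted values are reported as a clearly labelled extension.

## Synthetic data

The generator emulates the vowel-imagery protocol: 9 participants (reported
cohort sizes for this protocol are inconsistent between nine and ten; nine
is the default and the count is configurable), 5 sessions × 10
repetitions per class, 3 s trials at 250 Hz, 6 balanced classes. Class
identity is encoded purely as band-limited oscillatory content — each class
owns a low (≤4 Hz) and a high (≥30 Hz) narrowband tone with per-trial
randomized phase and frequency jitter — over 1/f background noise (pink by
default) and an optional 60 Hz powerline sinusoid that exercises the notch.
Channel count defaults to 8 for desk-scale decomposition (64 supported).

What this does **not** emulate: volume conduction and realistic spatial
covariance, non-stationarity within trials, eye/muscle artifacts, or any
physiological generative model. Passing tests therefore demonstrate that the
pipeline recovers known spectral class structure and respects its own
contracts — not that the published real-data accuracies are reproducible,
which would require the unreleased recordings.

## Problem sizes and numerical notes

Tests and the acceptance script run the method at desk scale as this
package's own study conditions: 2–4 channels, K = 8–16 directions for
pipeline runs (K = 64 for the dedicated alignment check), 1.5–2 s trials,
3-fold single-repeat CV, and small CNN kernels (6, 10, 14, 18) when feature
vectors are short — the kernel ladder must fit the input length, and a
single-band feature vector has only channels×6 elements. The full-scale
defaults (64 directions, 10×10-fold, 2000 iterations, kernels 20–80) remain
the configured defaults for real use.

Degenerate inputs: constant signals have no extrema and become pure residue;
a zero-variance channel makes NA-MEMD's noise scaling undefined and is
rejected; all-zero sub-bands produce the zero-statistics convention;
dominant frequency of an all-zero mode is NaN.

## Known limitations

* NA-MEMD is O(K × sift iterations × spline fits) per segment; 64-channel
  decompositions at K ≥ 128 directions are expensive on one core.
* EDF output is 16-bit quantized (inherent to the format); the delimited
  route is lossless.
* The exact architecture constants of the emulated network (branch kernels
  2–4, filter counts, pooling, FC widths) are unpublished, so published
  accuracy tables are not a reproduction target at any scale.
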