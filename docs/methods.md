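# Methods

This package implements an end-to-end analysis of mouse ultrasonic
vocalizations (USVs): detection of calls in continuous 300 kHz recordings,
formula-defined acoustic features per call, a family of classifiers that
decode the emitter's class (sex or strain) from single calls, and analyses
of what a trained network represents. Because the pipeline is exercised on
synthetic data with exact ground truth, every stage is testable end to end.

## Synthetic vocalizations

Mouse USVs are single frequency-modulated whistles, 10-150 ms long, in the
25-125 kHz band, essentially without harmonics. The generator samples a
per-call trajectory (duration, start frequency, net sweep, optional
sinusoidal tremolo, silent breaks >= 2 ms, optional band-limited broadband
content) from per-class distributions, synthesizes a phase-continuous tone
at 300 kHz, and schedules calls over white Gaussian noise at a configurable
SNR (defined against mean per-call power). Defaults follow the magnitudes
typical of laboratory recordings: ~200 calls per minute, per-call amplitude
x U[0.5, 1.5] (uncontrolled mouse-microphone distance), optional 32 %
class imbalance, and 9 + 8 individuals per two-class dataset. Six derived
labels per call (direction, peaks, breaks, broadband, tremolo, complexity)
stand in for manually scored call properties; they are deterministic
functions of the sampled trajectory and therefore exact.

Two class constructions exist. The *linear* profiles shift duration and
frequency distributions between classes (magnitudes are configuration, not
science — real effect sizes are not published as usable numbers). The
*nonlinear* profiles plant the class signal exclusively in an interaction:
class = parity of (sweep direction, tremolo presence), with every marginal
parameter distribution identical across classes (verified by rank-sum
tests at n = 2000 per class). This construction is the surrogate for the
claim that class information can live in feature combinations that no
single feature carries.

What the generator does *not* emulate: vocal-fold acoustics, room
reverberation, overlapping callers, harmonic stacks, and the long-tailed
repertoire structure of real mice. Passing tests therefore demonstrate the
correctness and the qualitative behavior of the pipeline, not real-data
accuracy levels.

## Call detection

The recording is high-pass filtered (4th-order Butterworth, 25 kHz), then
transformed to a magnitude spectrogram (500-sample Hann windows, 50 %
overlap: 1.67 ms windows, 1.2 kHz frame rate). Of the 251 non-negative
rFFT bins the top 233 are kept (600 Hz spacing, ~10.8-150 kHz), which is
the fixed frequency axis of all later stages. The spectrogram is
sparsified by zeroing all bins below its recording-wide 70th percentile.
Candidate intervals are contiguous runs of frames that pass an energy gate
(any bin at or above the recording-wide 99.8th percentile of bin values);
a candidate must additionally pass

* a continuity gate — the per-frame peak-row track's absolute one-step
  jumps, accumulated over 4-step windows, must somewhere stay below 15
  bins (a stable spectral line exists); single-frame candidates pass by
  convention; and
* a frequency gate — energy-weighted mean frequency >= 25 kHz.

Both gates are independent predicates, so their order is irrelevant.
Accepted intervals closer than 15 ms are merged (this re-joins calls that
contain internal breaks); candidates shorter than 5 ms are dropped (the
sub-frame debris the merge rule cannot attach to anything). Each call is
exported as a left-aligned 100x100 uint8 image: the 233-row patch is
expressed in 1 ms time pixels, truncated at 100 ms, rescaled by 100/233 in
both axes (M = round(N·100/233) occupied columns) and linearly mapped to
[0, 255] per image.

Numerical conventions worth noting: the energy gate uses >= (strict >
misses the maximum when the percentile interpolates to it); percentiles
are computed per recording; the Hann window is a configuration default
(the window function is otherwise a free choice).

## Acoustic features

Features are computed on a call's full-band power patch S(f, t) =
|STFT|^2, resampled to 1 ms frames. The patch is first denoised by min/max
level-set curvature flow, realized at pixel scale by its standard discrete
equivalent (3x3 stencil median) with a min/max switch on the local 3x3
average vs the global median: isolated speckle is eroded, the call's ridge
(wider than one pixel) is nearly a fixed point. Five iterations are the
default — enough to clear speckle while leaving tremolo crests (regions of
high ridge curvature) intact; more iterations visibly bias the tracked
fundamental at modulation extrema.

The fundamental-frequency line FF(t) is the maximal-amplitude bin per
frame, restricted to the temporal range bearing Prewitt edges (threshold:
3x the mean gradient magnitude — a free convention, chosen on noiseless
synthetic calls). Interior frames without edges are breaks (FF = 0);
single-frame outliers deviating > 5 kHz from both neighbors are replaced
by their interpolation (single pass). FE(t) = S(FF(t), t) where FF > 0.

Eighteen automatic scalars are computed (duration; spectral width
max-min of FF; start/end/min/max frequency; FF-mean and intensity-weighted
mean frequency; skewness/kurtosis of FE(t) and of the spectral marginal,
population definitions with Pearson kurtosis; direction = sign of the mean
one-step FF difference; Wiener entropy = temporal mean of geometric/
arithmetic spectral mean; spectral salience = temporal mean of the largest
off-zero local maximum of the across-frequency autocorrelation over its
zero-lag value, computed on mean-subtracted columns; tremolo = the same
salience applied to the voiced FF(t) sequence, mean-subtracted so a
constant fundamental scores 0; mean FE; spectral purity = temporal mean of
max/median, with a zero median replaced by the frame's smallest positive
value). Mean subtraction in the salience is deliberate: on raw
non-negative spectra the autocorrelation of white noise is dominated by
the squared mean and every frame would look periodic.

The extended per-call descriptor is a 457-vector: 24 scalar slots (18
automatic + the 6 scored labels, which the generator supplies as ground
truth), the FF line zero-padded to 100, the 233-bin frequency marginal
(per-bin temporal mean of FE contributions), and the FE time marginal
zero-padded to 100.

## Classifiers

Three architectures are specified declaratively and built by a compact
NumPy neural-network core (2-D/1-D convolutions with "same" padding,
batch normalization on every layer, ReLU, inverted dropout on fully
connected layers, Xavier initialization, Adam, sigmoid or softmax heads
with optionally class-weighted cross-entropy):

* spectrogram CNN — 6 conv layers (kernels 10, 5, 3, 3, 3, 3; strides
  2, 2, 1, 1, 1, 1; 256 units each by default) + 3 FC layers of 120 units
  (80 for the broadband variant); heads: sigmoid for binary tasks,
  softmax-4 for peaks/breaks, softmax-3 for direction, softmax-k for
  individual identity;
* dense feature network — 4 FC layers of 70 units on the 9 basic features;
* semi-convolutional network — three parallel 1-D conv stacks (kernels
  7, 5, 3, 3, 3; strides 2, 2, 1, 1, 1; 32 units) over the FF line, time
  marginal and frequency marginal, concatenated with the 24 scalars into
  3 FC layers of 90 units.

Convolutions are evaluated as a sum of k^2 shifted GEMMs (one matmul per
kernel offset), which on one CPU is ~3x faster than im2col for multi-
channel layers; the single-channel input layer uses im2col. Gradients are
verified against central differences and the conv forward against a
brute-force implementation.

Training protocols are staged (epochs, learning rate, dropout): 40/25/25
epochs at lr 1e-3/1e-4/1e-5 with dropout 0/0.5/0.7 for spectrogram
networks; two stages for feature prediction (the second with quadratic lr
decay 1e-3 -> 1e-5); four stages down to lr 2e-6 for the extended
network; batch size 64 throughout. A `scaled(f)` helper shrinks stage
lengths proportionally for reduced-compute runs. Augmentation operates on
[0, 1]-normalized inputs: time clip up to 10 % per end (re-left-aligned),
amplitude x U[0.5, 1.5], Gaussian noise with variance U[0, 0.01]; the 1-D
streams use clip + noise without amplification except the frequency
marginal, which uses amplitude U[0.8, 1.2] + noise. Class imbalance is
handled by inverse-frequency loss weights for networks and by downsampling
the larger class for the baselines.

Baselines: ridge regression by direct normal equations w =
(X'X + λI)^-1 X'y on {0, 1} targets with the decision at 0.5 (the
mathematically identical dual form is used when d > n; no intercept —
λ = 10 for image inputs, inside the broad flat region of accuracy), and a
soft-margin SVM with a quadratic kernel for images, linear for features.

Evaluation is percent correct, overall and per class, under
leave-one-subject folds (one fold per individual, subject-disjoint by
construction) or k random folds partitioning the data; shuffled-label
controls permute the label vector.

## Network interpretation and embeddings

Activation sparsity is 1 - active/total units, an active unit being
strictly positive post-ReLU. Class structure is quantified by mean
pairwise Pearson correlation of flattened activation vectors within and
across classes (constant vectors excluded). Deconvolution back-projects a
conv layer's (optionally single-channel) response through the transposed
weights of all preceding convolutions — exactly the adjoint operator,
verified in matrix form — with an optional guided variant that masks by
the forward ReLU pattern. Embeddings: PCA, and t-SNE to 3 dimensions
(perplexity 30, optional PCA pre-reduction to 9 for feature vectors or
100 for images, explicit seed, duplicate rows jittered); decoding is
leave-one-out 1-nearest-neighbour (ties to the lowest index, verified
against O(n^2) brute force); density differences subtract per-class
Gaussian KDEs (Scott's rule) normalized to unit mass on a common grid.

## Statistics

Two-group comparisons use Wilcoxon's rank-sum (exact for small tie-free
samples), paired comparisons the signed-rank test, multi-group the
Kruskal-Wallis test; Bonferroni correction is available. Above-chance
classification uses the exact one-sided binomial tail. Effect sizes are
reported as between-group variance over total variance.

## Problem sizes and reproducibility

The bundled analyses and the acceptance script use these sizes: a 60 s
recording with 200 calls at 20 dB SNR for detection scoring; 120 noiseless
calls for feature recovery (duration within 2 ms, mean fundamental within
1 kHz, exact break count, >= 95 % of calls); and a 2000-call
interaction-coded dataset for the classifier comparison, evaluated as the
mean of two complementary 1000/1000 folds, with the CNN reduced to 32
units per layer and the first protocol stage scaled to 5 epochs (10 in
the single-split interpretation analysis) — ample
for this surrogate, where it reaches ~100 % training accuracy. The
two-fold averaging keeps the shuffled-label control's sampling error near
1 percentage point so the 50 ± 3 % chance band is a ~3-sigma statement.
All randomness flows through explicit seeds; repeated runs are
bit-identical.

## Known limitations

Real-data accuracies cannot be reproduced from synthetic calls and are not
asserted anywhere; the surrogate demonstrates ordering and direction-of-
effect claims only. The energy gate's percentile threshold couples call
density to the detection threshold — recordings with a very low duty cycle
push the 99.8th percentile into the noise tail; the merge rule then
controls the damage. The FF tracker assumes a single spectral component
(valid for USVs, wrong for harmonic-rich signals). Batch-norm statistics
make training nondeterministic across BLAS builds at the last digit, but
fixed seeds give bit-identical runs within one environment.
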