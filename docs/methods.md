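# Methods

`ramanres` classifies Raman spectra of colorectal tissue as tumor or normal
with a one-dimensional residual convolutional network, and interprets the
trained network with gradient-weighted class activation mapping (Grad-CAM).
This note records the model, the synthetic data it is validated on, the
numerical choices, and the limits of what the tests show.

## The classification model

A preprocessed spectrum is a vector of 1024 intensities on the uniform grid

    channel i  ->  385 + i * (1545 - 385) / 1023  cm^-1,   i = 0..1023,

min-max scaled to [0, 1]. The network maps an (N, 1, 1024) batch to N tumor
probabilities:

- **Stem**: kernel-3 convolution, 1 -> `stem_channels` channels, length
  preserved.
- **Stages** (default 10): each stage is one *normal* residual block
  (channels and length preserved, identity shortcut) followed by one
  *downsample* block (stride-2 first convolution, 1x1 stride-2 projection
  shortcut, channels stepping up a doubling schedule capped at
  `channel_cap`).
- **Blocks** are pre-activation: two [BN -> ReLU -> dropout -> conv(k=3)]
  sets; the block output is H(X) = F(X) + shortcut(X).
- **Head**: BN -> ReLU -> dense layer to a single logit -> sigmoid.

With the defaults (stem 32, 10 stages, cap 1024) the pre-head feature map
is (N, 1024, 1) and the parameter count is 77,323,841. The default
configuration preserves the reference topology; experiments in this
package's tests and acceptance script use a narrow schedule of the same
family (`ModelConfig.compact()`: stem 8, 6 stages, cap 32, 64k parameters),
sized so that training runs complete in minutes on a single CPU core with
the NumPy compute backend.

Two architecture choices are worth flagging:

- **Zero-initialized residual branches.** The second convolution of every
  block starts at zero, so each block is initially the identity (or a pure
  projection). This is the standard stabilizer for deep residual stacks;
  without it the scaled training runs showed oscillating validation
  accuracy.
- **Batch-normalization recalibration.** Dropout inflates activation
  variance during training, so BN running statistics collected then
  misrepresent evaluation-mode activations; the error compounds across the
  network's many BN layers and can destroy evaluation accuracy outright
  (train-mode accuracy 1.0 against evaluation-mode 0.5 in a controlled
  experiment). After every epoch the running statistics are therefore
  re-estimated over the training set with dropout disabled
  (`ResNet1D.recalibrate_batchnorm`). Epsilon in the BN denominator is the
  usual numerical stabilizer (1e-5).

## Training

Class-weighted binary cross-entropy,

    L = -mean( w1 y log p + w0 (1-y) log(1-p) ),
    w1 = n / (2 n_pos),  w0 = n / (2 n_neg)  (inverse-frequency weighting),

minimized with Adam (beta1 0.9, beta2 0.999). Defaults follow the reference
protocol — learning rate 1e-4, batch size 128, 200 epochs, 80/10/10
stratified train/validation/test split over spectra. Model selection keeps
the parameter snapshot with the best validation accuracy; selecting on the
test set would leak, so that variant is available only as
`selection="last"` plus external monitoring. Probabilities are clamped to
[1e-7, 1 - 1e-7] inside the loss; the decision threshold is 0.5 with ties
predicted positive.

Scaled runs (tests, acceptance script, examples) train the compact model
for 15-30 epochs at learning rate 1e-3: they use roughly 60x fewer
optimizer steps than the reference schedule, and a proportionally larger
step size recovers convergence on the separable synthetic task. These
sizes are the package's own experimental choices and are stated with each
run.

A `split_mode="patient"` option assigns whole patients to one partition.
Spectrum-level splitting mirrors the reference protocol but lets spectra
from one patient span partitions, which optimistically biases accuracy on
real cohorts; patient-level splitting is the honest control and is
recommended for any claim about generalization to new patients.

## The three-strategy ensemble

Three views of the data each train their own network:

1. **original** — the preprocessed rows;
2. **intensify** — rows whose main peaks (prominence >= 0.05) are
   multiplied by 1.5 within +-5 channels, blended linearly to 1 at the
   window edges, then renormalized;
3. **split** — two half-grid windows, channels [0, 512) and [128, 640),
   each renormalized and fed to a shallower network (one fewer stage);
   their probabilities are averaged.

The ensemble probability is the fixed convex combination

    p = 0.8 p_original + 0.1 p_intensify + 0.1 p_split,

from weights 8:1:1 normalized. The window bounds are read as channel
indices on the 1024-point grid, covering the lower-shift half of the
spectrum; the intensify factors are unquantified in the reference protocol
and the defaults here (prominence 0.05, half-width 5, factor 1.5) alter
peaks visibly without saturation.

## Preprocessing

Per spectrum, in order:

1. **Baseline.** Asymmetric least squares in Whittaker-smoother form:
   minimize sum w_i (y_i - b_i)^2 + lambda sum (D2 b)_i^2 with w_i = p where
   y_i > b_i else 1 - p, iterated to a fixed point of the weights (at most
   10 iterations). Defaults lambda = 1e5, p = 0.01 — the community-standard
   settings; the pentadiagonal system is solved exactly per iteration.
   Whether the reference procedure fit asymmetric-weighted polynomials or a
   Whittaker smoother is ambiguous; the Whittaker form is implemented.
2. **Denoise.** Savitzky-Golay filter, window 11, order 3 (the reference
   procedure names no method; window 0 disables the step). Exact on
   polynomials up to the filter order.
3. **Resample.** Linear interpolation onto the 1024-point grid, values
   clamped at the measured range's edges; a spectrum must cover at least
   half the target range.
4. **Normalize.** Min-max to [0, 1]; a constant spectrum maps to all zeros
   rather than erroring, so degenerate augmented rows keep batches valid.

Resampling precedes normalization so the [0, 1] invariant holds on the
model grid. On noiseless simulated spectra with the default polynomial
fluorescence background, this chain recovers the normalized peak-only
signal to a maximum absolute error below 0.05 (acceptance-tested).

## Augmentation

Three stochastic operators extend a training set, applied per copy in the
order noise -> shift -> scale, then renormalized:

- Gaussian noise with s.d. proportional to each channel's magnitude
  (default fraction 0.03; a zero channel stays exactly zero);
- a uniform random translation of at most +-3 channels, edge-replicated
  (zero fill would fabricate spurious band edges);
- a multiplicative factor ~ Uniform(0.2, 2).

Because rows are renormalized, the pure multiplicative factor is annulled
unless combined with the additive noise — which is why noise runs first.
Augmentation never alters labels and is reproducible from its seed.

## Synthetic data

The generator emulates the acquisition the classifier targets: 1024
channels over 385-1545 cm^-1; Gaussian bands (width 8 cm^-1) at the fifteen
positions of the shipped peak-assignment table with amplitudes 1/2/3 for
weak/mid/strong bands; a fourth-degree polynomial fluorescence background
with positive coefficients and peak-comparable magnitude; per-replicate
Gaussian noise at 2% of the local magnitude with three replicates averaged
per sample; and 26 synthetic patients, each contributing both classes with
a patient-level amplitude factor (s.d. 5%).

The tumor class *reduces* the four bands at 936, 986, 1328 and 1447 cm^-1
by 0.3 (10% of their amplitude). The sign matters: per-spectrum min-max
normalization divides by the spectrum maximum, and if the tumor class
*raised* the strongest bands the class signal would be redistributed onto
every other channel by the rescaling (measurably none of the
class-difference mass remains at the informative bands), leaving nothing
localized for an interpretation method to find. With reduced tumor bands
the overlapping 1125/1130 cm^-1 complex acts as a class-independent
normalization anchor and the class difference stays at the four bands.
Reduced polysaccharide/collagen band intensity in tumor tissue is also the
biologically expected direction. `ground_truth_channels` returns the
channels within one band width of any class-informative band and is the
reference for the interpretation tests.

What the generator does **not** emulate: cosmic-ray spikes, instrument
response and wavelength-calibration drift, non-Gaussian line shapes,
heteroscedastic detector noise, within-patient heterogeneity beyond a
scalar amplitude factor, and any real biochemical covariance between bands.
Passing tests therefore show that the pipeline's machinery is correct and
that it can learn and localize a planted, separable class signal — not
that comparable accuracy would be reached on patient spectra.

## Grad-CAM

For a spectrum x and target class c (1 = tumor; with a single sigmoid head
the normal-class map is computed on the negated logit), relevance is

    CAM = ReLU( sum_k alpha_k A_k ),   alpha_k = mean_t dL_c / dA_k(t),

where A is the feature map of the target block, linearly upsampled to 1024
channels and min-max scaled. Activated regions are maximal channel runs
with relevance >= 0.5 (configurable), at least 3 channels long, annotated
against the shipped assignment table with a +-5 cm^-1 tolerance.

**Target layer.** Each stride-2 stage doubles a feature cell's receptive
field; a few stages in, one cell spans hundreds of channels — wider than
any Raman band — and the relevance map delocalizes. Measured on the trained
synthetic model, the deepest feature maps put most relevance outside the
planted bands, while maps that keep at least a quarter of the input
resolution localize cleanly. The default target is therefore the deepest
block with spatial length >= max(8, input_length / 4); the layer is an
argument of `grad_cam` for users who want a different depth.

## Evaluation

Accuracy, precision, recall and F1 from confusion counts (zero
denominators report 0, logged, never NaN); ROC over all distinct score
thresholds with tied scores sharing one vertex; AUC by the trapezoidal
rule, which under this tie handling equals the Mann-Whitney pair statistic
with half credit for ties (property-tested against exhaustive pair
enumeration). The baseline harness fits scikit-learn SVM and random
forest, XGBoost and LightGBM on the flattened rows with shared splits and
the same metrics, skipping unavailable backends with a warning; it is a
comparison harness only, with no tuning beyond fixed seeds.

## Numerical choices and degenerate inputs

- Network arithmetic is float32 (GEMM-bound im2col convolutions); float64
  is available via `ModelConfig.dtype` and is used in the finite-difference
  gradient tests, which match analytic gradients to ~1e-10.
- All randomness flows through explicit seeds; one `global_seed` derives
  every module seed by fixed offsets (`ramanres.config`). Identical seeds
  give bit-identical datasets, augmentations, initializations and training
  histories on a fixed platform.
- Batch normalization refuses training-mode batches of one sample; the
  training loop drops a trailing batch of size one.
- A constant spectrum normalizes to zeros; an all-zero relevance map yields
  no activated regions and a warning, not an error.
- Descending-axis CSV input is reversed on read with intensities kept
  paired.

## Known limitations

- The compute backend is NumPy on CPU; the default 77M-parameter
  configuration is practical for inference and architecture checks but not
  for full-scale training, which is why experiments use the compact
  schedule.
- The exact block count and channel schedule of the reference network are
  not recoverable from its description; only the input shape, kernel size,
  block internals, downsampling rule and terminal feature shape are pinned,
  and the schedule here is configurable.
- Printed loss in the reference protocol is reproduced as class-weighted
  cross-entropy; its printed algebra is not a valid cross-entropy and was
  treated as typographical.
- Synthetic validation bounds what the tests demonstrate (see above);
  reported accuracies on the synthetic task are not comparable to accuracy
  on patient data.
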