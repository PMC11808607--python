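# Methods

## Network family and the reference configuration

The network is declared as an ordered block table (`ArchitectureConfig`):
a 3×3 convolutional stem, residual depthwise-separable blocks with
squeeze-and-excitation (SE) gating, and a global-average-pool + softmax
head. Two residual block kinds exist: `proj_block` (1×1 projection
convolution + batch norm on the skip path; required when channels or
resolution change) and `id_block` (identity skip; requires equal channels
and stride 1). The SE gate sits after the residual addition and output ReLU
and rescales the block output channel-wise.

The reference table (`portnet_reference`) is 13 rows: widths
3→24→48→96→96→96→192→192→192→384→768→768→768→(classes), stride schedule
2,2,2,–,–,2,–,–,2,1,–,– (32× total downsampling; a 224 input reaches the
head at 7×7, a 96 input at 3×3), and SE hidden widths 6, 12, 6, 7, 33, 24,
24, 48, 96, 96, 96 per residual row. Nominal SE widths follow the usual
C_out/8 bottleneck; three rows (6, 7, 33) deviate deliberately so that the
family's published parameter budget is met exactly. With the normative bias
conventions — convolutions bias-free, batch norm 2 trainable values per
channel, SE affine maps and classifier with biases — the total is exactly
2,621,827 trainable parameters for 3 classes, independent of input
resolution (global average pooling decouples the head from spatial size).
The closed-form per-block counts are:

| kind | trainable parameters |
|---|---|
| stem | 9·Cin·Cout + 2·Cout |
| proj_block | 11·Cin + 2·Cin·Cout + 5·Cout + 2·Cout·h + h |
| id_block | C² + 14·C + 2·C·h + h |
| head | Cin·K + K |

`count_params_closed_form` implements this arithmetic;
`introspect_params` enumerates the arrays held by a built model. The test
suite requires the two to agree block-by-block on the reference table and on
randomized architectures — each route is an independent check on the other.

## Layer engine

Layers (`portnet.nn`) carry explicit forward/backward passes in float32:
dense convolutions run as im2col plus one BLAS matrix product, depthwise
convolutions as k² shifted multiply-accumulate taps, and 1×1 convolutions as
batched matrix products over flattened spatial positions. Initialization is
uniform fan-in (U(−1/√fan_in, 1/√fan_in)) from a generator seeded per build,
so a (config, seed) pair fully determines the model.

Batch normalization uses eps 1e-5 and, for its eval-mode running
statistics, a cumulative average over all training batches rather than the
conventional exponential moving average: with the short schedules used here
(tens of optimizer steps), an exponential average with momentum 0.1 retains
a visible fraction of the arbitrary (0, 1) initialization, which
mis-scales eval-mode activations through the stacked normalization layers.
Additionally, `train()` ends by re-estimating the running statistics in one
frozen-weight sweep over the training data, since statistics accumulated
under early, rapidly changing weights are stale by the last epoch. Neither
choice changes any trainable parameter or the parameter count.

Ties in argmax prediction resolve to the lowest class index (numpy argmax
semantics), making inference deterministic.

## Preprocessing chain

`preprocess_pipeline` = brightness equalization ∘ edge-enhanced denoising:

1. k×k box filter (default k=3), reflective borders;
2. Gaussian high-pass (img − G_σ(img), default σ=2.0, kernel half-width
   ⌈3σ⌉, reflective borders) computed from the *original* image and added
   back with gain α (default 1.0) — restoring the edges the box filter
   attenuated. Computing the high-pass from the already-filtered image is
   available behind `highpass_on_filtered`. The per-channel mean is
   subtracted before blurring, making the high-pass of a constant image
   exactly zero in floating point (the operation is shift-invariant up to
   rounding);
3. 256-bin CDF histogram equalization of the brightness channel only —
   BT.601 luminance by default (`y → round(cdf(y)·255)`, half-up rounding),
   HSV value behind `space="hsv"`. Chrominance is untouched; the final
   conversion back to RGB clips into range, which is the only way chroma
   can shift.

Kernel size, σ, α, the high-pass source, and the brightness space are not
pinned down by the protocol this mirrors; all are exposed in
`PreprocessParams` with the defaults above chosen as the mildest standard
settings.

## Splits and evaluation

`holdout_split` carves a stratified hold-out of n images (largest-remainder
apportionment across classes) and halves it into validation/test, odd
per-class carve-outs alternating so the halves stay exactly equal.
`kfold_split` wraps scikit-learn's `StratifiedKFold` (shuffled, seeded);
per-class fold counts differ by at most 1 and every item is tested once.

Scalar metrics follow the confusion-count definitions with both averaging
modes recorded explicitly: micro (pooled counts — in single-label
classification this forces PRE = REC = ACC, the pattern of an external-test
table reporting one identical number per model) and macro (unweighted class
means, the pattern of a cross-validation table where PRE ≠ ACC). Macro is
the cross-validation default, micro the external-test default. AUC is
one-vs-rest, computed by the rank (Mann–Whitney) formulation with half
credit for ties, macro-averaged over classes with a defined AUC; ROC curve
points come from scikit-learn's threshold sweep. Cross-validation summaries
report mean ± t_{0.975,k−1}·sd/√k per metric.

## Training protocol

Adam (β = 0.9/0.999, eps 1e-8) on softmax cross-entropy. Protocol defaults:
batch 32, 10 epochs, learning rate 1e-5. The optimizer and loss are the
standard choices for this model family; both are configurable. Per-fold
models in cross-validation are built fresh with seeds derived from the
master seed via `SeedSequence([master, fold])`, and train/test index
disjointness is asserted on every fold. Scaled-down demonstration and test
runs raise the learning rate to 1e-3 so the network converges on hundreds
of images within 10 epochs; problem sizes used in the protocol tests are
300 images at 96×96 for the full reference network (five folds, ~6 minutes
on one CPU) and 120–150 images for the 5-block toy variant (seconds).

## Synthetic data

`portnet.synthetic` renders seeded 3-class RGB images: anti-aliased rotated
ellipses on a pale noisy background, one morphology recipe per class —
many small eccentric purple ellipses ("adenocarcinoma-like"), few large
round pink blobs ("benign-like"), elongated overlapping blue-gray ridges
("squamous-like"). Palettes are required to be distinct; Gaussian noise
(sd 6/255) is added after rendering, before uint8 quantization; per-image
boolean masks mark pixels majority-covered by an object. A two-feature
baseline (foreground mean hue + connected-component count) reaches ≥90%
cross-validated accuracy on 300 images, so the classes are separable by
construction and convergence tests exercise the pipeline rather than luck.
What the generator does *not* emulate: stain variability, tissue texture,
nuclear chromatin structure, scanner artifacts, or any real histological
morphology — passing tests demonstrate that the pipeline learns and
localizes the structure the generator encodes, not clinical performance.

## Interpretability

`grad_cam` takes the gradient of the target class's pre-softmax logit
(avoiding softmax saturation) with respect to the post-SE feature maps of a
chosen block — by default the last residual block. Channel weights are the
spatial means of that gradient; the map is the ReLU of the weighted feature
sum, bilinearly upsampled to the input size and then max-normalized into
[0, 1] (normalizing after upsampling keeps the delivered map's maximum at
exactly 1; an all-zero map — no positive evidence — is left at zero rather
than divided). Max-normalization is used instead of min-max so maps with
only negative evidence stay at zero. Localization quality is quantified on
synthetic ground truth as the fraction of heatmap mass inside object masks.

## Known limitations

- The engine is CPU/numpy; it is sized for the package's test-scale
  protocols, not for training on the full 15,000-image lung set.
- Eval-mode batch norm depends on the post-training recalibration sweep;
  models evaluated mid-training (e.g., per-epoch validation in the manifest)
  use the cumulative statistics accumulated so far.
- The checkpoint format is a `.npz` archive of parameter arrays plus the
  architecture YAML — portable across this package's versions only.
- Augmentation (rotation/flip/brightness) is implemented for training-time
  use but disabled by default in the protocol runners; the synthetic classes
  are separable without it.
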