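# Methods

## Scope and model

`dermrestore` studies the effect of two dermoscopy artifacts — hair
strands and Gaussian noise — on lesion classification, and implements
the two restoration pipelines that remove them.  Its components are:
the image operators (blur, morphology, thresholding), fast-marching
inpainting, non-local means denoising, a procedural synthetic-data
generator that provides paired ground truth, and a frozen-backbone
classification harness that quantifies the downstream effect.

## Conventions fixed across the package

- Images are RGB, intensities in [0, 255]; `uint8` at file boundaries
  and pipeline outputs, `float64` internally.  Pixel indexing is
  0-based (row, col), row 0 at top.
- Grayscale is Rec. 601 luma (0.299 R + 0.587 G + 0.114 B), rounded —
  the RGB2GRAY convention of the mainstream image libraries whose
  operator vocabulary the pipelines mirror.
- CIELAB uses the sRGB transfer curve with D65 white (delegated to
  scikit-image), the dominant convention for consumer-camera JPEGs.
  Round-trips are within ±1 intensity level for in-gamut colors.
- "Reflect" border handling means edge-repeating symmetric padding
  (`scipy` mode `reflect`, `np.pad` mode `symmetric`).  With this
  convention a normalised blur kernel preserves the image mean exactly,
  which is asserted in the tests; mirror-without-repeat padding does
  not have that property.
- Resampling is centre-aligned bilinear interpolation without an
  antialiasing prefilter; outputs stay within the input range by
  convexity.

## Dehairing pipeline

Order of stages: Gaussian blur (3 × 3; σ derived from the kernel size
as 0.3·((k−1)·0.5 − 1) + 0.8 = 0.8 unless given), median blur (3 × 3),
grayscale, blackhat with an 11 × 11 cross structuring element, binary
threshold, inpainting.  The blur runs on the colour image before
grayscale conversion, and the *median-blurred* image is what gets
inpainted, so the default restored output is a smoothed image;
`inpaint_source="original"` transplants only the on-mask inpainted
values into the unblurred input for applications where the softening
matters.

The threshold default is 10 on the 0–255 blackhat response with a
strict `>` comparison (ties excluded).  The value is the conventional
choice for this hair-masking recipe and is exposed as a parameter and
CLI flag; no dilation of the mask is applied by default, with a
`mask_dilate` option for 1-px hair halos.

## Fast-marching inpainting

Arrival times T solve |∇T| = 1 by the classical fast-marching method:
a quadratic upwind update from frozen (KNOWN) 4-neighbours, degrading
to the 1-D solve `min + 1` when the two directional values differ by
at least one grid step; a binary heap with (T, row, col) lexicographic
tie-breaking makes the traversal deterministic.  On disc masks up to
radius 10 the field stays within 1 px of the exact Euclidean distance
transform (oracle: `scipy.ndimage.distance_transform_edt`).  An
outward pass stores negated distances on known pixels near the
boundary (saturated at ε + 2) so the level-set weight sees a
continuous field across it.

Each masked pixel is estimated per channel as the normalised weighted
sum of first-order predictions from known pixels in the Chebyshev
window of radius ε (default 1, i.e. the 8-neighbourhood): weights are
the product of a directional term |(p−q)·N(p)|/‖p−q‖ floored at 1e−6
(N is the normalised gradient of T), an inverse-square distance term
d0²/‖p−q‖² and a level-set term T0/(T0 + |T(p) − T(q)|), with
d0 = T0 = 1 px.  Image gradients use central differences over known
pixels only, one-sided at known/unknown interfaces, zero when
isolated.  Consequences asserted in tests: off-mask pixels are
bit-identical to the input, constants are reproduced exactly, linear
ramps are recovered within 2 intensity levels across 3-px masks, and
outputs never leave [0, 255].

## Non-local means

Weights are exp(−max(D − 2σ̂², 0)/h²) on the mean squared patch
difference D, normalised per pixel; σ̂ is a robust noise estimate (MAD
of the Laplacian response scaled by 1.4826/√20 — the Laplacian
annihilates locally linear structure, so ramps do not inflate it).
Defaults: 7 × 7 patches (template radius 3), 21 × 21 search window
(radius 10), h = h_color = 10.  The self-weight is the maximum of the
other weights in the window (standard stabilisation; a literal
`exp(0)` mode exists and the brute-force oracle mirrors whichever mode
is configured).  A full-image summation mode honours the literal
all-pixels sum on small images.  The colour path denoises L and each
of A, B separately after rescaling the channels to 0–255, so h = 10
keeps its 8-bit meaning on every channel; per-channel chroma denoising
was chosen over a joint 2-channel patch distance for oracle
simplicity.  The windowed implementation is verified against a
quadruple-loop oracle to 1e−6 on random fields.

## Synthetic data

The generator emulates the study's corpora at desk scale: 64 × 64
phantoms, 20 per class by default (the study's corpora have 5000
images at 224 × 224; the scaled sizes keep the full experiment within
minutes on one CPU and are stated wherever results are reported).
Each phantom is a skin-toned background (default (224, 172, 140)) with
smooth low-frequency texture (amplitude 6) and a soft-edged ellipse
whose colour and size family is set by the 7-way class label; the
palettes are mutually distant in RGB, so a nearest-centroid classifier
on mean lesion colour exceeds 95% on clean phantoms — the signal whose
degradation the harness measures.

Hair strands are quadratic Bézier curves with per-hair thickness
(1–4 px), dark intensity (10–90) and curvature jitter; corpus
generation draws 15–25 strands per image (heavy occlusion).  Strand
pixels replace the image values outright (hard replacement; how the
original corpus blended donor hairs is not recorded, and the choice is
flagged in each pair's provenance).  Noise is i.i.d. zero-mean
Gaussian per pixel and channel, applied in float and clipped to
[0, 255]; per-image σ is drawn uniformly from [1, 30] in corpus
generation, and the calibration tests use mid-grey constants so
clipping cannot bias the measured σ.  Every generator is a pure
function of its seed; regeneration is byte-identical.

What the phantoms do **not** model: real lesion morphology (asymmetry,
border irregularity, pigment networks), rulers, ink marks, bubbles,
illumination gradients, or JPEG artifacts.  Passing tests therefore
demonstrate that the pipelines remove what they claim to remove and
that occlusion measurably hurts a classifier with colour/texture
features — not that the absolute accuracies transfer to clinical data.

## Classification harness

The transfer scheme keeps the feature extractor frozen and trains only
a new fully connected 7-class softmax head — so the harness needs no
backpropagation through the backbone, and any callable from image
batches to fixed-length features satisfies the `backbone` contract.
The shipped reference backbone is a small 3-conv-block CNN (16/32/64
channels, 3 × 3 kernels with fixed seeded He-initialised weights,
ReLU, 2 × 2 average pooling) whose feature vector concatenates the
global average pool of each block with the global standard deviation
of the last block, capturing both colour and texture statistics.

The head is zero-initialised (the softmax starts exactly uniform and
the trajectory depends only on the seeded batch order) and optimised
with Adam at lr 1e-3, β₁ = 0.9, β₂ = 0.999, ε = 1e−8, batch size 32,
25 epochs, categorical cross-entropy on features standardised with
training-set statistics.  The 80/20 split is stratified by class and
seed-deterministic; the 20% held-out set is reported as "validation"
(VAcc/VLoss) to match the study's naming.  No augmentation, schedule
or early stopping.  Divergence (non-finite loss) aborts with a
diagnostic.

The five-variant experiment (clean, hairy, dehaired, noisy, denoised)
trains one model per variant per seed replicate from identical split
and initialisation seeds, and summarises, at the final epoch, in how
many replicates each expected direction holds (occluded never beats
clean; restored never loses to occluded; ties count as holding, since
mild corruption can be fully absorbed by the pooled features).

## Numerical choices and degenerate inputs

- Thresholds are strict (`>`); argmax ties break to the lowest index.
- An all-true inpainting mask is an error (nothing to propagate from);
  an empty mask returns the input unchanged.
- Classes with a single sample put it in the training split; an empty
  validation split disables validation metrics rather than emitting
  NaNs from empty means.
- Probability rows are clipped to [1e−12, 1] before logarithms.
- All randomness flows through `numpy.random.default_rng` seeds;
  derived seeds stay below 2³¹.

## Known limitations

- The blackhat detector misses hairs wider than the structuring
  element's arm and lightly flags lesion-border pixels (the Dice of
  the detected mask against procedural truth is ~0.6–0.8, with the
  surplus being a 1-px halo that is harmless to inpaint).
- The default restored image inherits the 3 × 3 blurs of the detection
  chain.
- NL-means cost grows with the square of the search radius; the
  full-image mode is only practical for small fields.
- The harness's frozen random-feature backbone is a stand-in for
  large pretrained networks: directions replicate, absolute accuracies
  do not transfer.
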