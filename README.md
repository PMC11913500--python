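# dermrestore

Dermoscopic images of skin lesions are routinely obscured by two
artifacts that degrade automated diagnosis: dark curvilinear **hair
strands** that occlude the lesion, and acquisition **noise**.
`dermrestore` implements both restoration pipelines end to end —

- **Hair removal**: Gaussian blur → median blur → grayscale → *blackhat*
  transform with an 11 × 11 cross-shaped structuring element → binary
  threshold → **fast-marching inpainting** of the detected strands.
  The blackhat transform, `close(I, B) − I`, responds exactly to dark
  structures thinner than the structuring element; the inpainting fills
  each masked pixel *p*, in increasing arrival time *T* of the eikonal
  front (|∇T| = 1, T = 0 on the mask boundary), with the normalised
  first-order estimate

  I(p) = Σ_q w(p,q) [ I(q) + ∇I(q)·(p−q) ] / Σ_q w(p,q),

  where q ranges over the known pixels of the window B_ε(p) and
  w = dir·dst·lev combines direction, inverse-square distance, and
  level-set proximity.

- **Noise removal**: non-local means denoising, NL[v](i) = Σ_j w(i,j) v(j)
  with patch-similarity weights, applied in CIELAB with filter strength
  h = 10 on the luminance channel and on each chroma channel.

- **Synthetic corpora**: procedural lesion phantoms (7 colour/size
  class families on a textured skin background), Bézier hair-strand
  occlusion with ground-truth masks, and zero-mean Gaussian noise with
  σ ∈ [1, 30] — so every stage is testable against known truth without
  downloading any data.

- **Classification harness**: a frozen convolutional feature extractor
  plus a trainable 7-class fully connected softmax head (Adam, lr 1e-3,
  batch 32, 25 epochs, stratified 80/20 split), reporting training and
  validation accuracy/loss at epochs 10, 15 and 25 — used to measure
  how much artifact removal buys downstream.

The estimators follow scikit-learn conventions (`HairRemover`,
`NLMeansDenoiser`, `LesionHeadClassifier` with `fit`/`transform`/
`predict`, `get_params`, fitted attributes ending in `_`) and compose
with `sklearn.pipeline.Pipeline`.

## Worked example

```python
import numpy as np
from dermrestore import (
    LesionPhantomParams, generate_lesion_phantom,
    HairParams, draw_procedural_hairs, dehair_inpainted,
)

clean, label = generate_lesion_phantom(LesionPhantomParams(seed=3, class_id=2))
pair = draw_procedural_hairs(clean, HairParams(n_hairs=10, seed=1))
restored, mask = dehair_inpainted(pair.corrupted)

ref = clean.astype(float)
print("hair pixels detected:", int(mask.sum()))
print("MAE hairy   :", round(np.abs(pair.corrupted - ref).mean(), 2))
print("MAE restored:", round(np.abs(restored - ref).mean(), 2))
```

Output:

```
hair pixels detected: 1261
MAE hairy   : 22.58
MAE restored: 6.53
```

The detector flags 1261 pixels (the 849 true hair pixels plus a thin
halo), and inpainting cuts the mean absolute error against the clean
phantom from 22.6 to 6.5 intensity levels.  The same comparison for
non-local means on σ = 20 noise drops the MAE from 15.8 to 3.0.

A command-line interface mirrors the library:

```sh
dermrestore simulate corpus --corruption hair --n-per-class 20 --seed 0
dermrestore dehair corpus/corrupted/0000.png restored.png --mask-out mask.png
dermrestore denoise noisy.png denoised.png --h 10 --h-color 10
dermrestore process corpus/manifest.csv --mode dehair --out-dir restored/
dermrestore experiment --n-per-class 20 --sigma 20
```

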