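# skinspace

Derivation of low-dimensional **hybrid color spaces** for pixel-wise skin
detection, and the full training/evaluation protocol around them.

The pipeline:

1. **Color space transforms** — 17 spaces (HSI, HSV, LAB, LUV, nRGB, RGB,
   TSL, XYZ, YCbCr, YCgCr, YES, YIQ, YPbPr, YUV, i1i2i3, RIQ, YQCr) turn
   each RGB pixel into a 32-component feature vector (the default component
   registry).
2. **Feature selection** — a genetic algorithm with a cross-validated
   random-forest F-score fitness (population 25, per-bit mutation 0.035,
   uniform crossover 0.55, estimation-of-distribution reproduction over the
   elite set, elitism) searches component subsets.
3. **Feature reduction** — explicit covariance PCA (mean centering, n−1
   covariance, symmetric eigendecomposition) projects the selected subset to
   a 3-D `HybridSpace`.
4. **SKN** — the fixed published 3-D hybrid space is built in
   (`rgb_to_skn` / `rgb_image_to_skn`), expressed directly over
   (g = G/(R+G+B), R, G, B).
5. **Classification & evaluation** — random forest (15 trees), kernel-density
   naive Bayes, degree-3 polynomial SVM, and a 5-layer MLP produce skin
   posteriors; evaluation covers pixel confusion counts, TPR/FPR/precision/F,
   image-averaged metrics, 50-threshold ROC with trapezoidal AUC, and
   TP/FN/FP/TN error overlays.

A seeded synthetic-scene generator (elliptical skin-chroma regions over
heterogeneous backgrounds, exact masks) provides reproducible fixtures, since
the original benchmark image collections are external.

## CLI

```bash
# synthesize a dataset
skinspace synth --n 30 --seed 1 --out data/

# tag a train/test split (75/25)
skinspace split --manifest data/manifest.csv --seed 1 --out data/split.csv

# transform an image into any space (per-component float planes)
skinspace transform --space skn --in data/scene_0000.png --out planes/

# derive a hybrid space: GA selection, then PCA reduction
skinspace derive select --manifest data/split.csv --seed 1 --out subset.json
skinspace derive reduce --manifest data/split.csv --subset subset.json --k 3 --out space.json

# train and evaluate a pixel classifier
skinspace train --manifest data/split.csv --space skn --clf random_forest --out model.bin
skinspace evaluate --manifest data/split.csv --model model.bin --out report.json \
    --roc roc.csv --overlays overlays/

# or the whole pipeline in one go
skinspace run --seed 1 --out runs/demo
```

`skinspace run` executes synth → (optionally) derive → train → evaluate,
persisting every stage artifact under the output directory and resuming from
any stage whose artifact already exists. All randomness flows from the single
master seed through named substreams.

## Conventions

- RGB channels are scaled to [0, 1]; 8-bit images are divided by 255 at load.
- Chromaticities of a black pixel are (1/3, 1/3, 1/3); hue of an achromatic
  pixel is 0.
- Y-family spaces use BT.601 luma with full-range chroma centered at 0.5;
  XYZ/LAB/LUV use sRGB primaries with D65 white applied linearly (no gamma
  step). All dialects are documented in `skinspace/colorspaces.py`.
- Masks are single-channel PNGs with 255 = skin, 0 = non-skin; any other
  value is rejected.
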