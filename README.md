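# lesionseg

Encoder–decoder segmentation of skin lesions in dermoscopy-style images,
built around depthwise-separable convolution (DSC) blocks, multi-dilated
convolution (MDC) blocks and swish activations, with pixel-overlap
evaluation metrics and a fully synthetic data path so everything runs
offline.

The package is pure scientific Python: the network runs on a compact
NumPy reverse-mode autodiff backend (`lesionseg.nn`) whose convolutions
are im2col/GEMM-based and whose gradients are covered by finite-difference
tests. Deliberately naive nested-loop convolution references
(`lesionseg.conv_math`) act as independent oracles for those layers.

## Layout

| module | contents |
| --- | --- |
| `conv_math` | parameter/cost formulas for standard vs separable convolutions; nested-loop depthwise/pointwise/dilated references |
| `activations` | swish, its closed-form derivative, He-normal and Glorot-uniform initializers |
| `preprocessing` | Gaussian smoothing (optional), grayscale morphological closing, unsharp-mask sharpening |
| `augmentation` | deterministic paired image/mask registry: 3 rotations + 12 pixel crops (= 15 variants), flip/shift behind flags |
| `architecture` | the segmentation network: 4-stage encoder of parallel {1×1 conv + 3×3 max-pool, DSC, MDC} branches, bottleneck at 1/16 resolution, transposed-convolution decoder with skip connections, 1×1 conv + sigmoid head |
| `metrics` | confusion counting; accuracy/Dice/sensitivity/Jaccard, the published specificity formula (TP/(TP+FP)) plus the textbook one; none/micro/macro averaging |
| `training_pipeline` | seeded Adam training loop (lr 0.001, BCE default loss), prediction, evaluation, contour overlays, npz checkpoints |
| `synthetic_data` | seeded generator of lesion scenes: irregular dark elliptical blobs on lighter skin, optional hair strokes, bubbles and illumination gradients, exact masks |
| `cli_io` | PNG/JPEG readers/writers, `images/`+`masks/` folder pairing, YAML run configs |
| `nn` | the autodiff backend (tensors, conv/pool/batch-norm/dropout layers, losses, Adam) |

## CLI

```bash
lesionseg synth --n 16 --size 64 --seed 1 --out data/       # synthetic scenes
lesionseg preprocess --in data/images --out data/clean      # closing + sharpening
lesionseg augment --in data --out data_aug                  # 15 variants per pair
lesionseg train --config cfg.yaml --out runs/               # seeded training
lesionseg predict --weights runs/model.npz --in data/images --out preds/
lesionseg evaluate --pred preds --truth data/masks --mode micro
lesionseg summary --config cfg.yaml                         # layer shapes, params
lesionseg cost -k 3 -m 16 -n 32                             # conv cost table
```

A run config is a sectioned YAML document; unknown keys are rejected:

```yaml
model: {input_size: 64, filter_ladder: [8, 16, 32, 64]}
train: {epochs: 12, batch_size: 8, seed: 1}
scene: {size: 64, hair_count: 2}
```

## Notes

- Crop amounts in the augmentation registry are in **pixels** (45/60/90);
  cropped results are resized back to the input shape.
- The published specificity formula is implemented verbatim as
  `metrics.specificity`; the textbook TN/(TN+FP) is available as
  `metrics.corrected_specificity`, and reports label which was used.
- Regular and dilated convolutions are He-normal initialized and
  DSC weights Glorot-initialized by default; `init_scheme: glorot`
  forces Glorot everywhere.
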