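# cayolo

A context-aware attention detector for clue-cell screening in
fluorescence microscopy images, implemented end-to-end in NumPy (no deep
learning framework required).

The package provides:

- **`cayolo.attention`** — the two feature-enhancement blocks: a
  context-aware residual module (1×1 conv → per-channel spatial softmax →
  conv–LayerNorm–conv–sigmoid gating) and a shuffle global attention
  mechanism (per-location channel attention followed by 7×7-conv spatial
  attention whose map is channel-shuffled before gating).
- **`cayolo.losses`** — BCE + focal classification loss (inverse-frequency
  per-class α, γ = 1.5 default) and CIoU + distribution-focal box loss,
  composed with exact additivity into a per-batch breakdown; includes the
  full detector criterion with a task-aligned assigner.
- **`cayolo.model`** — a single-stage anchor-free detector (backbone → PAN
  neck → decoupled heads, strides 8/16/32) with the attention blocks
  insertable at named neck nodes (`1_layer_P5`, `3_layers_P345`, `none`),
  plus decoding, NMS and prediction.
- **`cayolo.nn`** — a compact reverse-mode autodiff engine on NumPy
  (conv2d via im2col, max-pool, upsampling, BN/LN, Adam).
- **`cayolo.synthdata`** — a synthetic scene generator: dark fluorescence
  background, bright elliptical cells of two classes distinguishable only
  by edge granularity and surface punctae, with controllable imbalance and
  YOLO-format annotations grouped into synthetic patients.
- **`cayolo.train`** — patient-level splitting, geometric + compound
  (mosaic/MixUp/copy-paste) augmentation, random hyper-parameter search
  over the published grid, and Adam training with early stopping on
  validation F1.
- **`cayolo.evaluation`** — image-level screening metrics (SEN/SPE/ACC via
  the strict >20% clue-area rule) and object-level precision/recall/F1,
  plus ROC/PR curves.
- **`cayolo.stats`** — paired model comparison: McNemar's test
  (continuity-corrected and exact) and a percentile bootstrap CI for the
  accuracy difference.

## CLI

```bash
cayolo generate --n-images 200 --out data/ --seed 0      # synthetic dataset
cayolo fit --data data/ --out weights.npz --epochs 20    # train (alias: train)
cayolo search --data data/ --log trials.csv              # random HP search
cayolo predict --weights weights.npz --image img.png
cayolo eval --weights weights.npz --data data/
cayolo compare --preds-a a.json --preds-b b.json --labels gt.json
cayolo export --weights weights.npz --out manifest.json
```

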