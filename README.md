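# lesionseg

Binary semantic segmentation of gastrointestinal lesions — bleeding spots
in wireless-capsule-endoscopy frames and polyps in colonoscopy images — for
researchers who need a compact, fully testable implementation of the
attention residual U-Net family without a GPU or external datasets.

## The model

Three encoder–decoder architectures are built from one configurable
skeleton: plain **U-Net**, **AttU-Net** (attention gates on skip
connections) and **AttResU-Net** (attention gates + residual encoder
blocks). Residual blocks compute

    y = F(x) + x,

where `F` is two [3×3 conv → batch norm → ReLU] stages (a 1×1 projection
replaces the identity when channel widths differ). The attention gate forms
per-location coefficients α ∈ [0, 1] from the encoder skip `x_l` and the
gating signal `g` one level deeper — strided 1×1 convolution on `x_l`, 1×1
convolution on `g`, elementwise sum, ReLU, 1×1 convolution to one channel,
sigmoid — then upsamples α bilinearly and rescales the skip as α ⊙ x_l, so
the decoder concentrates on lesion-relevant locations. Predictions are
evaluated pixelwise by accuracy, the Dice coefficient
2|A∩B|/(|A|+|B|) and the Jaccard index |A∩B|/|A∪B| (related by
D = 2J/(1+J)).

The network layers, reverse-mode autodiff and Adam optimizer are
implemented in NumPy inside the package (`lesionseg.nn`); every backward
pass is verified against finite differences in the test suite. A synthetic
scene generator (`lesionseg.synthetic`) produces endoscopy-like images —
red-dominant irregular blobs on a textured mucosal background — with exact
ground-truth masks, so the entire pipeline runs without downloading
anything.

## Worked example

```python
import lesionseg as ls

# 200 synthetic 64x64 scenes, split 60/20/20
spec = ls.SyntheticSceneSpec(size=(64, 64), n_lesions=1,
                             radius_range=(5.0, 14.0), seed=7)
data = ls.generate_dataset(spec, 200)
train, val, test = ls.split_dataset(data, ls.DatasetSplit(seed=7))

cfg = ls.ModelConfig(architecture="attresunet", input_size=(64, 64),
                     depth=3, base_filters=8)
model = ls.build_model(cfg, seed=7)
tcfg = ls.TrainConfig(batch_size=40, epochs=15, seed=7,
                      augmentation=ls.AugmentationPolicy(seed=7))
model, history = ls.train(model, train, val, tcfg)
report = ls.evaluate_dataset(model, test)
print(f"val dice {history.records[-1].val_dice:.4f}")
print(f"test dice {report.dice:.4f}  jaccard {report.jaccard:.4f}  "
      f"accuracy {report.accuracy:.4f}")
```

Output (a few minutes on one CPU core):

```
val dice 0.9399
test dice 0.9317  jaccard 0.8729  accuracy 0.9921
```

Validation Dice 0.94 means the predicted lesion masks overlap the ground
truth almost completely on held-out scenes; an untrained network scores
about 0.2 on the same data, so essentially all of that overlap is learned.

The same pipeline is available from the shell:

```sh
lesionseg synth --out-dir data --n 200 --size 64 --seed 7
lesionseg train --config config.yaml --data-dir data --out-dir run
lesionseg evaluate --checkpoint run/model.npz --data-dir data --out-dir eval
lesionseg predict --checkpoint run/model.npz --image data/images/scene-00000.png --out mask.png
```

Every command writes a `manifest.json` (resolved config, seed, package
version, paths) sufficient to re-run it.

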