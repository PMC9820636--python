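# colonyqc

Automated quality control of human pluripotent stem-cell (hPSC) colony
images from phase-contrast microscopy.

hPSC cultures must be monitored daily: colonies drifting into spontaneous
differentiation have to be removed before passaging. An experienced
operator reads this from morphology alone — a **good** colony is flat with
a prominent, well-defined edge and tightly packed, square-shaped cells,
while a **bad** colony shows loosely packed, elongated cells with
phase-bright gaps between them and a spiky edge. `colonyqc` implements an
end-to-end deep-learning substitute for that expert call, plus the tooling
needed to study it at desk scale:

* a **synthetic colony generator** that renders pseudo-phase-contrast
  colonies with ground-truth labels and a tunable class `separation`
  (0 = classes identical, 1 = full morphological contrast), so the whole
  pipeline runs and is testable without any external data;
* the four **preprocessing operators** (grayscale `Y = 0.299R + 0.587G +
  0.114B`, min–max normalization, binarization, global histogram
  equalization) and the resize to the square network input;
* **augmentation**: random cropping and the 8-element dihedral family
  (rotations by multiples of 90°, flips, transpositions);
* five **VGG-family classifiers** (VGG13, VGG13-FirstPool4, VGG12,
  VGG12-FirstPool4, Res+VGG13) with a single sigmoid output, built on a
  compact numpy CNN engine (im2col convolutions, Adam) so no deep-learning
  framework is required;
* **training** by minimizing binary cross-entropy
  `L = -(1/N) Σᵢ [yᵢ log ŷᵢ + (1-yᵢ) log(1-ŷᵢ)]` with y = 1 for good,
  on a stratified 4:1 train:validation split;
* **evaluation**: confusion matrix, accuracy, precision, recall, F1 and
  rank-based AUC, reported under both positive-class conventions;
* the **characteristic-spatial-scale experiment**: recursively quarter
  every image, retrain per level, and find the crop size (in µm) at which
  the phenotype is easiest to classify;
* an **ablation harness** over architectures × preprocessing ×
  augmentation, and a `colonyqc` command-line interface.

## Worked example

Train a reduced-width VGG12 (input 64 px, channel widths ×1/8) on 200
synthetic colonies at full class separation:

```python
from colonyqc import ColonyClassifier, GeneratorParams, generate_dataset
from colonyqc.preprocess import PreprocessSpec
from colonyqc.train import TrainConfig

ds = generate_dataset(100, 100, GeneratorParams(separation=1.0), seed=11)
clf = ColonyClassifier(
    ds, architecture="VGG12",
    preprocess=PreprocessSpec(method="none", target_side_px=64),
    config=TrainConfig(epochs=20, seed=1, early_stop_patience=5),
    width_multiplier=0.125)
res = clf.fit()
print(res.summary())
```

```
                 Colony phenotype classifier
==============================================================
Architecture:      VGG12 (input 64px, width x0.125)
Parameters:        118,649
Preprocessing:     none
Augmentation:      crop=False, rotation=False
Train/validation:  160/40 (ratio 4:1)
Epochs run:        20 (best epoch 19)
--------------------------------------------------------------
Validation confusion matrix (rows = actual):
                 pred good   pred bad
  actual good          20          0
  actual bad            0         20
--------------------------------------------------------------
metric         good-positive    bad-positive
accuracy              1.0000          1.0000
precision             1.0000          1.0000
recall                1.0000          1.0000
f1                    1.0000          1.0000
auc                   1.0000          1.0000
==============================================================
```

With `separation=1.0` the two synthetic phenotypes differ strongly in
packing, gap brightness, cell elongation and edge spikiness, and the
classifier separates the 40 validation colonies perfectly; at
`separation=0.0` the classes are statistically identical and validation
accuracy stays at chance. The same objects drive the scale experiment:

```python
from colonyqc.scale import scale_scan
from colonyqc.synth import generate_scale_probe_dataset

ds = generate_scale_probe_dataset(40, 40, seed=5)   # signal only below whole-image scale
table = scale_scan(ds, max_k=1, model_name="VGG12",
                   train_cfg=TrainConfig(epochs=6, early_stop_patience=None),
                   preprocess=PreprocessSpec(method="none", target_side_px=64),
                   seeds=(0, 1, 2), width_multiplier=0.0625)
print(table.groupby("level")[["crop_um", "accuracy"]].mean())
```

```
        crop_um  accuracy
level
0         290.0  0.479167
1         145.0  0.916667
```

Whole images (290 µm, downsampled to the 64 px input) are classified at
chance, while quarter crops (145 µm, native resolution) are classified
almost perfectly — the constructed fine-scale signal is only visible below
whole-image scale, so the argmax level is k ≥ 1.

The same workflows are available from the shell, e.g.:

```bash
colonyqc synth --n-good 100 --n-bad 100 --separation 1.0 --seed 1 --out data/
colonyqc models list
colonyqc train --config run.yaml --out runs/baseline
colonyqc scale-scan --config run.yaml --max-k 2 --seeds 0,1,2 --report scan.json
```

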