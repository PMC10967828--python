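# octseg

Hybrid attention U-Net for segmenting retinal layers in optical coherence
tomography (OCT) B-scans.

OCT produces cross-sectional images of the retina in which ophthalmologists
delineate ordered tissue regions — above the internal limiting membrane
(ILM), ILM to IPL/INL, IPL/INL to the retinal pigment epithelium (RPE), the
RPE–Bruch's membrane complex, and the choroid under BM.  Manual delineation
is slow and subjective; `octseg` automates it with a five-level
encoder/decoder network and provides everything around the model: a
synthetic layered-phantom generator (so the pipeline runs with no dataset
download), preprocessing, a nine-transform augmentation set, the training
protocol, and a full agreement-statistics evaluation suite.

## The model

A standard U-Net (five encoder stages, one base stage, five decoder stages,
channels doubling from a configurable base) with two modifications:

* **Residual skip connections.**  At each encoder stage the feature map is
  max-pooled with 2×2 windows.  The pooled maxima continue downward; the
  skip path carries the *residual* map — the input with the argmax pixel of
  every window set to zero — so the decoder receives exactly the
  information the deeper stages did not already process:

  ```
  pooled[i,j]  = max of window (i,j)
  residual     = x  with x[argmax of each window] := 0
  ```

* **Hybrid attention on the skips.**  The two shallowest skips pass an
  *edge attention* (EA) gate: the skip features are enhanced with their
  edge response `F = x ∗ K_t + x ∗ K_l` (the transverse/longitudinal Sobel
  derivative pair used inside the Canny detector), fused by addition, and
  gated by additive-attention coefficients
  `α = σ(ψ(ReLU(W_s·enhanced + W_g·gate))) ∈ [0, 1]`.
  The three deepest skips pass a *spatial attention* (SA) gate built from
  channel-wise max and average pooling: the two pooled maps are stacked,
  passed through a sigmoid, averaged into one map in (0, 1), and multiplied
  into the features.  Shallow features are edge-dominated and deep features
  shape-dominated, which motivates the 2 EA + 3 SA split.

Training follows a fixed protocol: composite loss `α·CE + β·Dice + γ·EdgeCE`
with weights (1, 0, 1), where EdgeCE is cross-entropy restricted to a 2 px
band around label boundaries; AdaBound optimizer at initial learning rate
0.001; ×0.1 learning-rate reduction after 5 stagnant validation epochs;
early stopping after 10; checkpoint restoration every 100 epochs; at most
300 epochs; batch size 4; 6-fold cross-validation.  Evaluation reports
per-class precision/recall/F1/Dice, boundary IoU, and the chance-corrected
agreement statistics (Cohen's kappa, Bennett's S, Bangdiwala's B, adjusted
Rand index, Hamming loss, chi-squared degrees of freedom) with
strength-of-agreement labels.

Because no deep-learning framework is a dependency, the network runs on a
small reverse-mode autodiff engine built on numpy (`octseg.nn`), with
convolutions as im2col + BLAS matmul.  All layer gradients are verified
against central differences in the test suite.

## Worked example

```python
import numpy as np
from octseg import (SyntheticConfig, ModelConfig, TrainConfig,
                    generate_dataset, build_model, train_model, evaluate_model)

pairs, _ = generate_dataset(SyntheticConfig(height=128, width=64, seed=7), 200)
model = build_model(ModelConfig(depth=5, base_channels=8,
                                input_shape=(128, 64), seed=7))
model, history = train_model(model, pairs, TrainConfig(max_epochs=6, seed=7))
print(f"final held-out mean Dice {history.val_dice[-1]:.4f}")
```

```
final held-out mean Dice 0.9853
```

Six epochs on 200 synthetic phantoms take the held-out mean Dice (averaged
over the five regions) to ≈0.985: the network has learned the layered
geometry, with the remaining errors concentrated in the 2 px boundary
bands.  `evaluate_model(model, val_pairs).summary()` then prints the
per-class table and the agreement statistics.

The same pipeline is scriptable from the shell:

```sh
octseg synth --n 50 --height 128 --width 64 --seed 1 --out data/
octseg augment --in data/ --out augmented/ --seed 1
octseg train --config cfg.yaml --data augmented/ --out run/
octseg evaluate --model run/model.npz --arch run/architecture.json \
                --data data/ --out report.json
```

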