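# fractalseg

Fractal U-Net architectures, surface-distance metrics and a synthetic
phantom pipeline for **cervical spinal-cord MRI segmentation**.

Multiple-sclerosis lesions in the cervical spinal cord are small,
irregular, and diagnostic: their burden tracks disease progression.
Segmenting them — and the cord cross-sectional area (CSA) that contains
them — from axial T2-weighted MRI is a hard two-target problem for
encoder–decoder networks. This package implements a family of four
architectures built around the *fractal expansion rule*

    f_1 = conv,   f_{C+1} = join(conv, f_C ∘ f_C),   join = elementwise mean,

which runs convolutional paths of depth 1 … 2^(C−1) in parallel inside
a single block (2^C − 1 conv units for order C), giving multi-scale
receptive fields at fixed topology:

| model | design | calibrated size |
|---|---|---|
| `unet` | baseline U-Net (double conv per stage, identity skips) | 31.4 M |
| `fractalspinet` | fractal blocks replace every conv stage | 109.9 M |
| `att_fractalspinet` | + additive attention gates on the skips | 115.8 M |
| `con_fractalunet` | U-Net with fractal blocks *inside the skip connections* | 53.3 M |

Sizes are trainable-parameter totals of the released default
configurations, pinned to the published capacity figures by a
deterministic bottleneck-width calibration (`calibrate_capacity`).

The package is self-contained: models train on an internal NumPy
autodiff engine (no deep-learning framework required), and a synthetic
T2-w cord **phantom generator** supplies paired images with nested
CSA/lesion ground-truth masks, so the whole pipeline runs end to end
with no data download. The evaluation suite implements the standard
eight metrics — DSC, VOE, RVD (%), ASD, HD, HD95 (mm, spacing-aware),
recall and precision — with explicit empty-mask conventions, plus a
paired Wilcoxon signed-rank comparison between models.

## Worked example

Train the skip-fractal model on 128 synthetic 64×64 cord slices and
score it on 32 held-out slices (about 2–3 minutes on one CPU core):

```python
import numpy as np
from fractalseg import FractalSegmenter
from fractalseg.phantom import PhantomParams, generate_dataset
from fractalseg.pipeline import evaluate

params = PhantomParams(image_size=(64, 64), seed=11, center_jitter_px=4)
pairs, _ = generate_dataset(params, n=160)
X = np.stack([p.image.pixels for p in pairs])
y = np.stack([p.csa_mask.grid for p in pairs])

model = FractalSegmenter(architecture="con_fractalunet", depth=3,
                         stage_widths=(8, 16, 32, 64), fractal_order=2,
                         epochs=30, seed=0)
model.fit(X[:128], y[:128])
print(f"trainable parameters: {model.n_parameters_:,}")
print(f"mean test Dice: {100 * model.score(X[128:], y[128:]):.2f}%")

row, reports, frame = evaluate(model.model_, pairs[128:], target="csa")
print({k: round(v, 2) for k, v in row.items()})
```

prints

```
trainable parameters: 158,177
mean test Dice: 98.01%
{'DSC': 98.01, 'VOE': 3.86, 'RVD': 3.72, 'ASD': 0.09, 'HD95': 0.67,
 'REC': 99.81, 'PRE': 96.33, 'HD': 0.88}
```

Read: the width-reduced skip-fractal network recovers the cord with
~98% volume overlap; boundaries sit within a tenth of a millimetre on
average (ASD) and within ~0.7 mm at the 95th percentile of worst-case
boundary error (HD95). `FractalSegmenter` is a scikit-learn estimator
(`get_params`/`set_params`/`clone` all work), and the lower-level
builders (`fractalseg.models.build_*`), metric functions
(`fractalseg.metrics`) and pipeline (`fractalseg.pipeline`) are usable
directly.

## Command line

```bash
fractalseg phantom --n 231 --seed 7 --out data/           # synthetic dataset
fractalseg prep --in data --out prepped --target 1080 --seed 0 [--split-first]
fractalseg train --arch con_fractalunet --data prepped --seed 0
fractalseg eval  --ckpt runs/con_fractalunet_csa_seed0/checkpoint.npz --data prepped
fractalseg metrics --pred preds/ --gt gts/ --out report.csv
fractalseg build --arch unet --print-summary                # layer table + count
fractalseg compare --scores-a a.csv --scores-b b.csv        # Wilcoxon test
```

The default preparation pipeline reproduces the published ordering
(augment 231 → 1080, then split 864/216); `--split-first` switches to
the leakage-free variant. See `docs/methods.md` for the model and
metric definitions, phantom realism limits, and the full-scale training
recipe for the original clinical dataset (not asserted by the tests).

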