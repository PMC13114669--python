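# busseg

Triple-branch breast-ultrasound tumor segmentation with adaptive
feature fusion, a boundary-aware composite loss, and a quantitative
explainability layer — implemented, trained and validated end to end on
synthetic speckle phantoms, with no GPU or external dataset required.

## Who this is for

Researchers working on lesion segmentation in B-mode breast ultrasound
who want a fully inspectable reference implementation of a hybrid
CNN / state-space (Mamba-style) / self-attention encoder: every
component — the selective-scan recurrence, the fusion softmax, the
boundary-band loss, the metric battery, and the attribution methods —
is plain numpy/scipy code with tests against independent oracles.

## The model

A CNN-anchored hierarchical parallel encoder: a residual CNN extracts
features at four levels; at each level the CNN map is refined in
parallel by a visual state-space block (selective S6 scan over four
spatial orders, zero-order-hold discretization Ā = exp(ΔA),
B̄ = (ΔA)⁻¹(exp(ΔA) − I)ΔB) and a pre-norm multi-head self-attention
block. An Adaptive Feature Fusion Module combines the three maps with
per-sample softmax weights,

    F_fused = w_cnn·F_cnn + w_mamba·F_mamba + w_trans·F_trans,
    w = softmax(a),  a = MLP(GAP(conv1x1([F_cnn; F_mamba; F_trans]))),

and a U-Net++-style dense nested decoder produces the logit map.
Training minimizes

    L = L_BCE_weighted + L_Dice + L_boundary,

where the BCE weights are 3.0 on a morphological boundary band
(7×7 dilation minus erosion of the ground-truth mask) and 1.0 inside,
and L_boundary is the BCE restricted to the band. Nine ablation
variants (branch removals, fusion alternatives, plain decoder, plain
BCE+Dice loss) are built by a variant factory. See `docs/methods.md`
for the full specification of every component.

## Worked example

```python
import numpy as np
from busseg import NeuralSegmenter, PhantomSpec, MINIATURE
from busseg.phantom import load_samples
from busseg.training import MINIATURE_TRAIN

samples = load_samples(PhantomSpec(image_size=64, lesion_count=1, seed=7), 48)
X = np.stack([s.image for s in samples])
y = np.stack([s.mask for s in samples])

seg = NeuralSegmenter(model_config=MINIATURE, train_config=MINIATURE_TRAIN, seed=1)
seg.fit(X[:40], y[:40])
print(f"parameters: {seg.n_parameters_}")
print(f"best epoch: {seg.best_epoch_}")
print(f"held-out mean DSC: {seg.score(X[40:], y[40:]):.3f}")
```

prints (exact DSC depends on the seed; this run):

```
parameters: 304181
best epoch: 7
held-out mean DSC: 0.902
```

i.e. a ~0.3 M-parameter miniature of the architecture reaches a Dice
overlap of ~0.90 on unseen phantoms after a few CPU minutes. The same
machinery scales to the reference configuration
(channels 64–512, ~35 M parameters) via `ModelConfig()`.

The command line covers the full pipeline on image folders + fold
manifests (CSV `id,image_path,mask_path,fold`):

```bash
busseg phantom --out data --n 160 --k-folds 2 --image-size 64 --seed 1
busseg cv      --manifest data/manifest.csv --config cfg.yaml --out runs/cv
busseg ablate  --manifest data/manifest.csv --variants full_affm,cnn_only --out runs/abl
busseg xai     --checkpoint runs/cv/fold0.npz --image data/images/phantom_1_00000.png \
               --method integrated_gradients --out runs/xai
busseg xai-quant --checkpoint runs/cv/fold0.npz --manifest data/manifest.csv --fold 0 \
               --report runs/xai_quant.json
```

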