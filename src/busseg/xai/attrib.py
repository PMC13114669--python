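"""Attribution, attention and uncertainty explanations for the
segmentation network.

Classification-style attribution methods need a scalar target; for dense
prediction this package uses the sum of output logits over the predicted
foreground (all pixels when the prediction is empty), with the predicted
mask frozen while the input is perturbed so the target is a smooth
function of the input.  Methods:

* Grad-CAM++ — gradient-weighted channel importance at any recorded
  layer (branch features at each level, fused maps, decoder nodes);
* Score-CAM — gradient-free channel scoring by masked-input forward
  passes;
* Eigen-CAM — first singular component of the (pixels x channels)
  activation matrix;
* Integrated Gradients — midpoint Riemann path integral from a baseline;
* Attention Rollout — cross-level accumulation of self-attention;
* kernel SHAP / LIME over intensity superpixels;
* Monte-Carlo dropout uncertainty (per-pixel SD over stochastic passes);
* branch deactivation analysis and fusion-weight profiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .. import metrics as met
from ..network import AFFM, SegModel
from ..nn import layers as nn
from ..nn.tensor import Tensor, upsample_bilinear


@dataclass
class AttributionMap:
    values: np.ndarray  # (H, W)
    method: str
    layer: str = ""
    signed: bool = False
    normalized: bool = True
    all_zero: bool = False


@dataclass
class UncertaintyMap:
    values: np.ndarray  # (H, W) per-pixel SD of sigmoid probabilities
    passes: int


def _norm_map(v: np.ndarray) -> tuple[np.ndarray, bool]:
    m = v.max()
    if m <= 0:
        return np.zeros_like(v), True
    return v / m, False


def _upsample_np(v: np.ndarray, size: int) -> np.ndarray:
    t = Tensor(v[None, None].astype(np.float64))
    return upsample_bilinear(t, size, size).data[0, 0]


def seg_target_scalar(logits: Tensor, pred_mask: np.ndarray) -> Tensor:
    """Sum of logits over predicted-foreground pixels (all pixels if the
    prediction is empty).  Differentiable in the logits."""
    mask = np.asarray(pred_mask, dtype=float)
    if mask.sum() == 0:
        mask = np.ones_like(mask)
    flat_mask = mask.reshape(logits.shape)
    return (logits * Tensor(flat_mask.astype(logits.dtype))).sum()


def _prep_image(model: SegModel, image: np.ndarray, requires_grad=False) -> Tensor:
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 2:
        x = x[None, None]
    return Tensor(x, requires_grad=requires_grad)


def _predict_mask(model: SegModel, image: np.ndarray) -> np.ndarray:
    model.eval()
    logits, _ = model.forward(_prep_image(model, image))
    return (logits.data[0, 0] >= 0.0).astype(float)  # sigmoid >= 0.5


def _target_fn(model: SegModel, pred_mask: np.ndarray):
    """Returns f(image) = target scalar with the prediction mask frozen."""

    def f(img: np.ndarray) -> float:
        logits, _ = model.forward(_prep_image(model, img))
        return seg_target_scalar(logits, pred_mask[None, None]).item()

    return f


def grad_cam_pp(model: SegModel, image: np.ndarray, layer: str) -> AttributionMap:
    """Grad-CAM++ at a recorded layer (e.g. ``cnn_l2``, ``mamba_l0``,
    ``fused_l3``, ``X(0,3)``)."""
    model.eval()
    x = _prep_image(model, image)
    logits, _ = model.forward(x, record=True)
    if layer not in model.activations:
        raise KeyError(f"unknown layer {layer!r}; available: {sorted(model.activations)}")
    act = model.activations[layer]
    target = seg_target_scalar(logits, (logits.data >= 0.0).astype(float))
    model.zero_grad()
    target.backward()
    A = act.data[0]  # (C, h, w)
    G = act.grad[0] if act.grad is not None else np.zeros_like(A)
    g2, g3 = G**2, G**3
    denom = 2.0 * g2 + (A * g3).sum(axis=(1, 2), keepdims=True)
    alpha = np.where(np.abs(denom) > 1e-12, g2 / np.where(denom == 0, 1.0, denom), 0.0)
    w = (alpha * np.maximum(G, 0)).sum(axis=(1, 2))
    cam = np.maximum((w[:, None, None] * A).sum(axis=0), 0.0)
    cam = _upsample_np(cam, image.shape[-1])
    cam = np.maximum(cam, 0.0)
    vals, zero = _norm_map(cam)
    return AttributionMap(vals, "grad_cam_pp", layer, all_zero=zero)


def score_cam(model: SegModel, image: np.ndarray, layer: str, batch_size: int = 16) -> AttributionMap:
    """Gradient-free CAM: each channel's normalized activation masks the
    input; its weight is the target-scalar increase over a zero baseline."""
    model.eval()
    image = np.asarray(image, dtype=np.float32)
    model.forward(_prep_image(model, image), record=True)
    if layer not in model.activations:
        raise KeyError(f"unknown layer {layer!r}")
    A = model.activations[layer].data[0]  # (C, h, w)
    pred_mask = _predict_mask(model, image)
    f = _target_fn(model, pred_mask)
    base = f(np.zeros_like(image))
    H = image.shape[-1]
    weights = np.empty(A.shape[0])
    masks = []
    for c in range(A.shape[0]):
        m, _ = _norm_map(np.maximum(_upsample_np(A[c], H), 0.0))
        masks.append(m)
    masks = np.stack(masks)  # (C, H, W)
    for i in range(0, len(masks), batch_size):
        chunk = masks[i : i + batch_size]
        batch = (chunk * image[None]).astype(np.float32)[:, None]
        logits, _ = model.forward(Tensor(batch))
        flat = np.broadcast_to(pred_mask, logits.data[:, 0].shape)
        weights[i : i + batch_size] = (logits.data[:, 0] * flat).sum(axis=(1, 2)) - base
    cam = np.maximum((weights[:, None, None] * A).sum(axis=0), 0.0)
    vals, zero = _norm_map(np.maximum(_upsample_np(cam, H), 0.0))
    return AttributionMap(vals, "score_cam", layer, all_zero=zero)


def eigen_cam(model: SegModel, image: np.ndarray, layer: str) -> AttributionMap:
    """First singular component of the activation matrix, sign-aligned."""
    model.eval()
    model.forward(_prep_image(model, image), record=True)
    if layer not in model.activations:
        raise KeyError(f"unknown layer {layer!r}")
    A = model.activations[layer].data[0]  # (C, h, w)
    C, h, w = A.shape
    M = A.reshape(C, h * w).T  # (pixels, channels)
    if not M.any():
        return AttributionMap(np.zeros(image.shape[-2:]), "eigen_cam", layer, all_zero=True)
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    proj = M @ Vt[0]
    if proj.mean() < 0:
        proj = -proj
    cam = np.abs(proj).reshape(h, w)
    vals, zero = _norm_map(_upsample_np(cam, image.shape[-1]))
    return AttributionMap(np.maximum(vals, 0.0), "eigen_cam", layer, all_zero=zero)


def integrated_gradients(
    model: SegModel, image: np.ndarray, baseline: np.ndarray | None = None, steps: int = 64
) -> AttributionMap:
    """Midpoint-rule path-integrated gradients from baseline to image.

    The default baseline is a Gaussian-blurred copy of the image (sigma 4),
    matching the occlusion baseline of the superpixel methods: an all-zero
    image is far outside the min-max-normalized speckle distribution, and
    near it the normalization layers' Jacobians spike (token variance
    collapses), which ruins the quadrature convergence of the path
    integral.  An explicit ``baseline`` (e.g. zeros) is honored as given.
    """
    import warnings

    if steps < 8:
        warnings.warn("integrated_gradients with steps < 8 is a coarse approximation")
    model.eval()
    image = np.asarray(image, dtype=np.float64)
    baseline = (
        ndimage.gaussian_filter(image, sigma=4.0) if baseline is None else np.asarray(baseline, dtype=np.float64)
    )
    pred_mask = _predict_mask(model, image)
    total = np.zeros_like(image)
    for i in range(steps):
        alpha = (i + 0.5) / steps
        pt = baseline + alpha * (image - baseline)
        x = _prep_image(model, pt, requires_grad=True)
        logits, _ = model.forward(x)
        target = seg_target_scalar(logits, pred_mask[None, None])
        model.zero_grad()
        target.backward()
        total += x.grad[0, 0]
    attr = (image - baseline) * total / steps
    return AttributionMap(attr, "integrated_gradients", signed=True, normalized=False)


def attention_rollout(model: SegModel, image: np.ndarray) -> AttributionMap:
    """Cross-level attention accumulation on the finest transformer grid.

    Per level the head-averaged attention is mixed with the identity
    ((A + I)/2, rows still sum to 1); coarser matrices are expanded to
    the finest token grid (uniformly over subdivided tokens) and the
    products accumulated shallow-to-deep.  Rows of predicted-foreground
    tokens are averaged into the output map."""
    if model.transformer is None:
        raise ValueError("attention rollout requires the transformer branch")
    model.eval()
    logits, _ = model.forward(_prep_image(model, image))
    attns = [blk.last_attention[0] for blk in model.transformer]  # (L,L) each
    g0 = int(math.isqrt(attns[0].shape[0]))
    R = None
    for A in attns:
        g = int(math.isqrt(A.shape[0]))
        A = 0.5 * (A + np.eye(A.shape[0]))
        if g != g0:
            # fine token p maps to coarse token (row(p)//k, col(p)//k);
            # mass spreads uniformly over the k*k subdivided targets so
            # rows stay stochastic
            k = g0 // g
            idx = (np.arange(g0) // k)[:, None] * g + (np.arange(g0) // k)[None, :]
            A = A[idx.ravel()][:, idx.ravel()] / (k * k)
        R = A if R is None else R @ A
    pred = (logits.data[0, 0] >= 0.0).astype(float)
    pred_tok = _downsample_mask(pred, g0)
    if pred_tok.sum() == 0:
        pred_tok = np.ones_like(pred_tok)
    rows = R[pred_tok.ravel() > 0]
    vec = rows.mean(axis=0).reshape(g0, g0)
    vals, zero = _norm_map(_upsample_np(vec, image.shape[-1]))
    return AttributionMap(vals, "attention_rollout", all_zero=zero)


def _downsample_mask(mask: np.ndarray, grid: int) -> np.ndarray:
    H = mask.shape[0]
    k = H // grid
    return (mask.reshape(grid, k, grid, k).mean(axis=(1, 3)) >= 0.5).astype(float)


# ------------------------------------------------------------- superpixels
def _shapley_kernel_weight(M: int, s: int) -> float:
    if s == 0 or s == M:
        return 1e7  # anchors: the exact constraints f(empty), f(full)
    return (M - 1) / (math.comb(M, s) * s * (M - s))


def superpixel_attribution(
    model: SegModel,
    image: np.ndarray,
    mode: str = "shap",
    n_segments: int = 50,
    n_samples: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
    target_fn=None,
) -> AttributionMap:
    """Kernel-SHAP or LIME over intensity superpixels.

    Superpixels come from grid-seeded region growth on intensity (SLIC);
    occluded segments are replaced by a Gaussian-blurred copy of the
    image (black patches are out-of-distribution for min-max-normalized
    ultrasound).  ``target_fn(img) -> float`` may override the default
    frozen-prediction logit-sum target (used by the exactness tests).
    """
    if mode not in ("shap", "lime"):
        raise ValueError("mode must be 'shap' or 'lime'")
    if n_segments < 2:
        raise ValueError("need n_segments >= 2")
    if not exhaustive and n_samples < n_segments + 2:
        raise ValueError("n_samples must be at least n_segments + 2 (underdetermined fit)")
    from skimage.segmentation import slic

    image = np.asarray(image, dtype=np.float64)
    segments = slic(image, n_segments=n_segments, compactness=0.1, channel_axis=None, start_label=0)
    seg_ids = np.unique(segments)
    M = len(seg_ids)
    if target_fn is None:
        model.eval()
        target_fn = _target_fn(model, _predict_mask(model, image))
    rng = np.random.default_rng(seed)
    if exhaustive:
        Z = np.array([[(i >> j) & 1 for j in range(M)] for i in range(2**M)], dtype=float)
    else:
        if n_samples < M + 2:
            raise ValueError("n_samples must be at least n_segments + 2")
        Z = (rng.random((n_samples - 2, M)) < 0.5).astype(float)
        Z = np.vstack([np.zeros(M), np.ones(M), Z])
    blurred = ndimage.gaussian_filter(image, sigma=4.0)
    fvals = np.empty(len(Z))
    seg_masks = np.stack([(segments == s).astype(float) for s in seg_ids])
    for i, z in enumerate(Z):
        keep = (z[:, None, None] * seg_masks).sum(axis=0)
        fvals[i] = target_fn(image * keep + blurred * (1 - keep))
    if mode == "shap":
        w = np.array([_shapley_kernel_weight(M, int(z.sum())) for z in Z])
        X = np.hstack([np.ones((len(Z), 1)), Z])
        W = np.sqrt(w)[:, None]
        coef, *_ = np.linalg.lstsq(X * W, fvals * W[:, 0], rcond=None)
        phi = coef[1:]
    else:
        from sklearn.linear_model import Ridge

        d = 1.0 - Z.mean(axis=1)
        w = np.exp(-(d**2) / 0.25**2)
        reg = Ridge(alpha=1.0)
        reg.fit(Z, fvals, sample_weight=w)
        phi = reg.coef_
    attr = (phi[:, None, None] * seg_masks).sum(axis=0)
    return AttributionMap(attr, mode, signed=True, normalized=False)


# ------------------------------------------------------------- uncertainty
def mc_dropout_uncertainty(model: SegModel, image: np.ndarray, T: int = 30, seed: int = 0):
    """Mean probability map and per-pixel SD over T dropout passes.

    Only dropout layers are stochastic (normalization layers stay in
    evaluation mode)."""
    drops = [m for m in model.modules() if isinstance(m, nn.Dropout) and m.p > 0]
    if not drops:
        raise ValueError("model has no active dropout layers; MC-dropout uncertainty is unsupported")
    model.eval()
    for d in drops:
        d.training = True
    nn.seed_all(seed)
    probs = []
    try:
        for _ in range(T):
            logits, _ = model.forward(_prep_image(model, image))
            probs.append(1.0 / (1.0 + np.exp(-logits.data[0, 0])))
    finally:
        model.eval()
    probs = np.stack(probs)
    return probs.mean(axis=0), UncertaintyMap(probs.std(axis=0), passes=T)


# ----------------------------------------------------- architectural XAI
def branch_contribution(model: SegModel, samples) -> dict:
    """Mean-DSC drop when each auxiliary branch's fusion weight is pinned
    to zero (remaining weights renormalize through the softmax)."""
    aux = [b for b in model.branch_names if b != "cnn"]
    if not aux:
        raise ValueError("branch contribution analysis needs a multi-branch model")
    if not any(isinstance(f, AFFM) for f in (model.fusion or [])):
        raise ValueError("branch deactivation requires AFFM fusion")
    model.eval()

    def mean_dsc(deactivate=()):
        vals = []
        for s in samples:
            logits, _ = model.forward(_prep_image(model, s.image), deactivate=deactivate)
            pred = logits.data[0, 0] >= 0.0
            vals.append(met.overlap_metrics(pred, s.mask)[0])
        return float(np.mean(vals))

    base = mean_dsc()
    out = {"baseline_dsc": base}
    for b in aux:
        out[b] = base - mean_dsc(deactivate=(b,))
    return out


def affm_weight_profile(model: SegModel, samples) -> dict:
    """Per-level fusion-weight distributions (violin-ready vectors)."""
    if not any(isinstance(f, AFFM) for f in (model.fusion or [])):
        raise ValueError("fusion-weight profiling requires AFFM fusion")
    model.eval()
    collected = [[] for _ in range(4)]
    for s in samples:
        _, weights = model.forward(_prep_image(model, s.image))
        for l, w in enumerate(weights):
            collected[l].append(w[0])
    out = {}
    for l in range(4):
        arr = np.stack(collected[l])  # (n, n_branches)
        out[f"level_{l}"] = {
            "weights": arr,
            "branches": list(model.branch_names),
            "mean": arr.mean(axis=0),
            "q25": np.quantile(arr, 0.25, axis=0),
            "q50": np.quantile(arr, 0.50, axis=0),
            "q75": np.quantile(arr, 0.75, axis=0),
        }
    return out


def decoder_feature_maps(model: SegModel, image: np.ndarray, nodes=None) -> dict[str, np.ndarray]:
    """Channel-mean absolute activation of decoder nodes, normalized to
    [0, 1] and upsampled to the image size."""
    model.eval()
    model.forward(_prep_image(model, image), record=True)
    available = model.decoder.node_names()
    nodes = available if nodes is None else list(nodes)
    out = {}
    for name in nodes:
        if name not in model.activations:
            raise KeyError(f"decoder node {name!r} not present (decoder: {type(model.decoder).__name__})")
        a = np.abs(model.activations[name].data[0]).mean(axis=0)
        vals, _ = _norm_map(_upsample_np(a, image.shape[-1]))
        out[name] = vals
    return out
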