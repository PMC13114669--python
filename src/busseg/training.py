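"""Training loop, augmentation, cross-validation and ablation harness.

Protocol: AdamW (decoupled weight decay), initial learning rate 1e-4,
weight decay 1e-4, batch size 16, up to 100 epochs with cosine annealing
warm restarts (T0 = 20 epochs, Tmult = 2, eta_min = 0, stepped per
epoch), early stopping with patience 30 on the validation loss, and
selection of the lowest-validation-loss parameters.  Augmentation:
random horizontal flip (p = 0.5), rotation uniform in +/-15 degrees, and
a mild affine jitter (translation <= 5%, scale 0.9-1.1, no shear) applied
identically to image (bilinear) and mask (nearest, re-binarized).

The validation set of a fold run is the held-out fold itself (no inner
split).  All randomness in a fold flows from ``seed + fold`` so folds are
reproducible yet decorrelated.
"""

from __future__ import annotations

import ctypes
import ctypes.util
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from . import metrics as met
from .losses import LossConfig, dbr_loss_on_logits
from .network import ModelConfig, SegModel, VariantSpec, build_model
from .nn import layers as nn
from .nn.tensor import Tensor, no_grad
from .phantom import ImageSample


def _trim_heap():
    """Ask glibc to return freed arena memory to the OS (no-op elsewhere).

    The training loop allocates and frees hundreds of MB of activation
    arrays per step; without trimming, allocator retention can grow the
    resident set far beyond live data on long runs."""
    try:
        ctypes.CDLL(ctypes.util.find_library("c")).malloc_trim(0)
    except (OSError, AttributeError, TypeError):
        pass


@dataclass
class TrainConfig:
    lr0: float = 1e-4
    weight_decay: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 100
    t0: int = 20
    t_mult: int = 2
    patience: int = 30
    seed: int = 0
    augment: bool = True
    flip_p: float = 0.5
    max_rotation_deg: float = 15.0
    max_translate_frac: float = 0.05
    scale_range: tuple[float, float] = (0.9, 1.1)

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.patience >= self.max_epochs and self.max_epochs > 1:
            # patience larger than the horizon silently disables early stopping
            raise ValueError("patience must be smaller than max_epochs")


# CPU-scale benchmark protocol for the miniature configuration: higher
# learning rate and smaller batches than the reference protocol, sized so
# a 2-fold run on 160 small phantoms converges within ~10 short epochs.
MINIATURE_TRAIN = TrainConfig(lr0=3e-3, batch_size=8, max_epochs=10, patience=8)


def lr_at(epoch: int, lr0: float, t0: int = 20, t_mult: int = 2) -> float:
    """Cosine-annealing-with-warm-restarts learning rate at an epoch.

    Cycle c has length t0 * t_mult**c; within a cycle,
    lr = lr0 * (1 + cos(pi * (epoch - start) / length)) / 2  (eta_min 0).
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    start, length = 0, t0
    while epoch >= start + length:
        start += length
        length *= t_mult
    return lr0 * (1.0 + np.cos(np.pi * (epoch - start) / length)) / 2.0


def augment(sample: ImageSample, rng: np.random.Generator, config: TrainConfig = TrainConfig()) -> ImageSample:
    """Randomly flipped/rotated/affine-jittered copy of a sample."""
    img, mask = sample.image, sample.mask
    if rng.random() < config.flip_p:
        img, mask = img[:, ::-1], mask[:, ::-1]
    angle = rng.uniform(-config.max_rotation_deg, config.max_rotation_deg)
    scale = rng.uniform(*config.scale_range)
    H, W = img.shape
    ty = rng.uniform(-config.max_translate_frac, config.max_translate_frac) * H
    tx = rng.uniform(-config.max_translate_frac, config.max_translate_frac) * W
    th = np.deg2rad(angle)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]) / scale
    center = np.array([(H - 1) / 2, (W - 1) / 2])
    offset = center - R @ (center + np.array([ty, tx]))
    img2 = ndimage.affine_transform(img, R, offset=offset, order=1, mode="constant", cval=0.0)
    mask2 = ndimage.affine_transform(mask.astype(float), R, offset=offset, order=0, mode="constant", cval=0.0)
    return ImageSample(
        image=np.clip(img2, 0.0, 1.0),
        mask=(mask2 > 0.5).astype(np.uint8),
        fold=sample.fold,
        id=sample.id,
    )


class EarlyStopper:
    """Stop when the validation loss has not improved for `patience` epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self.since_best = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record an epoch; returns True when training should stop."""
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = epoch
            self.since_best = 0
        else:
            self.since_best += 1
        return self.since_best >= self.patience


@dataclass
class TrainHistory:
    epochs: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_dsc: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    best_epoch: int = -1

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": self.epochs,
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "val_dsc": self.val_dsc,
                "lr": self.lr,
            }
        )


@dataclass
class Checkpoint:
    config: ModelConfig
    state: dict
    epoch: int
    best_val_loss: float

    def save(self, path):
        from dataclasses import asdict
        import json

        cfg = asdict(self.config)
        np.savez(
            path,
            __config__=json.dumps(cfg),
            __epoch__=self.epoch,
            __best_val_loss__=self.best_val_loss,
            **self.state,
        )

    @staticmethod
    def load(path) -> "Checkpoint":
        import json

        from .ssm import SSMParams

        z = np.load(path, allow_pickle=False)
        cfg = json.loads(str(z["__config__"]))
        cfg["ssm"] = SSMParams(**cfg["ssm"])
        for k in ("level_channels", "blocks_per_level", "heads_per_level", "branches"):
            cfg[k] = tuple(cfg[k])
        state = {k: z[k] for k in z.files if not k.startswith("__")}
        return Checkpoint(
            config=ModelConfig(**cfg),
            state=state,
            epoch=int(z["__epoch__"]),
            best_val_loss=float(z["__best_val_loss__"]),
        )

    def build(self) -> SegModel:
        model = build_model(self.config)
        model.load_state_dict(self.state)
        return model


def _batched_val_loss(model: SegModel, X, y, loss_config, batch_size):
    model.eval()
    total, n = 0.0, 0
    dscs = []
    for i in range(0, len(X), batch_size):
        xb = X[i : i + batch_size][:, None]
        yb = y[i : i + batch_size]
        with no_grad():
            logits, _ = model.forward(Tensor(xb.astype(np.float32)))
            lb = dbr_loss_on_logits(logits[:, 0], yb, loss_config)
        total += lb.total.item() * len(xb)
        n += len(xb)
        probs = 1.0 / (1.0 + np.exp(-logits.data[:, 0]))
        for p, t in zip(probs, yb):
            dscs.append(met.overlap_metrics(p >= 0.5, t)[0])
    model.train()
    _trim_heap()
    return total / n, float(np.mean(dscs))


def fit_model(
    model: SegModel,
    train_samples: list[ImageSample],
    val_samples: list[ImageSample],
    train_config: TrainConfig,
    loss_config: LossConfig = LossConfig(),
    log=None,
) -> TrainHistory:
    """Train a model in place; returns the history.  The model is left
    loaded with the best-validation-loss parameters."""
    rng = np.random.default_rng(train_config.seed)
    opt = nn.AdamW(model.parameters(), lr=train_config.lr0, weight_decay=train_config.weight_decay)
    stopper = EarlyStopper(train_config.patience)
    history = TrainHistory()
    X_val = np.stack([s.image for s in val_samples]).astype(np.float32)
    y_val = np.stack([s.mask for s in val_samples]).astype(np.float32)
    best_state = None
    model.train()
    for epoch in range(train_config.max_epochs):
        lr = lr_at(epoch, train_config.lr0, train_config.t0, train_config.t_mult)
        opt.lr = lr
        order = rng.permutation(len(train_samples))
        losses = []
        for i in range(0, len(order), train_config.batch_size):
            batch = [train_samples[j] for j in order[i : i + train_config.batch_size]]
            if train_config.augment:
                batch = [augment(s, rng, train_config) for s in batch]
            xb = np.stack([s.image for s in batch]).astype(np.float32)[:, None]
            yb = np.stack([s.mask for s in batch]).astype(np.float32)
            logits, _ = model.forward(Tensor(xb))
            lb = dbr_loss_on_logits(logits[:, 0], yb, loss_config)
            if not np.isfinite(lb.total.item()):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}: {lb.total.item()}")
            opt.zero_grad()
            lb.total.backward()
            opt.step()
            losses.append(lb.total.item())
            del logits, lb
            _trim_heap()
        val_loss, val_dsc = _batched_val_loss(model, X_val, y_val, loss_config, train_config.batch_size)
        history.epochs.append(epoch)
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(val_loss)
        history.val_dsc.append(val_dsc)
        history.lr.append(lr)
        if log:
            log(f"epoch={epoch} lr={lr:.2e} train_loss={np.mean(losses):.4f} val_loss={val_loss:.4f} val_dsc={val_dsc:.4f}")
        improved = val_loss < stopper.best
        stop = stopper.update(epoch, val_loss)
        if improved:
            best_state = model.state_dict()
        if stop:
            break
    history.best_epoch = stopper.best_epoch
    if best_state is not None:
        model.load_state_dict(best_state)
    return history


def train_fold(
    samples: list[ImageSample],
    fold: int,
    model_config: ModelConfig,
    train_config: TrainConfig,
    loss_config: LossConfig = LossConfig(),
    log=None,
) -> tuple[Checkpoint, TrainHistory]:
    """Train on all folds != `fold`, validate on `fold`."""
    train_s = [s for s in samples if s.fold != fold]
    val_s = [s for s in samples if s.fold == fold]
    if not train_s or not val_s:
        raise ValueError(f"fold {fold} yields an empty train or validation set")
    fold_seed = int(train_config.seed) + int(fold)
    nn.seed_all(fold_seed)
    model = build_model(replace(model_config, seed=fold_seed))
    history = fit_model(model, train_s, val_s, replace(train_config, seed=fold_seed), loss_config, log=log)
    ckpt = Checkpoint(
        config=model.config,
        state=model.state_dict(),
        epoch=history.best_epoch,
        best_val_loss=float(np.min(history.val_loss)),
    )
    return ckpt, history


@dataclass
class CVResult:
    records: list[met.MetricsRecord]
    summary: met.FoldSummary
    checkpoints: dict[int, Checkpoint]
    histories: dict[int, TrainHistory]
    fold_of_id: dict[str, int]

    def records_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([r.as_dict() for r in self.records])
        df["fold"] = df["id"].map(self.fold_of_id)
        return df


def run_cv(
    samples: list[ImageSample],
    model_config: ModelConfig,
    train_config: TrainConfig,
    loss_config: LossConfig = LossConfig(),
    log=None,
) -> CVResult:
    """K-fold cross-validation: train per fold, evaluate on the held-out
    fold only (no image is ever evaluated by a model trained on it)."""
    folds = sorted({s.fold for s in samples})
    if len(folds) < 2:
        raise ValueError("need at least 2 folds")
    fold_of_id = {s.id: s.fold for s in samples}
    records, ckpts, hists = [], {}, {}
    for fold in folds:
        t0 = time.time()
        ckpt, hist = train_fold(samples, fold, model_config, train_config, loss_config, log=log)
        model = ckpt.build()
        val_s = [s for s in samples if s.fold == fold]
        probs = model.predict_proba(np.stack([s.image for s in val_s]), train_config.batch_size)
        for s, p in zip(val_s, probs):
            records.append(met.compute_record(s.id, p >= 0.5, s.mask))
        ckpts[fold] = ckpt
        hists[fold] = hist
        if log:
            log(f"fold={fold} done in {time.time() - t0:.1f}s best_epoch={hist.best_epoch}")
    summary = met.fold_aggregate(records, fold_of_id)
    return CVResult(records, summary, ckpts, hists, fold_of_id)


def run_ablation(
    samples: list[ImageSample],
    variant_names: list[str],
    base_model_config: ModelConfig,
    train_config: TrainConfig,
    base_loss_config: LossConfig = LossConfig(),
    log=None,
):
    """Train every requested variant under identical seeds and folds.

    Returns ``(report_frame, results)`` where the report mirrors the
    ablation table layout: DSC mean +/- SD, B-IoU, HD95, parameter count.
    """
    rows, results = [], {}
    for name in variant_names:
        spec = VariantSpec(name)
        mcfg = spec.model_config(base_model_config)
        lcfg = spec.loss_config(base_loss_config)
        if log:
            log(f"ablation variant={name}")
        res = run_cv(samples, mcfg, train_config, lcfg, log=log)
        n_params = build_model(mcfg).n_parameters()
        rows.append(
            {
                "variant": name,
                "dsc_mean": res.summary.mean["dsc"],
                "dsc_sd": res.summary.sd["dsc"],
                "b_iou": res.summary.mean["b_iou"],
                "hd95": res.summary.mean["hd95"],
                "params": n_params,
            }
        )
        results[name] = res
    return pd.DataFrame(rows), results
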