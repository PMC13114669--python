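"""Manifests, image I/O, run configuration and report writing.

The manifest is a CSV with header ``id,image_path,mask_path,fold``
assigning every image to one cross-validation fold.  Images are 8-bit
grayscale PNGs; masks are 8-bit PNGs in {0, 255}, binarized at 128.
Reports are deterministic: JSON with sorted keys and 6-significant-digit
floats, stamped with the configuration hash and seed, so re-running an
identical configuration reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .losses import LossConfig
from .network import ModelConfig
from .phantom import ImageSample
from .ssm import SSMParams
from .training import TrainConfig

MANIFEST_COLUMNS = ["id", "image_path", "mask_path", "fold"]


class ManifestError(ValueError):
    pass


@dataclass
class RunConfig:
    data: dict = field(default_factory=dict)  # manifest path, image_size
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    xai: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "runs"

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        import yaml

        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        model_raw = dict(raw.get("model", {}))
        if "ssm" in model_raw:
            model_raw["ssm"] = SSMParams(**model_raw["ssm"])
        for k in ("level_channels", "blocks_per_level", "heads_per_level", "branches"):
            if k in model_raw:
                model_raw[k] = tuple(model_raw[k])
        train_raw = dict(raw.get("train", {}))
        if "scale_range" in train_raw:
            train_raw["scale_range"] = tuple(train_raw["scale_range"])
        return RunConfig(
            data=raw.get("data", {}),
            model=ModelConfig(**model_raw),
            train=TrainConfig(**train_raw),
            loss=LossConfig(**raw.get("loss", {})),
            xai=raw.get("xai", {}),
            seed=int(raw.get("seed", 0)),
            out_dir=str(raw.get("out_dir", "runs")),
        )

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_manifest(path) -> pd.DataFrame:
    """Read and validate a fold manifest."""
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != MANIFEST_COLUMNS:
        raise ManifestError(f"manifest must have columns {MANIFEST_COLUMNS}, got {list(df.columns)}")
    dup = df["id"][df["id"].duplicated()]
    if len(dup):
        raise ManifestError(f"duplicate id(s) in manifest: {sorted(set(dup))}")
    folds = []
    for i, v in enumerate(df["fold"]):
        try:
            folds.append(int(v))
        except (TypeError, ValueError):
            raise ManifestError(f"non-integer fold {v!r} at manifest row {i}") from None
    df["fold"] = folds
    base = Path(path).parent
    for col in ("image_path", "mask_path"):
        for i, p in enumerate(df[col]):
            full = Path(p) if Path(p).is_absolute() else base / p
            if not full.exists():
                raise ManifestError(f"missing file {p!r} at manifest row {i}")
    return df


def load_sample(row, image_size: int, manifest_dir: Path | None = None) -> ImageSample:
    """Load one manifest row: grayscale-convert, resize (bilinear image /
    nearest mask), per-image min-max normalize, binarize the mask at 128."""

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() or manifest_dir is None else manifest_dir / p

    img = Image.open(resolve(row["image_path"])).convert("L")
    msk = Image.open(resolve(row["mask_path"])).convert("L")
    img = img.resize((image_size, image_size), Image.BILINEAR)
    msk = msk.resize((image_size, image_size), Image.NEAREST)
    arr = np.asarray(img, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    mask = (np.asarray(msk) >= 128).astype(np.uint8)
    return ImageSample(image=arr, mask=mask, fold=int(row["fold"]), id=str(row["id"]))


def load_dataset(manifest_path, image_size: int) -> list[ImageSample]:
    df = load_manifest(manifest_path)
    base = Path(manifest_path).parent
    return [load_sample(row, image_size, base) for _, row in df.iterrows()]


# ------------------------------------------------------------------- reports
def _round_sig(x, sig=6):
    if isinstance(x, dict):
        return {k: _round_sig(v, sig) for k, v in sorted(x.items())}
    if isinstance(x, (list, tuple)):
        return [_round_sig(v, sig) for v in x]
    if isinstance(x, (np.floating, float)):
        x = float(x)
        if np.isnan(x) or np.isinf(x) or x == 0:
            return x
        return float(f"{x:.6g}")
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, np.ndarray):
        return _round_sig(x.tolist(), sig)
    return x


def write_json_report(payload: dict, path, config_hash: str = "", seed: int | None = None):
    """Deterministic JSON: sorted keys, 6-significant-digit floats."""
    out = dict(payload)
    if config_hash:
        out["config_hash"] = config_hash
    if seed is not None:
        out["seed"] = seed
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        json.dump(_round_sig(out), f, sort_keys=True, indent=2)
        f.write("\n")


def write_reports(cv_result, out_dir, config: RunConfig | None = None, comparisons: dict | None = None):
    """Emit the standard report bundle for one cross-validation run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h = config.hash() if config else ""
    seed = config.seed if config else None
    df = cv_result.records_frame()
    float_cols = df.select_dtypes(include=[float]).columns
    df[float_cols] = df[float_cols].map(lambda v: float(f"{v:.6g}"))
    df.to_csv(out_dir / "per_image_metrics.csv", index=False)
    summary = {
        "mean": cv_result.summary.mean,
        "sd": cv_result.summary.sd,
        "ci_low": cv_result.summary.ci_low,
        "ci_high": cv_result.summary.ci_high,
        "n_folds": cv_result.summary.n_folds,
        "fold_means": {str(k): v for k, v in cv_result.summary.fold_means.to_dict(orient="index").items()},
    }
    write_json_report(summary, out_dir / "fold_summary.json", h, seed)
    if comparisons:
        write_json_report(comparisons, out_dir / "comparisons.json", h, seed)
    for fold, hist in cv_result.histories.items():
        hist.as_frame().to_csv(out_dir / f"history_fold{fold}.csv", index=False, float_format="%.6g")
    return out_dir
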