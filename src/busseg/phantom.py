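"""Synthetic breast-ultrasound phantom generator.

Real breast ultrasound is characterized by multiplicative speckle, low
lesion/background contrast, hypoechoic (darker-than-surroundings) tumor
regions with irregular margins, and posterior acoustic shadowing below
some lesions.  This module emulates those properties well enough to
exercise a segmentation pipeline end to end: a smooth tissue background,
star-convex lesions whose radius is perturbed per angle by a low-order
random Fourier series, a multiplicative gamma speckle field, an optional
soft vertical shadow band under each lesion, and min-max normalization.

It is deliberately not a physical simulator: there is no beamforming,
attenuation or frequency-dependent scattering.  Identical (spec, seed,
index) triplets produce byte-identical images and masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image


class PlacementError(RuntimeError):
    """Raised when non-overlapping lesion placement fails after retries."""


@dataclass
class PhantomSpec:
    image_size: int = 64
    lesion_count: int = 1
    lesion_area_fraction_range: tuple[float, float] = (0.03, 0.12)
    boundary_irregularity: float = 0.15
    lesion_contrast: float = 0.45
    speckle_scale: float = 6.0
    shadow_probability: float = 0.3
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lesion_area_fraction_range
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if not (0 < lo < hi < 1):
            raise ValueError("lesion_area_fraction_range must satisfy 0 < min < max < 1")
        if self.lesion_count < 0:
            raise ValueError("lesion_count must be >= 0")
        if not (0 < self.lesion_contrast < 1):
            raise ValueError("lesion_contrast must be in (0,1)")
        if self.speckle_scale <= 0:
            raise ValueError("speckle_scale must be positive")
        if not (0 <= self.shadow_probability <= 1):
            raise ValueError("shadow_probability must be in [0,1]")
        if self.boundary_irregularity < 0:
            raise ValueError("boundary_irregularity must be nonnegative")


@dataclass
class ImageSample:
    image: np.ndarray  # (H, W) float in [0, 1]
    mask: np.ndarray  # (H, W) uint8 in {0, 1}
    fold: int = -1
    id: str = ""
    clean: np.ndarray | None = None  # pre-speckle intensity field (diagnostics)

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")


def _lesion_radius_profile(rng: np.random.Generator, irregularity: float, n_theta: int = 256):
    """Smooth periodic radial perturbation s(theta) from a low-order Fourier series."""
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    s = np.zeros(n_theta)
    orders = (2, 3, 4, 5)
    amps = rng.standard_normal(len(orders))
    phases = rng.uniform(0, 2 * np.pi, len(orders))
    for k, a, p in zip(orders, amps, phases):
        s += a * np.cos(k * theta + p)
    norm = np.sqrt(np.mean(s**2)) + 1e-12
    s = s / norm  # unit RMS so `irregularity` is the RMS radial amplitude
    return theta, 1.0 + irregularity * s


def _polygon_mask(cy, cx, radii, theta, axis_ratio, rot, shape):
    """Rasterize a star-convex region from per-angle radii: rotate pixel
    offsets into the ellipse frame and compare polar radius to r(theta)."""
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    ca, sa = np.cos(rot), np.sin(rot)
    xr = (xx - cx) * ca + (yy - cy) * sa
    yr = (-(xx - cx) * sa + (yy - cy) * ca) / axis_ratio
    ang = np.mod(np.arctan2(yr, xr), 2 * np.pi)
    r_pix = np.hypot(xr, yr)
    idx = (ang / (2 * np.pi) * len(theta)).astype(int) % len(theta)
    return r_pix <= radii[idx]


def _place_lesion(rng, spec: PhantomSpec, occupied: np.ndarray):
    H = spec.image_size
    target_frac = rng.uniform(*spec.lesion_area_fraction_range)
    target_area = target_frac * H * H
    theta, profile = _lesion_radius_profile(rng, spec.boundary_irregularity)
    axis_ratio = rng.uniform(0.65, 1.0)
    rot = rng.uniform(0, np.pi)
    # calibrate r0 so the rasterized area matches the target: polygon area
    # of r(theta) = r0 * profile under y-scaling by axis_ratio is
    # 0.5 * axis_ratio * r0^2 * integral(profile^2)
    integ = np.trapezoid(np.concatenate([profile**2, profile[:1] ** 2]), dx=2 * np.pi / len(theta))
    r0 = np.sqrt(2 * target_area / (axis_ratio * integ))
    radii = r0 * profile
    rmax = radii.max() * max(axis_ratio, 1.0)
    if 2 * rmax > 0.9 * H:
        raise PlacementError(
            f"lesion of area fraction {target_frac:.3f} does not fit in a {H}x{H} image"
        )
    for _ in range(50):
        cy = rng.uniform(rmax + 1, H - rmax - 1 - 0.15 * H)  # keep room for shadow below
        cx = rng.uniform(rmax + 1, H - rmax - 1)
        m = _polygon_mask(cy, cx, radii, theta, axis_ratio, rot, (H, H))
        if not (m & occupied).any():
            return m, (cy, cx, rmax)
    raise PlacementError("could not place a non-overlapping lesion after 50 retries")


def generate_phantom(spec: PhantomSpec, index: int = 0) -> ImageSample:
    """Generate one phantom image + mask, deterministically from (spec, index)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), int(index)]))
    H = spec.image_size
    yy, xx = np.mgrid[0:H, 0:H].astype(float) / H

    # smooth tissue background with a mild depth gradient and low-freq texture
    bg = 0.72 - 0.12 * yy
    for _ in range(3):
        fy, fx = rng.uniform(1, 4, 2)
        ph = rng.uniform(0, 2 * np.pi, 2)
        bg = bg + 0.04 * np.sin(2 * np.pi * fy * yy + ph[0]) * np.sin(2 * np.pi * fx * xx + ph[1])

    mask = np.zeros((H, H), dtype=bool)
    clean = bg.copy()
    centers = []
    for _ in range(spec.lesion_count):
        m, geom = _place_lesion(rng, spec, mask)
        mask |= m
        clean = np.where(m, clean * spec.lesion_contrast, clean)
        centers.append(geom)

    # posterior shadow: soft darkening column below the lesion
    for cy, cx, rmax in centers:
        if rng.random() < spec.shadow_probability:
            depth = np.clip((yy * H - cy) / (0.8 * H), 0, 1)
            lateral = np.exp(-0.5 * ((xx * H - cx) / (0.8 * rmax + 1e-9)) ** 2)
            clean = clean * (1.0 - 0.35 * depth * lateral)

    speckle = rng.gamma(shape=spec.speckle_scale, scale=1.0 / spec.speckle_scale, size=(H, H))
    noisy = clean * speckle
    lo, hi = noisy.min(), noisy.max()
    image = (noisy - lo) / (hi - lo) if hi > lo else np.zeros_like(noisy)
    return ImageSample(
        image=image.astype(np.float64),
        mask=mask.astype(np.uint8),
        id=f"phantom_{spec.seed}_{index:05d}",
        clean=clean,
    )


def fold_assignment(n: int, k_folds: int) -> np.ndarray:
    """Balanced fold ids [0..k) with sizes differing by at most one."""
    folds = np.arange(n) % k_folds
    return folds


def generate_dataset(spec: PhantomSpec, n: int, k_folds: int, out_dir) -> "pd.DataFrame":
    """Write n phantoms (PNG image + mask) and a fold manifest CSV.

    Folds are image-disjoint with sizes differing by <= 1.  Returns the
    manifest as a DataFrame with columns id, image_path, mask_path, fold.
    """
    import pandas as pd

    if not (n >= k_folds >= 2):
        raise ValueError("need n >= k_folds >= 2")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    folds = fold_assignment(n, k_folds)
    rows = []
    for i in range(n):
        s = generate_phantom(spec, i)
        img_path = out_dir / "images" / f"{s.id}.png"
        mask_path = out_dir / "masks" / f"{s.id}.png"
        Image.fromarray(np.round(s.image * 255).astype(np.uint8)).save(img_path)
        Image.fromarray((s.mask * 255).astype(np.uint8)).save(mask_path)
        rows.append(
            {"id": s.id, "image_path": str(img_path), "mask_path": str(mask_path), "fold": int(folds[i])}
        )
    manifest = pd.DataFrame(rows, columns=["id", "image_path", "mask_path", "fold"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_samples(spec: PhantomSpec, n: int, k_folds: int = 2) -> list[ImageSample]:
    """Generate n in-memory samples with balanced fold ids (no file I/O)."""
    folds = fold_assignment(n, k_folds)
    out = []
    for i in range(n):
        s = generate_phantom(spec, i)
        s.fold = int(folds[i])
        out.append(s)
    return out
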