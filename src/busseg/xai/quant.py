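"""Quantitative validation of attribution and uncertainty maps.

* nEAR (normalized Energy Attribution Ratio): the fraction of total
  attribution energy (sum of absolute values) inside the ground-truth
  lesion mask, divided by the lesion's area fraction.  1.0 is chance
  level; > 1 means disproportionate focus on the lesion.
* Top-k% lesion hit rate: fraction of the k% highest-|attribution|
  pixels inside the mask, again normalized by the lesion area fraction.
* Cross-method consistency: pairwise Spearman rank correlation and SSIM
  between attribution maps.
* Uncertainty-error analysis: Pearson correlation between MC-dropout
  uncertainty and the segmentation error indicator (pooled over pixels
  and per image), error/correct and boundary/interior uncertainty
  ratios, and Cohen's d between error- and correct-pixel uncertainty.
* Quartile case selection and mean-uncertainty failure flagging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..losses import boundary_band

UNDEFINED = float("nan")


def _energy(attr: np.ndarray) -> np.ndarray:
    return np.abs(np.asarray(attr, dtype=float))


def near(attr, mask) -> float:
    """Normalized energy attribution ratio (nan for degenerate input)."""
    e = _energy(attr)
    m = np.asarray(mask).astype(bool)
    if e.shape != m.shape:
        raise ValueError("attribution/mask shape mismatch")
    total = e.sum()
    if not m.any() or total == 0:
        return UNDEFINED
    area_frac = m.mean()
    return float((e[m].sum() / total) / area_frac)


def topk_hit_rate(attr, mask, k_percent: float) -> float:
    """Hit rate of the top-k% |attribution| pixels, area-normalized.

    Ties are broken by fixed row-major pixel order."""
    if not (0 < k_percent <= 100):
        raise ValueError("k_percent must be in (0, 100]")
    e = _energy(attr).ravel()
    m = np.asarray(mask).astype(bool).ravel()
    if e.shape != m.shape:
        raise ValueError("attribution/mask shape mismatch")
    if not m.any() or e.sum() == 0:
        return UNDEFINED
    n = int(np.ceil(k_percent / 100.0 * e.size))
    # stable sort on (-value, index): ties resolve in row-major order
    order = np.lexsort((np.arange(e.size), -e))[:n]
    hit_frac = m[order].mean()
    return float(hit_frac / m.mean())


@dataclass
class ConsistencyMatrix:
    methods: list
    spearman: np.ndarray
    ssim: np.ndarray

    def mean_offdiag(self):
        k = len(self.methods)
        iu = np.triu_indices(k, 1)
        rho = self.spearman[iu]
        return float(np.nanmean(rho)), float(np.nanmean(self.ssim[iu]))

    def family_means(self, families: dict[str, str]):
        """Mean within- and between-family Spearman, for caller-supplied
        method -> family labels."""
        k = len(self.methods)
        within, between = [], []
        for i in range(k):
            for j in range(i + 1, k):
                same = families[self.methods[i]] == families[self.methods[j]]
                (within if same else between).append(self.spearman[i, j])
        return (
            float(np.nanmean(within)) if within else UNDEFINED,
            float(np.nanmean(between)) if between else UNDEFINED,
        )


def cross_method_consistency(maps: dict[str, np.ndarray], ssim_window: int = 7) -> ConsistencyMatrix:
    """Pairwise Spearman and SSIM between attribution maps."""
    from skimage.metrics import structural_similarity

    names = list(maps)
    if len(names) < 2:
        raise ValueError("need at least two maps")
    arrs = [np.asarray(maps[n], dtype=float) for n in names]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("maps must share a shape")
    k = len(names)
    S = np.eye(k)
    M = np.eye(k)
    norm = []
    for a in arrs:
        lo, hi = a.min(), a.max()
        norm.append((a - lo) / (hi - lo) if hi > lo else np.zeros_like(a))
    for i in range(k):
        for j in range(i + 1, k):
            if arrs[i].std() == 0 or arrs[j].std() == 0:
                rho = UNDEFINED
            else:
                rho = stats.spearmanr(arrs[i].ravel(), arrs[j].ravel()).statistic
            S[i, j] = S[j, i] = rho
            M[i, j] = M[j, i] = structural_similarity(
                norm[i], norm[j], win_size=ssim_window, data_range=1.0
            )
    return ConsistencyMatrix(names, S, M)


@dataclass
class UncertaintyErrorReport:
    pooled_r: float
    pooled_p: float
    per_image_r: float
    per_image_p: float
    error_correct_ratio: float
    cohens_d: float
    boundary_interior_ratio: float
    n_images: int
    n_pixels: int


def uncertainty_error_report(unc_maps, pred_masks, gt_masks, band_kernel: int = 7) -> UncertaintyErrorReport:
    """Correlate per-pixel uncertainty with segmentation error."""
    if not (len(unc_maps) == len(pred_masks) == len(gt_masks)):
        raise ValueError("need aligned per-image triples")
    unc_all, err_all = [], []
    img_unc, img_err = [], []
    bnd_vals, int_vals = [], []
    for u, p, g in zip(unc_maps, pred_masks, gt_masks):
        u = np.asarray(u, dtype=float)
        err = (np.asarray(p).astype(bool) ^ np.asarray(g).astype(bool)).astype(float)
        unc_all.append(u.ravel())
        err_all.append(err.ravel())
        img_unc.append(u.mean())
        img_err.append(err.mean())
        band = boundary_band(g, band_kernel).astype(bool)
        if band.any():
            bnd_vals.append(u[band])
        if (~band).any():
            int_vals.append(u[~band])
    unc_all = np.concatenate(unc_all)
    err_all = np.concatenate(err_all)
    if unc_all.std() == 0 or err_all.std() == 0:
        pooled_r, pooled_p = UNDEFINED, UNDEFINED
    else:
        r = stats.pearsonr(unc_all, err_all)
        pooled_r, pooled_p = float(r.statistic), float(r.pvalue)
    img_unc, img_err = np.asarray(img_unc), np.asarray(img_err)
    if len(img_unc) > 2 and img_unc.std() > 0 and img_err.std() > 0:
        r = stats.pearsonr(img_unc, img_err)
        per_r, per_p = float(r.statistic), float(r.pvalue)
    else:
        per_r, per_p = UNDEFINED, UNDEFINED
    on_err = unc_all[err_all > 0]
    on_ok = unc_all[err_all == 0]
    if len(on_err) and len(on_ok) and on_ok.mean() > 0:
        ratio = float(on_err.mean() / on_ok.mean())
    else:
        ratio = 1.0 if unc_all.std() == 0 else UNDEFINED
    if len(on_err) > 1 and len(on_ok) > 1:
        pooled_sd = np.sqrt(
            ((len(on_err) - 1) * on_err.var(ddof=1) + (len(on_ok) - 1) * on_ok.var(ddof=1))
            / (len(on_err) + len(on_ok) - 2)
        )
        d = float((on_err.mean() - on_ok.mean()) / pooled_sd) if pooled_sd > 0 else UNDEFINED
    else:
        d = UNDEFINED
    bnd = np.concatenate(bnd_vals) if bnd_vals else np.array([])
    itr = np.concatenate(int_vals) if int_vals else np.array([])
    if len(bnd) and len(itr) and itr.mean() > 0:
        bi = float(bnd.mean() / itr.mean())
    else:
        bi = UNDEFINED
    return UncertaintyErrorReport(
        pooled_r=pooled_r,
        pooled_p=pooled_p,
        per_image_r=per_r,
        per_image_p=per_p,
        error_correct_ratio=ratio,
        cohens_d=d,
        boundary_interior_ratio=bi,
        n_images=len(pred_masks),
        n_pixels=int(unc_all.size),
    )


def quartile_case_selection(dsc_by_id: dict[str, float]) -> list[str]:
    """Representative ids at the minimum, 25th percentile, median and
    maximum DSC rank (ascending; ties broken by id)."""
    if len(dsc_by_id) < 4:
        raise ValueError("need at least 4 cases")
    items = sorted(dsc_by_id.items(), key=lambda kv: (kv[1], kv[0]))
    n = len(items)
    ranks = [1, int(np.ceil(0.25 * n)), int(np.ceil(0.5 * n)), n]
    # small n can collide ranks; advance to the next unused rank so the
    # four representatives are distinct cases
    used, resolved = set(), []
    for r in ranks:
        while r in used:
            r += 1
        used.add(r)
        resolved.append(r)
    return [items[r - 1][0] for r in resolved]


def failure_flag(unc_map, threshold: float):
    """Mean uncertainty and a reliability flag (mean > threshold)."""
    if not (0 < threshold < 0.5):
        raise ValueError("threshold must be in (0, 0.5)")
    m = float(np.asarray(unc_map).mean())
    return m > threshold, m
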