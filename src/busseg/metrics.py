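"""Segmentation metrics and the statistical comparison battery.

Per-image metrics: Dice similarity (DSC), IoU, 95th-percentile Hausdorff
distance (HD95), Boundary IoU over the ground-truth boundary band,
recall, precision and specificity.  Fold-level aggregation reports
cross-fold mean +/- SD with t-distribution confidence intervals, and
model comparisons use the paired t-test, exact Wilcoxon signed-rank,
Cohen's d (paired), Shapiro-Wilk normality on the differences, and the
Friedman rank test across >2 models.

Empty-mask conventions (the field has no single standard; these are
bounded, monotone sentinels): both masks empty -> DSC = IoU = B-IoU = 1
and HD95 = 0; exactly one empty -> DSC = IoU = B-IoU = 0 and HD95 = the
image diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .losses import boundary_band

UNDEFINED = float("nan")


@dataclass
class MetricsRecord:
    id: str
    dsc: float
    iou: float
    b_iou: float
    recall: float
    precision: float
    specificity: float
    hd95: float
    hd95_sentinel: bool = False

    def as_dict(self):
        return {
            "id": self.id,
            "dsc": self.dsc,
            "iou": self.iou,
            "b_iou": self.b_iou,
            "recall": self.recall,
            "precision": self.precision,
            "specificity": self.specificity,
            "hd95": self.hd95,
            "hd95_sentinel": self.hd95_sentinel,
        }


def _check_pair(pred, gt):
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    return pred, gt


def overlap_metrics(pred, gt):
    """(dsc, iou, recall, precision, specificity) from the confusion counts."""
    pred, gt = _check_pair(pred, gt)
    tp = float((pred & gt).sum())
    fp = float((pred & ~gt).sum())
    fn = float((~pred & gt).sum())
    tn = float((~pred & ~gt).sum())
    if not pred.any() and not gt.any():
        return 1.0, 1.0, 1.0, 1.0, tn / max(tn + fp, 1.0)
    dsc = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    iou = tp / (tp + fp + fn) if (tp + fp + fn) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    specificity = tn / (tn + fp) if (tn + fp) > 0 else 0.0
    return dsc, iou, recall, precision, specificity


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """(n,2) coordinates of mask pixels with a 4-neighbor background pixel
    (pixels on the image border count as boundary)."""
    m = np.asarray(mask).astype(bool)
    padded = np.pad(m, 1)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return np.argwhere(m & ~interior)


def hd95(pred, gt):
    """Symmetrized 95th-percentile Hausdorff distance between mask boundaries.

    Returns ``(value, sentinel_flag)``; an empty/one-sided pair yields the
    sentinel (0 for both-empty, image diagonal otherwise).
    """
    pred, gt = _check_pair(pred, gt)
    pe, ge = pred.any(), gt.any()
    if not pe and not ge:
        return 0.0, False
    if pe != ge:
        return float(np.hypot(*pred.shape)), True
    bp = boundary_pixels(pred).astype(float)
    bg = boundary_pixels(gt).astype(float)
    d_pg = cKDTree(bg).query(bp)[0]
    d_gp = cKDTree(bp).query(bg)[0]
    return float(max(np.percentile(d_pg, 95), np.percentile(d_gp, 95))), False


def boundary_iou(pred, gt, kernel: int = 7) -> float:
    """IoU restricted to the ground-truth boundary band (dilation - erosion)."""
    pred, gt = _check_pair(pred, gt)
    band = boundary_band(gt, kernel).astype(bool)
    if not band.any():
        return 1.0 if np.array_equal(pred, gt) else 0.0
    inter = (pred & gt & band).sum()
    union = ((pred | gt) & band).sum()
    return 1.0 if union == 0 else float(inter / union)


def compute_record(sample_id: str, pred, gt, band_kernel: int = 7) -> MetricsRecord:
    dsc, iou, rec, prec, spec = overlap_metrics(pred, gt)
    h, sent = hd95(pred, gt)
    return MetricsRecord(
        id=sample_id,
        dsc=dsc,
        iou=iou,
        b_iou=boundary_iou(pred, gt, band_kernel),
        recall=rec,
        precision=prec,
        specificity=spec,
        hd95=h,
        hd95_sentinel=sent,
    )


METRIC_NAMES = ("dsc", "iou", "b_iou", "recall", "precision", "specificity", "hd95")


@dataclass
class FoldSummary:
    fold_means: pd.DataFrame  # index fold, columns METRIC_NAMES
    mean: dict
    sd: dict
    ci_low: dict
    ci_high: dict
    n_folds: int


def fold_aggregate(records: list[MetricsRecord], fold_of_id: dict[str, int]) -> FoldSummary:
    """Per-image -> per-fold mean -> cross-fold mean +/- SD with 95% t-CI."""
    rows = []
    for r in records:
        if r.id not in fold_of_id:
            raise KeyError(f"record id {r.id!r} has no fold assignment")
        d = r.as_dict()
        d["fold"] = fold_of_id[r.id]
        rows.append(d)
    df = pd.DataFrame(rows)
    fold_means = df.groupby("fold")[list(METRIC_NAMES)].mean().sort_index()
    n = len(fold_means)
    mean = fold_means.mean().to_dict()
    sd = fold_means.std(ddof=1).to_dict() if n > 1 else {k: 0.0 for k in METRIC_NAMES}
    if n > 1:
        tcrit = stats.t.ppf(0.975, df=n - 1)
        half = {k: tcrit * sd[k] / np.sqrt(n) for k in METRIC_NAMES}
    else:
        half = {k: 0.0 for k in METRIC_NAMES}
    return FoldSummary(
        fold_means=fold_means,
        mean=mean,
        sd={k: float(0.0 if np.isnan(sd[k]) else sd[k]) for k in METRIC_NAMES},
        ci_low={k: mean[k] - half[k] for k in METRIC_NAMES},
        ci_high={k: mean[k] + half[k] for k in METRIC_NAMES},
        n_folds=n,
    )


@dataclass
class ComparisonResult:
    mean_diff: float
    t_stat: float
    t_p: float
    wilcoxon_stat: float
    wilcoxon_p: float
    cohens_d: float  # nan when differences have zero variance
    d_label: str
    p_bonferroni: float
    shapiro_p: float
    n: int
    degenerate: bool = False


def effect_size_label(d: float) -> str:
    if np.isnan(d):
        return "undefined"
    a = abs(d)
    if a < 0.2:
        return "negligible"
    if a < 0.5:
        return "small"
    if a < 0.8:
        return "medium"
    return "large"


def paired_compare(a, b, bonferroni_m: int = 1) -> ComparisonResult:
    """Paired comparison of two models' per-item metric values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length 1-D arrays with n >= 3")
    diff = a - b
    n = len(diff)
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    degenerate = sd == 0.0
    if degenerate:
        d = UNDEFINED
        t_stat, t_p = UNDEFINED, 1.0 if mean_diff == 0 else 0.0
        w_stat, w_p = UNDEFINED, 1.0
        shapiro_p = UNDEFINED
    else:
        d = mean_diff / sd
        t_stat, t_p = stats.ttest_rel(a, b)
        nz = diff[diff != 0]
        if len(nz) == 0:
            w_stat, w_p = UNDEFINED, 1.0  # all-zero differences: drop-zeros rule
        else:
            method = "exact" if n <= 25 else "auto"
            res = stats.wilcoxon(a, b, zero_method="wilcox", method=method, alternative="two-sided")
            w_stat, w_p = float(res.statistic), float(res.pvalue)
        shapiro_p = float(stats.shapiro(diff).pvalue) if len(np.unique(diff)) > 1 else UNDEFINED
    return ComparisonResult(
        mean_diff=mean_diff,
        t_stat=float(t_stat),
        t_p=float(t_p),
        wilcoxon_stat=w_stat,
        wilcoxon_p=w_p,
        cohens_d=float(d),
        d_label=effect_size_label(d),
        p_bonferroni=float(min(1.0, w_p * bonferroni_m)),
        shapiro_p=shapiro_p,
        n=n,
        degenerate=degenerate,
    )


def friedman_rank(matrix):
    """Friedman test over an (items x models) matrix.

    Ranks within each item (average ranks for ties; rank 1 = smallest
    value), then  chi2 = 12/(n k (k+1)) * sum_j R_j^2 - 3 n (k+1).
    Returns (chi2, mean_ranks, p).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need an (items >= 2) x (models >= 2) matrix")
    n, k = X.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    R = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float((R**2).sum()) - 3.0 * n * (k + 1)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return float(chi2), ranks.mean(axis=0), p


def difficulty_strata(dsc_a: dict, dsc_b: dict, gt_masks: dict, hard_quantile: float = 0.25):
    """Stratified mean DSC differences (model a - model b).

    Strata: tumor-size terciles by ground-truth area fraction, and a
    hard/easy split at the ``hard_quantile`` DSC percentile of model b
    (the reference).  Returns a dict of stratum -> (mean_diff, n).
    """
    ids = sorted(dsc_a)
    if set(ids) != set(dsc_b) or not set(ids) <= set(gt_masks):
        raise ValueError("id sets of the two models and the masks must align")
    areas = np.array([np.asarray(gt_masks[i]).mean() for i in ids])
    da = np.array([dsc_a[i] for i in ids])
    db = np.array([dsc_b[i] for i in ids])
    t1, t2 = np.quantile(areas, [1 / 3, 2 / 3])
    size_bins = np.where(areas <= t1, "small", np.where(areas <= t2, "medium", "large"))
    out = {}
    for name in ("small", "medium", "large"):
        sel = size_bins == name
        out[f"size_{name}"] = (float((da[sel] - db[sel]).mean()) if sel.any() else UNDEFINED, int(sel.sum()))
    thr = np.quantile(db, hard_quantile)
    hard = db <= thr
    out["hard"] = (float((da[hard] - db[hard]).mean()) if hard.any() else UNDEFINED, int(hard.sum()))
    out["easy"] = (float((da[~hard] - db[~hard]).mean()) if (~hard).any() else UNDEFINED, int((~hard).sum()))
    return out
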