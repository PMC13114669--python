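"""Segmentation metrics and the statistical battery."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import cdist

from busseg import metrics as met


def brute_force_hd95(pred, gt):
    """All-pairs oracle for the 95th-percentile Hausdorff distance."""
    bp = met.boundary_pixels(pred).astype(float)
    bg = met.boundary_pixels(gt).astype(float)
    D = cdist(bp, bg)
    return max(np.percentile(D.min(axis=1), 95), np.percentile(D.min(axis=0), 95))


class TestOverlapMetrics:
    def test_perfect_prediction(self):
        m = np.zeros((10, 10), bool)
        m[2:5, 2:5] = True
        assert met.overlap_metrics(m, m) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_partial_overlap_arithmetic(self):
        gt = np.zeros((4, 4), bool)
        pred = np.zeros((4, 4), bool)
        gt[0, :4] = True  # |gt| = 4
        pred[0, 2:4] = pred[1, 0:2] = True  # |pred| = 4, overlap 2
        dsc, iou, *_ = met.overlap_metrics(pred, gt)
        assert dsc == pytest.approx(0.5)
        assert iou == pytest.approx(1 / 3)

    def test_empty_pred_nonempty_gt(self):
        gt = np.zeros((5, 5), bool)
        gt[2, 2] = True
        dsc, iou, rec, prec, spec = met.overlap_metrics(np.zeros((5, 5), bool), gt)
        assert (dsc, iou, rec, prec) == (0.0, 0.0, 0.0, 0.0)
        assert spec == 1.0

    def test_both_empty_convention(self):
        z = np.zeros((5, 5), bool)
        dsc, iou, *_ = met.overlap_metrics(z, z)
        assert dsc == 1.0 and iou == 1.0

    def test_dsc_iou_identity_random(self, rng):
        for _ in range(100):
            a = rng.random((16, 16)) > 0.5
            b = rng.random((16, 16)) > 0.5
            dsc, iou, *_ = met.overlap_metrics(a, b)
            assert dsc == pytest.approx(2 * iou / (1 + iou), abs=1e-9)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            met.overlap_metrics(np.zeros((3, 3)), np.zeros((4, 4)))


class TestHd95:
    def test_identical_masks_zero(self):
        m = np.zeros((12, 12), bool)
        m[3:7, 4:9] = True
        assert met.hd95(m, m) == (0.0, False)

    def test_single_pixel_euclidean(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[0, 0] = True
        b[3, 4] = True
        assert met.hd95(a, b)[0] == pytest.approx(5.0)

    def test_matches_brute_force_oracle(self, rng):
        n_checked = 0
        for _ in range(100):
            a = rng.random((32, 32)) > 0.7
            b = rng.random((32, 32)) > 0.7
            if not (a.any() and b.any()):
                continue
            v, sent = met.hd95(a, b)
            assert not sent
            assert v == pytest.approx(brute_force_hd95(a, b), abs=1e-9)
            n_checked += 1
        assert n_checked > 90

    def test_symmetry_and_translation_invariance(self, rng):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[4:8, 4:8] = True
        b[10:13, 9:14] = True
        assert met.hd95(a, b)[0] == met.hd95(b, a)[0]
        assert met.hd95(np.roll(a, 3, 1), np.roll(b, 3, 1))[0] == pytest.approx(met.hd95(a, b)[0])

    def test_empty_sentinels(self):
        z = np.zeros((10, 10), bool)
        m = z.copy()
        m[5, 5] = True
        assert met.hd95(z, z) == (0.0, False)
        v, sent = met.hd95(z, m)
        assert sent and v == pytest.approx(np.hypot(10, 10))


class TestBoundaryIoU:
    def test_identical_masks(self):
        m = np.zeros((15, 15), bool)
        m[5:10, 5:10] = True
        assert met.boundary_iou(m, m) == 1.0

    def test_empty_pred(self):
        m = np.zeros((15, 15), bool)
        m[5:10, 5:10] = True
        assert met.boundary_iou(np.zeros_like(m), m) == 0.0

    def test_shifted_square_hand_count(self):
        from busseg.losses import boundary_band

        gt = np.zeros((15, 15), bool)
        gt[5:10, 5:10] = True  # centered 5x5
        pred = np.zeros((15, 15), bool)
        pred[5:10, 6:11] = True  # shifted right by 1
        band = boundary_band(gt, 7).astype(bool)
        inter = (pred & gt & band).sum()
        union = ((pred | gt) & band).sum()
        assert met.boundary_iou(pred, gt, 7) == pytest.approx(inter / union)
        # independent set-arithmetic count: the 7x7 band around a 5x5
        # square covers everything (erosion empty), so band is the 11x11
        # dilation square; intersection is the 5x4 overlap strip
        assert inter == 20
        assert union == 30
        assert met.boundary_iou(pred, gt, 7) == pytest.approx(2 / 3)

    def test_band_covering_image_equals_plain_iou(self, rng):
        gt = rng.random((9, 9)) > 0.45  # dense mask: band covers everything
        from busseg.losses import boundary_band

        if boundary_band(gt, 7).all():
            pred = rng.random((9, 9)) > 0.5
            _, iou, *_ = met.overlap_metrics(pred, gt)
            assert met.boundary_iou(pred, gt, 7) == pytest.approx(iou)


class TestFoldAggregate:
    def _records(self, values, ids=None):
        ids = ids or [f"s{i}" for i in range(len(values))]
        return [
            met.MetricsRecord(id=i, dsc=v, iou=v, b_iou=v, recall=v, precision=v, specificity=v, hd95=1.0)
            for i, v in zip(ids, values)
        ]

    def test_identical_values_zero_sd(self):
        recs = self._records([0.5] * 10)
        folds = {f"s{i}": i % 5 for i in range(10)}
        s = met.fold_aggregate(recs, folds)
        assert s.mean["dsc"] == pytest.approx(0.5)
        assert s.sd["dsc"] == 0.0
        assert s.ci_low["dsc"] == pytest.approx(0.5)

    def test_t_interval_arithmetic(self):
        fold_means = [0.89, 0.90, 0.91, 0.90, 0.905]
        recs = self._records(fold_means)
        folds = {f"s{i}": i for i in range(5)}
        s = met.fold_aggregate(recs, folds)
        assert s.mean["dsc"] == pytest.approx(0.901)
        sd = np.std(fold_means, ddof=1)
        assert s.sd["dsc"] == pytest.approx(sd)
        half = stats.t.ppf(0.975, 4) * sd / np.sqrt(5)
        assert stats.t.ppf(0.975, 4) == pytest.approx(2.776, abs=5e-4)
        assert s.ci_high["dsc"] - s.mean["dsc"] == pytest.approx(half)

    def test_permutation_invariance(self, rng):
        vals = rng.random(12)
        recs = self._records(list(vals))
        folds = {f"s{i}": i % 3 for i in range(12)}
        s1 = met.fold_aggregate(recs, folds)
        s2 = met.fold_aggregate(recs[::-1], folds)
        assert s1.mean == s2.mean and s1.sd == s2.sd

    def test_missing_fold_raises(self):
        with pytest.raises(KeyError):
            met.fold_aggregate(self._records([0.5]), {})


def exact_wilcoxon_p(diffs):
    """Full 2^n sign-enumeration oracle (zeros dropped, two-sided)."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    mean_w = n * (n + 1) / 4
    p = np.mean(np.abs(ws - mean_w) >= abs(w_obs - mean_w) - 1e-12)
    return p


class TestPairedCompare:
    def test_identical_series_degenerate(self):
        r = met.paired_compare([0.1, 0.2, 0.3, 0.4], [0.1, 0.2, 0.3, 0.4])
        assert r.mean_diff == 0.0
        assert r.wilcoxon_p == 1.0
        assert np.isnan(r.cohens_d)
        assert r.d_label == "undefined"
        assert r.degenerate

    def test_n5_all_positive_exact_p(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a - np.array([0.1, 0.2, 0.3, 0.15, 0.25])
        r = met.paired_compare(a, b)
        assert r.wilcoxon_p == pytest.approx(2 / 32)

    def test_cohens_d_arithmetic(self):
        diffs = np.array([0.01, 0.02, 0.03, 0.02, 0.02])
        b = np.zeros(5)
        r = met.paired_compare(diffs, b)
        assert r.mean_diff == pytest.approx(0.02)
        assert r.cohens_d == pytest.approx(0.02 / np.std(diffs, ddof=1), rel=1e-6)
        assert r.cohens_d == pytest.approx(2.828, abs=5e-3)
        assert r.d_label == "large"

    def test_exact_p_matches_sign_enumeration(self, rng):
        for n in (4, 6, 8, 10):
            a = rng.standard_normal(n)
            b = a + rng.standard_normal(n) * 0.5
            r = met.paired_compare(a, b)
            assert r.wilcoxon_p == pytest.approx(exact_wilcoxon_p(a - b), abs=1e-12)

    def test_bonferroni(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a - 0.1
        r = met.paired_compare(a, b, bonferroni_m=10)
        assert r.p_bonferroni == pytest.approx(min(1.0, r.wilcoxon_p * 10))

    def test_effect_size_labels(self):
        assert met.effect_size_label(0.1) == "negligible"
        assert met.effect_size_label(-0.3) == "small"
        assert met.effect_size_label(0.65) == "medium"
        assert met.effect_size_label(-2.0) == "large"


class TestFriedman:
    def test_identical_models_zero(self):
        X = np.tile(np.arange(5.0)[:, None], (1, 3))
        chi2, ranks, p = met.friedman_rank(X)
        assert chi2 == pytest.approx(0.0)

    def test_consistent_ordering_fixture(self):
        # 10 items, 3 models, same ordering per item -> chi2 = 20
        X = np.arange(30.0).reshape(10, 3)
        chi2, ranks, p = met.friedman_rank(X)
        assert chi2 == pytest.approx(20.0)
        assert np.allclose(ranks, [1, 2, 3])

    def test_monotone_invariance(self, rng):
        X = rng.random((8, 4))
        chi2a, _, _ = met.friedman_rank(X)
        chi2b, _, _ = met.friedman_rank(np.exp(3 * X))
        assert chi2a == pytest.approx(chi2b)

    def test_matches_scipy_without_ties(self, rng):
        X = rng.standard_normal((12, 4))
        chi2, _, p = met.friedman_rank(X)
        ref = stats.friedmanchisquare(*[X[:, j] for j in range(4)])
        assert chi2 == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestDifficultyStrata:
    def _masks(self, rng, n, sizes):
        masks = {}
        for i, frac in enumerate(sizes):
            m = np.zeros((32, 32), np.uint8)
            side = max(1, int(np.sqrt(frac * 1024)))
            m[:side, :side] = 1
            masks[f"s{i}"] = m
        return masks

    def test_identical_models_zero_differences(self, rng):
        n = 12
        sizes = np.linspace(0.02, 0.3, n)
        masks = self._masks(rng, n, sizes)
        dsc = {f"s{i}": float(v) for i, v in enumerate(rng.uniform(0.5, 0.95, n))}
        out = met.difficulty_strata(dsc, dsc, masks)
        for k, (d, cnt) in out.items():
            assert d == pytest.approx(0.0)

    def test_strata_partition_and_planted_effect(self, rng):
        n = 30
        sizes = np.linspace(0.02, 0.3, n)
        masks = self._masks(rng, n, sizes)
        base = {f"s{i}": float(v) for i, v in enumerate(rng.uniform(0.6, 0.9, n))}
        # model A = base + 0.01 only on the small-size tercile (thresholds
        # computed on the rasterized mask areas, like the implementation)
        areas = {k: m.mean() for k, m in masks.items()}
        small_thr = np.quantile(list(areas.values()), 1 / 3)
        boosted = {k: v + (0.01 if areas[k] <= small_thr else 0.0) for k, v in base.items()}
        out = met.difficulty_strata(boosted, base, masks)
        sizes_sum = out["size_small"][1] + out["size_medium"][1] + out["size_large"][1]
        assert sizes_sum == n
        assert out["hard"][1] + out["easy"][1] == n
        assert out["size_small"][0] == pytest.approx(0.01, abs=1e-9)
        assert out["size_medium"][0] == pytest.approx(0.0, abs=1e-9)
        assert out["size_large"][0] == pytest.approx(0.0, abs=1e-9)
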