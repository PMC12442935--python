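"""Agreement statistics against hand arithmetic and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from endovia.metrics import (
    ConfusionCounts,
    bland_altman,
    bootstrap_ci,
    confusion,
    continuous_agreement,
    hausdorff_distances,
    overlap_metrics,
    pearson,
    rotation_homoscedasticity,
)
from endovia.raster import BinaryMask
from endovia.rings import outer_boundary


def naive_confusion(pred, truth, region):
    """Pixel-by-pixel loop, independent of the vectorized implementation."""
    tp = fp = fn = tn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            if not region.membership[i, j]:
                continue
            p, t = pred.membership[i, j], truth.membership[i, j]
            tp += p and t
            fp += p and not t
            fn += t and not p
            tn += not p and not t
    return ConfusionCounts(tp, fp, fn, tn)


def naive_hausdorff(pred, truth):
    """All-pairs directed distances between boundary point sets."""
    a = np.argwhere(outer_boundary(pred)).astype(float)
    b = np.argwhere(outer_boundary(truth)).astype(float)
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
    d_ab = d.min(axis=1)
    d_ba = d.min(axis=0)
    return max(d_ab.max(), d_ba.max()), max(d_ab.mean(), d_ba.mean())


class TestConfusionAndOverlap:
    def test_identity_and_anticomplement(self, rng):
        m = BinaryMask(rng.random((8, 8)) < 0.5)
        region = BinaryMask(np.ones((8, 8), bool))
        c = confusion(m, m, region)
        assert c.fp == 0 and c.fn == 0
        anti = BinaryMask(~m.membership)
        c2 = confusion(anti, m, region)
        assert c2.tp == 0 and c2.tn == 0

    def test_4x4_matches_enumeration(self, rng):
        for _ in range(5):
            pred = BinaryMask(rng.random((4, 4)) < 0.5)
            truth = BinaryMask(rng.random((4, 4)) < 0.5)
            region = BinaryMask(rng.random((4, 4)) < 0.7)
            assert confusion(pred, truth, region) == naive_confusion(pred, truth, region)

    def test_identical_masks_all_ones(self):
        s = overlap_metrics(ConfusionCounts(tp=10, fp=0, fn=0, tn=20))
        assert (
            s.precision == s.recall == s.balanced_accuracy == s.dice == s.iou == 1.0
        )

    def test_half_overlap_dice_and_iou(self):
        # |pred| = |truth| = 100, overlap 50
        s = overlap_metrics(ConfusionCounts(tp=50, fp=50, fn=50, tn=300))
        assert s.dice == pytest.approx(0.5)
        assert s.iou == pytest.approx(1 / 3)

    def test_degenerate_denominators_flagged(self):
        s = overlap_metrics(ConfusionCounts(tp=0, fp=0, fn=5, tn=10))
        assert s.precision is None and "precision" in s.undefined
        assert s.recall == 0

    def test_dice_iou_identity_and_symmetry(self, rng):
        """dice = 2·iou/(1+iou); dice/iou symmetric; precision↔recall swap."""
        region = BinaryMask(np.ones((16, 16), bool))
        for _ in range(10):
            pred = BinaryMask(rng.random((16, 16)) < 0.4)
            truth = BinaryMask(rng.random((16, 16)) < 0.4)
            s = overlap_metrics(confusion(pred, truth, region))
            t = overlap_metrics(confusion(truth, pred, region))
            if s.iou is not None:
                assert s.dice == pytest.approx(2 * s.iou / (1 + s.iou))
                assert s.dice == pytest.approx(t.dice)
                assert s.iou == pytest.approx(t.iou)
            if s.precision is not None and t.recall is not None:
                assert s.precision == pytest.approx(t.recall)


class TestHausdorff:
    def test_identical_masks_zero(self, rng):
        m = BinaryMask(rng.random((12, 12)) < 0.4)
        if m.is_empty():
            m = BinaryMask(np.ones((12, 12), bool))
        h = hausdorff_distances(m, m)
        assert h.std_px == 0 and h.mod_px == 0

    def test_singletons_five_apart(self):
        a = np.zeros((12, 12), bool)
        b = np.zeros((12, 12), bool)
        a[3, 2] = True
        b[3, 7] = True
        h = hausdorff_distances(BinaryMask(a), BinaryMask(b))
        assert h.std_px == 5 and h.mod_px == 5

    def test_translated_square_matches_allpairs_oracle(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[5:10, 5:10] = True
        b[5:10, 8:13] = True
        h = hausdorff_distances(BinaryMask(a), BinaryMask(b))
        std, mod = naive_hausdorff(BinaryMask(a), BinaryMask(b))
        assert h.std_px == pytest.approx(std)
        assert h.mod_px == pytest.approx(mod)
        assert h.std_px == pytest.approx(3)

    def test_random_masks_match_oracle_and_mod_le_std(self, rng):
        for _ in range(8):
            a = BinaryMask(rng.random((16, 16)) < 0.35)
            b = BinaryMask(rng.random((16, 16)) < 0.35)
            if a.is_empty() or b.is_empty():
                continue
            h = hausdorff_distances(a, b)
            std, mod = naive_hausdorff(a, b)
            assert h.std_px == pytest.approx(std)
            assert h.mod_px == pytest.approx(mod)
            assert h.mod_px <= h.std_px + 1e-12

    def test_empty_mask_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            hausdorff_distances(
                BinaryMask(np.zeros((4, 4), bool)), BinaryMask(np.ones((4, 4), bool))
            )

    def test_mm_scaling(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[2, 2], b[2, 6] = True, True
        h = hausdorff_distances(BinaryMask(a), BinaryMask(b), mm_per_pixel=0.05)
        assert h.std_mm == pytest.approx(0.2)


class TestContinuousAgreement:
    def test_identical_vectors(self):
        mae, rmse, r2 = continuous_agreement([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert (mae, rmse, r2) == (0, 0, 1)

    def test_constant_offset(self):
        t = np.array([0.1, 0.2, 0.3, 0.4])
        mae, rmse, _ = continuous_agreement(t + 0.02, t)
        assert mae == pytest.approx(0.02)
        assert rmse == pytest.approx(0.02)

    def test_hand_computed_five_elements(self):
        truth = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        pred = np.array([1.5, 1.5, 3.5, 3.5, 5.5])
        # |d| = .5 each -> mae .5 ; rmse .5 ; SSres = 5*.25 ; SStot = 10
        mae, rmse, r2 = continuous_agreement(pred, truth)
        assert mae == pytest.approx(0.5)
        assert rmse == pytest.approx(0.5)
        assert r2 == pytest.approx(1 - 1.25 / 10)

    def test_constant_truth_r2_undefined(self):
        _, _, r2 = continuous_agreement([1.0, 2.0], [3.0, 3.0])
        assert r2 is None


class TestBootstrap:
    def test_constant_data_point_interval(self):
        lo, hi = bootstrap_ci(np.full(10, 4.2), np.mean, seed=0)
        assert lo == hi == pytest.approx(4.2)

    def test_seed_reproducible(self, rng):
        x = rng.normal(size=30)
        assert bootstrap_ci(x, np.mean, seed=7) == bootstrap_ci(x, np.mean, seed=7)

    def test_paired_resampling(self, rng):
        x = rng.normal(size=25)
        y = x + rng.normal(scale=0.1, size=25)
        lo, hi = bootstrap_ci(
            (x, y), lambda a, b: float(np.corrcoef(a, b)[0, 1]), seed=3
        )
        assert 0.9 < lo <= hi <= 1.0


class TestBlandAltmanPearson:
    def test_equal_methods(self):
        c = bland_altman([1, 2, 3.0], [1, 2, 3.0])
        assert c.mean_difference == 0
        assert c.loa_low == 0 and c.loa_high == 0

    def test_constant_offset(self):
        a = np.array([1.0, 2, 3, 4])
        c = bland_altman(a, a + 5)
        assert c.mean_difference == pytest.approx(5)
        assert c.loa_low == pytest.approx(5) and c.loa_high == pytest.approx(5)

    def test_hand_arithmetic_six_elements(self):
        a = np.array([10.0, 12, 8, 9, 11, 10])
        b = np.array([11.0, 14, 9, 9, 13, 10])
        d = b - a  # 1 2 1 0 2 0 -> mean 1, sd = sqrt(4/5)
        c = bland_altman(a, b)
        assert c.mean_difference == pytest.approx(1.0)
        sd = np.sqrt(4 / 5)
        assert c.sd_difference == pytest.approx(sd)
        assert c.loa_low == pytest.approx(1 - 1.96 * sd)
        assert c.loa_high == pytest.approx(1 + 1.96 * sd)

    def test_loa_cover_95pct_of_normal_differences(self, rng):
        a = rng.normal(size=4000)
        b = a + rng.normal(size=4000)
        c = bland_altman(a, b)
        d = b - a
        frac = np.mean((d >= c.loa_low) & (d <= c.loa_high))
        assert frac == pytest.approx(0.95, abs=0.02)

    def test_pearson_perfect_lines(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert pearson(x, 2 * x)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_pearson_hand_data(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        rho, p = pearson(x, y)
        assert rho == pytest.approx(num / den)
        assert 0 < p < 1

    def test_pearson_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1.0, 1, 1], [1.0, 2, 3])


def _levene_mean_W(groups):
    """Hand-evaluated classic Levene statistic (mean-centered)."""
    z = [np.abs(np.asarray(g, float) - np.mean(g)) for g in groups]
    zi = [g.mean() for g in z]
    zbar = np.concatenate(z).mean()
    k = len(groups)
    n = sum(len(g) for g in groups)
    num = sum(len(g) * (m - zbar) ** 2 for g, m in zip(groups, zi))
    den = sum(((g - m) ** 2).sum() for g, m in zip(z, zi))
    return (n - k) / (k - 1) * num / den


class TestLevene:
    def _table(self, values_by_rotation, ring=1):
        rows = []
        for rot, vals in values_by_rotation.items():
            for i, v in enumerate(vals):
                rows.append(
                    {"tissue_id": i, "rotation_deg": rot, "ring": ring, "mortality_pct": v}
                )
        return pd.DataFrame(rows)

    def test_identical_rotations_p_one(self):
        vals = [3.0, 9.0, 15.0]
        df = self._table({0: vals, 90: vals, 180: vals, 270: vals})
        res = rotation_homoscedasticity(df)
        assert res.loc[0, "levene_W"] == 0
        assert res.loc[0, "levene_p"] == 1

    def test_matches_hand_formula(self):
        g0 = [0.0, 2.0, 1.0, 3.0]
        g90 = [0.0, 1.0, 2.0, 5.0]
        df = self._table({0: g0, 90: g90})
        res = rotation_homoscedasticity(df)
        # z-scoring is affine and common to both groups: W is invariant to it
        assert res.loc[0, "levene_W"] == pytest.approx(_levene_mean_W([g0, g90]))

    def test_needs_enough_groups(self):
        df = self._table({0: [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="rotations"):
            rotation_homoscedasticity(df)
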