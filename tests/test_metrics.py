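import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omtcube.metrics import (
    confusion_metrics,
    dice_ce_loss,
    ensemble_vote,
    hd95,
    inverse_orientation,
    orientation_variants,
)


def brute_confusion(gt, pd):
    """Triple-loop confusion counts (oracle)."""
    tp = fp = fn = tn = 0
    for i in range(gt.shape[0]):
        for j in range(gt.shape[1]):
            for k in range(gt.shape[2]):
                g, p = gt[i, j, k], pd[i, j, k]
                if g and p:
                    tp += 1
                elif p:
                    fp += 1
                elif g:
                    fn += 1
                else:
                    tn += 1
    return tp, fp, fn, tn


def brute_surface(mask):
    pts = []
    sh = mask.shape
    for i in range(sh[0]):
        for j in range(sh[1]):
            for k in range(sh[2]):
                if not mask[i, j, k]:
                    continue
                for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    ii, jj, kk = i + d[0], j + d[1], k + d[2]
                    if not (0 <= ii < sh[0] and 0 <= jj < sh[1] and 0 <= kk < sh[2]) or not mask[ii, jj, kk]:
                        pts.append((i, j, k))
                        break
    return np.array(pts, dtype=float)


def brute_hd95(gt, pd, spacing):
    sg = brute_surface(gt) * spacing
    sp = brute_surface(pd) * spacing
    d_g = np.array([np.sqrt(((sp - p) ** 2).sum(axis=1)).min() for p in sg])
    d_p = np.array([np.sqrt(((sg - p) ** 2).sum(axis=1)).min() for p in sp])
    return max(np.percentile(d_g, 95), np.percentile(d_p, 95))


class TestOrientationVariants:
    def test_identity_first(self):
        rng = np.random.default_rng(0)
        cube = rng.random((6, 6, 6))
        variants = orientation_variants(cube)
        np.testing.assert_array_equal(variants[0], cube)

    def test_rotation_order_four(self):
        rng = np.random.default_rng(1)
        cube = rng.random((6, 6, 6))
        out = cube
        for _ in range(4):
            out = orientation_variants(out)[1]
        np.testing.assert_array_equal(out, cube)

    @pytest.mark.parametrize("mu", [2, 3])
    def test_mirror_involution(self, mu, ):
        rng = np.random.default_rng(2)
        cube = rng.random((6, 6, 6))
        twice = orientation_variants(orientation_variants(cube)[mu])[mu]
        np.testing.assert_array_equal(twice, cube)

    @pytest.mark.parametrize("mu", range(5))
    def test_inverse_registered(self, mu):
        rng = np.random.default_rng(3)
        cube = rng.random((6, 6, 6))
        np.testing.assert_array_equal(
            inverse_orientation(orientation_variants(cube)[mu], mu), cube
        )

    def test_non_cubic_rejected(self):
        with pytest.raises(ValueError):
            orientation_variants(np.zeros((4, 4, 5)))


class TestEnsembleVote:
    def _sets(self, base, rng):
        sets = {}
        for nu in (1, 2, 3):
            for mu in range(5):
                sets[(mu, nu)] = base.copy()
        return sets

    def test_identical_inputs_vote_to_input(self):
        rng = np.random.default_rng(0)
        base = rng.random((8, 8, 8))
        voted, info = ensemble_vote(self._sets(base, rng))
        np.testing.assert_allclose(voted, base)
        assert info["N"] == 15

    def test_low_dice_set_excluded(self):
        rng = np.random.default_rng(1)
        base = (rng.random((8, 8, 8)) > 0.5).astype(float)
        sets = self._sets(base, rng)
        # an input agreeing on only ~half the positives has Dice ~ 0.5
        bad = base.copy().ravel()
        on = np.flatnonzero(bad >= 0.5)
        bad[on[: len(on) // 2]] = 0.0
        off = np.flatnonzero(bad < 0.5)
        bad[off[: len(on) // 2]] = 1.0
        sets[(2, 2)] = bad.reshape(base.shape)
        d = 2 * (base.astype(bool) & (sets[(2, 2)] >= 0.5)).sum() / (
            base.sum() + (sets[(2, 2)] >= 0.5).sum()
        )
        assert d < 0.8
        voted, info = ensemble_vote(sets)
        assert info["alpha"][(2, 2)] == 0
        assert info["N"] == 14
        np.testing.assert_allclose(voted, base)

    def test_two_value_mean(self):
        # two included sets with 0.6 and 0.8 at a voxel vote to 0.7
        b = np.full((2, 2, 2), 0.8)
        a2 = np.full((2, 2, 2), 0.6)
        voted, info = ensemble_vote({(0, 1): a2, (1, 1): b})
        np.testing.assert_allclose(voted, (0.6 + 0.8) / 2)
        assert info["N"] == 2

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            ensemble_vote({(1, 1): np.zeros((2, 2, 2))})


class TestConfusionMetrics:
    def test_perfect_overlap(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[1:3, 1:3, 1:3] = True
        rep = confusion_metrics(m, m)
        assert rep.dice == rep.sensitivity == rep.precision == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros((4, 4, 4), dtype=bool)
        a[0, 0, 0] = True
        b[1, 1, 1] = True
        assert confusion_metrics(a, b).dice == 0.0

    def test_half_overlap_counts(self):
        gt = np.zeros((20, 1, 1), dtype=bool)
        pd = np.zeros((20, 1, 1), dtype=bool)
        gt[:10] = True
        pd[5:15] = True
        rep = confusion_metrics(gt, pd)
        assert rep.dice == 0.5
        assert rep.sensitivity == 0.5
        assert rep.precision == 0.5

    def test_empty_conventions(self):
        z = np.zeros((3, 3, 3), dtype=bool)
        rep = confusion_metrics(z, z)
        assert rep.dice == 1.0
        assert rep.sensitivity is None
        assert rep.precision is None
        assert rep.specificity == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(3, 9, 3))
        gt = rng.random(shape) > 0.6
        pd = rng.random(shape) > 0.6
        rep = confusion_metrics(gt, pd)
        tp, fp, fn, tn = brute_confusion(gt, pd)
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (tp, fp, fn, tn)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            confusion_metrics(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))


class TestHd95:
    def test_identical_sets_zero(self):
        m = np.zeros((6, 6, 6), dtype=bool)
        m[2:5, 2:5, 2:5] = True
        assert hd95(m, m) == 0.0

    def test_shifted_block(self):
        gt = np.zeros((14, 14, 14), dtype=bool)
        pd = np.zeros((14, 14, 14), dtype=bool)
        gt[2:12, 2:12, 2:12] = True
        pd[3:13, 2:12, 2:12] = True
        assert hd95(gt, pd) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        gt = np.zeros((9, 9, 9), dtype=bool)
        pd = np.zeros((9, 9, 9), dtype=bool)
        gt[tuple(rng.integers(1, 8, (3, 25)))] = True
        pd[tuple(rng.integers(1, 8, (3, 25)))] = True
        spacing = (1.0, 1.5, 2.0)
        assert hd95(gt, pd, spacing) == pytest.approx(
            brute_hd95(gt, pd, np.asarray(spacing)), rel=1e-12
        )

    def test_empty_set_rejected(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        f = m.copy()
        f[1, 1, 1] = True
        with pytest.raises(ValueError):
            hd95(m, f)

    def test_hd95_not_above_max(self):
        rng = np.random.default_rng(5)
        gt = rng.random((8, 8, 8)) > 0.7
        pd = rng.random((8, 8, 8)) > 0.7
        if gt.any() and pd.any():
            sg = brute_surface(gt)
            sp = brute_surface(pd)
            hd100 = max(
                max(np.sqrt(((sp - p) ** 2).sum(axis=1)).min() for p in sg),
                max(np.sqrt(((sg - p) ** 2).sum(axis=1)).min() for p in sp),
            )
            assert hd95(gt, pd) <= hd100 + 1e-12


class TestDiceCeLoss:
    def test_perfect_prediction(self):
        gt = np.zeros((4, 4, 4))
        gt[1:3, 1:3, 1:3] = 1.0
        loss = dice_ce_loss(gt, gt)
        assert loss == pytest.approx(0.0, abs=1e-5)

    def test_half_probability_ce(self):
        gt = np.zeros((4, 4, 4))
        gt[0, 0, :3] = 1.0  # k = 3 one-hot voxels
        pd = np.full((4, 4, 4), 0.5)
        loss = dice_ce_loss(gt, pd)
        k = 3
        expected_ce = k * np.log(2)
        expected_dice = 1 - 2 * (k * 0.5) / (k + 0.5 * 64)
        assert loss == pytest.approx(expected_ce + expected_dice, rel=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        gt = (rng.random((4, 4, 4)) > 0.5).astype(float)
        pd = rng.random((4, 4, 4))
        assert dice_ce_loss(gt, pd) >= 0.0
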