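import numpy as np
import pytest
from scipy.spatial.distance import cdist

from pemt import asd, dice_jaccard, evaluate_masks, hd95
from pemt.metrics import surface


# -- independent brute-force oracle (no distance transform, no KD-tree) ----

def brute_surface(mask):
    mask = mask.astype(bool)
    out = np.zeros_like(mask)
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if not (0 <= ni < h and 0 <= nj < w) or not mask[ni, nj]:
                    out[i, j] = True
                    break
    return out


def brute_directed(p, y, spacing=(1.0, 1.0)):
    sp = np.argwhere(brute_surface(p)) * np.asarray(spacing)
    sy = np.argwhere(brute_surface(y)) * np.asarray(spacing)
    return cdist(sp, sy).min(axis=1)


def brute_hd95(p, y, spacing=(1.0, 1.0)):
    return max(np.percentile(brute_directed(p, y, spacing), 95),
               np.percentile(brute_directed(y, p, spacing), 95))


def brute_asd(p, y, spacing=(1.0, 1.0)):
    return brute_directed(p, y, spacing).mean()


def random_blob(rng, size=32):
    """A random nonempty blobby mask."""
    cy, cx = rng.uniform(6, size - 6, 2)
    ry, rx = rng.uniform(2, 8, 2)
    yy, xx = np.mgrid[0:size, 0:size]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


class TestDiceJaccard:
    def test_perfect_overlap(self):
        m = random_blob(np.random.default_rng(0))
        assert dice_jaccard(m, m) == (1.0, 1.0)

    def test_hand_value(self):
        p = np.zeros((4, 4), bool)
        y = np.zeros((4, 4), bool)
        p[0, :4] = True           # |p| = 4
        y[0, 2:] = True
        y[1, :2] = True           # |y| = 4, overlap 2
        dsc, jac = dice_jaccard(p, y)
        assert dsc == pytest.approx(0.5)
        assert jac == pytest.approx(1 / 3)

    def test_disjoint_masks(self):
        p = np.zeros((4, 4), bool)
        y = np.zeros((4, 4), bool)
        p[0, 0] = True
        y[3, 3] = True
        assert dice_jaccard(p, y) == (0.0, 0.0)

    def test_both_empty_is_perfect(self):
        z = np.zeros((5, 5), bool)
        assert dice_jaccard(z, z) == (1.0, 1.0)

    def test_dsc_jaccard_identity_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = rng.random((8, 8)) > 0.5
            y = rng.random((8, 8)) > 0.5
            dsc, jac = dice_jaccard(p, y)
            assert dsc == pytest.approx(2 * jac / (1 + jac), abs=1e-12)


class TestSurfaceDistances:
    def test_identical_masks_give_zero(self):
        m = random_blob(np.random.default_rng(1))
        assert hd95(m, m) == 0.0
        assert asd(m, m) == 0.0

    def test_single_pixel_offset_3_4(self):
        p = np.zeros((16, 16), bool)
        y = np.zeros((16, 16), bool)
        p[2, 2] = True
        y[5, 6] = True           # offset (3, 4) -> distance 5
        assert hd95(p, y) == pytest.approx(5.0)
        assert asd(p, y) == pytest.approx(5.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        p = random_blob(rng, 24)
        y = random_blob(rng, 24)
        big_p = np.zeros((40, 40), bool)
        big_y = np.zeros((40, 40), bool)
        big_p[:24, :24] = p
        big_y[:24, :24] = y
        shifted_p = np.roll(big_p, (5, 7), axis=(0, 1))
        shifted_y = np.roll(big_y, (5, 7), axis=(0, 1))
        assert hd95(big_p, big_y) == pytest.approx(hd95(shifted_p, shifted_y))

    def test_hd95_symmetric(self):
        rng = np.random.default_rng(3)
        p = random_blob(rng)
        y = random_blob(rng)
        assert hd95(p, y) == pytest.approx(hd95(y, p))

    def test_asd_is_one_directional(self):
        p = np.zeros((8, 8), bool)
        y = np.zeros((8, 8), bool)
        p[2, 2] = True            # 1 surface pixel
        y[2, 4] = True
        y[2, 5] = True            # 2 surface pixels
        assert asd(p, y) == pytest.approx(brute_asd(p, y))
        assert asd(y, p) == pytest.approx(brute_asd(y, p))
        assert asd(p, y) != pytest.approx(asd(y, p))

    def test_empty_mask_rejected(self):
        m = random_blob(np.random.default_rng(4))
        with pytest.raises(ValueError):
            hd95(m, np.zeros_like(m))
        with pytest.raises(ValueError):
            asd(np.zeros_like(m), m)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = random_blob(rng)
        y = random_blob(rng)
        assert surface(p).sum() == brute_surface(p).sum()
        np.testing.assert_array_equal(surface(p), brute_surface(p))
        assert hd95(p, y) == pytest.approx(brute_hd95(p, y), abs=1e-9)
        assert asd(p, y) == pytest.approx(brute_asd(p, y), abs=1e-9)
        d, j = dice_jaccard(p, y)
        inter = (p & y).sum()
        assert d == pytest.approx(2 * inter / (p.sum() + y.sum()))
        assert j == pytest.approx(inter / (p.sum() + y.sum() - inter))

    def test_spacing_scales_distances(self):
        p = np.zeros((8, 8), bool)
        y = np.zeros((8, 8), bool)
        p[2, 2] = True
        y[2, 4] = True
        assert asd(p, y, spacing=(1.0, 2.5)) == pytest.approx(5.0)
        assert asd(p, y, spacing=(1.0, 2.5)) == pytest.approx(
            brute_asd(p, y, (1.0, 2.5)))

    def test_exact_hd_bounds_hd95(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            p = random_blob(rng)
            y = random_blob(rng)
            assert hd95(p, y, percentile=100) >= hd95(p, y) - 1e-12
            assert hd95(p, y) >= 0.0


class TestEvaluateMasks:
    def test_multiclass_macro_average(self):
        label = np.zeros((16, 16), int)
        label[2:6, 2:6] = 1
        label[10:14, 10:14] = 2
        pred = label.copy()
        rep = evaluate_masks(pred, label, num_classes=3)
        assert rep.dsc == 1.0 and rep.jac == 1.0
        assert rep.hd95 == 0.0 and rep.asd == 0.0

    def test_missing_class_excluded_from_surface_metrics(self):
        label = np.zeros((8, 8), int)
        label[2:4, 2:4] = 1        # class 2 absent everywhere
        pred = label.copy()
        rep = evaluate_masks(pred, label, num_classes=3)
        # overlap metrics average the empty-vs-empty convention (1.0)
        assert rep.dsc == 1.0
        assert rep.hd95 == 0.0     # only class 1 contributes
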