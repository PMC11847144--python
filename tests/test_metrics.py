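"""Evaluation metrics vs independent brute-force oracles and hand values."""

import math

import numpy as np
import pytest

from mdoi.metrics import (BHATTACHARYYA_CAP, MSSSIMConfig, bhattacharyya,
                          contrast, evaluate_case, msssim_volume,
                          normalize_for_comparison, reconstructed_depth,
                          rmse, seg_scores)

# ---------------------------------------------------------------------------
# independent oracles: direct loops, no shared code with the implementation


def oracle_rmse(a, b):
    s = 0.0
    n = 0
    for x, y in zip(a.ravel(), b.ravel()):
        s += (x - y) ** 2
        n += 1
    return math.sqrt(s / n)


def oracle_bhattacharyya(a, b, n_bins):
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        hi = lo + 1.0
    width = (hi - lo) / n_bins
    p = [0] * n_bins
    q = [0] * n_bins
    for x in a.ravel():
        k = min(int((x - lo) / width), n_bins - 1)
        p[k] += 1
    for x in b.ravel():
        k = min(int((x - lo) / width), n_bins - 1)
        q[k] += 1
    bc = sum(math.sqrt((pi / a.size) * (qi / b.size))
             for pi, qi in zip(p, q))
    return -math.log(bc) if bc > 0 else None


def oracle_contrast(vol, frac=0.2):
    vals = sorted(vol.ravel().tolist())
    k = max(1, int(math.floor(frac * len(vals))))
    bg = sum(vals[:k]) / k
    ft = sum(vals[-k:]) / k
    return (ft - bg) / bg


def oracle_depth(mask, dz, frac=0.01):
    depths = sorted((k + 0.5) * dz for (_, _, k) in zip(*np.nonzero(mask)))
    if not depths:
        return None
    k = max(1, int(math.floor(frac * len(depths))))
    tail = depths[-k:]
    return sum(tail) / len(tail)


def oracle_seg(gt, seg):
    tp = tn = fp = fn = 0
    for g, s in zip(gt.ravel(), seg.ravel()):
        if g and s:
            tp += 1
        elif g and not s:
            fn += 1
        elif not g and s:
            fp += 1
        else:
            tn += 1
    return (tn / (tn + fp), tp / (tp + fn),
            2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0)


def oracle_ssim_single_scale(x, y, cfg):
    """Direct windowed SSIM with explicit Gaussian kernel and symmetric
    padding (matches scipy's 'reflect'), M = 1."""
    half = cfg.window // 2
    ax = np.arange(-half, half + 1)
    k1 = np.exp(-ax**2 / (2 * cfg.sigma**2))
    k1 /= k1.sum()
    kern = np.outer(k1, k1)

    def win_stats(img):
        pad = np.pad(img, half, mode="symmetric")
        mu = np.empty_like(img, dtype=float)
        m2 = np.empty_like(img, dtype=float)
        for i in range(img.shape[0]):
            for j in range(img.shape[1]):
                w = pad[i:i + cfg.window, j:j + cfg.window]
                mu[i, j] = (kern * w).sum()
                m2[i, j] = (kern * w * w).sum()
        return mu, m2

    def win_cross(a, b):
        pad_a = np.pad(a, half, mode="symmetric")
        pad_b = np.pad(b, half, mode="symmetric")
        out = np.empty_like(a, dtype=float)
        for i in range(a.shape[0]):
            for j in range(a.shape[1]):
                out[i, j] = (kern * pad_a[i:i + cfg.window, j:j + cfg.window]
                             * pad_b[i:i + cfg.window,
                                     j:j + cfg.window]).sum()
        return out

    mux, x2 = win_stats(x)
    muy, y2 = win_stats(y)
    xy = win_cross(x, y)
    vx = np.clip(x2 - mux**2, 0, None)
    vy = np.clip(y2 - muy**2, 0, None)
    sx, sy = np.sqrt(vx), np.sqrt(vy)
    cov = xy - mux * muy
    lum = (2 * mux * muy + cfg.C1) / (mux**2 + muy**2 + cfg.C1)
    con = (2 * sx * sy + cfg.C2) / (vx + vy + cfg.C2)
    st = (cov + cfg.C3) / (sx * sy + cfg.C3)
    return lum.mean() * con.mean() * st.mean()


# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def random_volumes():
    rng = np.random.default_rng(101)
    return [(rng.random((8, 8, 8)), rng.random((8, 8, 8)) > 0.6)
            for _ in range(100)]


class TestOracleAgreement:
    def test_rmse_matches_bruteforce(self, random_volumes):
        for rec, gt in random_volumes:
            assert rmse(rec, gt.astype(float)) == pytest.approx(
                oracle_rmse(rec, gt.astype(float)), rel=1e-12)

    def test_bhattacharyya_matches_bruteforce(self, random_volumes):
        for rec, gt in random_volumes[:50]:
            got = bhattacharyya(rec, gt.astype(float), n_bins=16)
            exp = oracle_bhattacharyya(rec, gt.astype(float), 16)
            assert got == pytest.approx(exp, rel=1e-10)

    def test_contrast_matches_bruteforce(self, random_volumes):
        for rec, _ in random_volumes:
            assert contrast(rec) == pytest.approx(oracle_contrast(rec),
                                                  rel=1e-12)

    def test_depth_matches_bruteforce(self, random_volumes):
        for _, gt in random_volumes:
            if not gt.any():
                continue
            assert reconstructed_depth(gt, (0.5, 0.5, 0.2)) == pytest.approx(
                oracle_depth(gt, 0.2), rel=1e-12)

    def test_seg_scores_match_bruteforce(self, random_volumes):
        for rec, gt in random_volumes:
            seg = rec > 0.5
            if not gt.any() or gt.all():
                continue
            got = seg_scores(gt, seg)
            exp = oracle_seg(gt, seg)
            assert got == pytest.approx(exp, rel=1e-12)

    def test_msssim_single_scale_matches_bruteforce(self):
        rng = np.random.default_rng(55)
        cfg = MSSSIMConfig(n_scales=1)
        for _ in range(10):
            x = rng.random((8, 8, 8))
            y = rng.random((8, 8, 8))
            got = msssim_volume(x, y, cfg)
            exp = np.mean([oracle_ssim_single_scale(x[:, :, k], y[:, :, k],
                                                    cfg)
                           for k in range(8)])
            assert got == pytest.approx(exp, rel=1e-7)

    def test_dice_sensitivity_identity(self, random_volumes):
        # dice == 2 * sens * |gt| / (|gt| + |seg|) exactly
        for rec, gt in random_volumes:
            seg = rec > 0.5
            if not gt.any() or gt.all():
                continue
            _, sens, dice = seg_scores(gt, seg)
            bound = min(1.0, 2 * sens * gt.sum() / (gt.sum() + seg.sum()))
            assert dice <= bound + 1e-12
            assert dice == pytest.approx(
                2 * sens * gt.sum() / (gt.sum() + seg.sum()))


class TestHandValues:
    def test_rmse_identities(self):
        v = np.random.default_rng(0).random((5, 5, 5))
        assert rmse(v, v) == 0.0
        assert rmse(np.ones((4, 4)), np.zeros((4, 4))) == 1.0

    def test_rmse_half_differ_by_one(self):
        a = np.zeros(10)
        b = np.zeros(10)
        b[:5] = 1.0
        assert rmse(a, b) == pytest.approx(math.sqrt(0.5))

    def test_rmse_shape_mismatch(self):
        with pytest.raises(ValueError):
            rmse(np.ones((2, 2)), np.ones((3, 3)))

    def test_bhattacharyya_identical_is_zero(self):
        v = np.random.default_rng(1).random(500)
        assert bhattacharyya(v, v.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_bhattacharyya_two_bin_hand_value(self):
        # p = (0.5, 0.5), q = (0.9, 0.1):
        # D = -ln(sqrt(0.45) + sqrt(0.05)) = 0.108843
        a = np.array([0.0] * 5 + [1.0] * 5)
        b = np.array([0.0] * 9 + [1.0] * 1)
        got = bhattacharyya(a, b, n_bins=2)
        assert got == pytest.approx(-math.log(math.sqrt(0.45)
                                              + math.sqrt(0.05)), rel=1e-9)

    def test_bhattacharyya_disjoint_capped(self):
        a = np.zeros(50)
        b = np.ones(50) * 10
        with pytest.warns(UserWarning, match="disjoint"):
            assert bhattacharyya(a, b, n_bins=4) == BHATTACHARYYA_CAP

    def test_contrast_hand_values(self):
        assert contrast(np.arange(1.0, 11.0)) == pytest.approx(
            (9.5 - 1.5) / 1.5)
        assert contrast(np.full(20, 3.0)) == 0.0
        arr = np.array([1.0] * 2 + [1.5] * 6 + [2.0] * 2)
        assert contrast(arr) == pytest.approx(1.0)

    def test_depth_hand_values(self):
        mask = np.zeros((3, 3, 12), dtype=bool)
        mask[1, 1, 9] = True
        assert reconstructed_depth(mask, (0.5, 0.5, 0.2)) == pytest.approx(
            1.9)
        col = np.zeros((3, 3, 10), dtype=bool)
        col[0, 0, :] = True
        assert reconstructed_depth(col, (0.5, 0.5, 0.2)) == pytest.approx(
            1.9)  # bottom-layer voxel center

    def test_depth_hemisphere_mask(self, pigment):
        from mdoi.phantoms import FeatureSpec, add_feature, make_phantom
        ph = add_feature(make_phantom(), FeatureSpec(
            "surface_hemisphere", 2.0, 3.0, pigment, (15.0, 15.0)))
        d = reconstructed_depth(ph.feature_mask, ph.voxel_size)
        assert abs(d - 3.0) <= 0.2

    def test_depth_empty_mask_nan(self):
        with pytest.warns(UserWarning, match="empty"):
            assert math.isnan(reconstructed_depth(np.zeros((2, 2, 2)),
                                                  (1, 1, 1)))

    def test_seg_scores_examples(self):
        gt = np.zeros((10, 10), dtype=bool)
        gt[:2, :5] = True  # 10 voxels
        assert seg_scores(gt, gt) == (1.0, 1.0, 1.0)
        disjoint = np.zeros_like(gt)
        disjoint[5:7, :5] = True
        spec, sens, dice = seg_scores(gt, disjoint)
        assert sens == 0.0 and dice == 0.0
        half = np.zeros_like(gt)
        half[:1, :5] = True
        half[5:6, :5] = True  # overlap 5, |seg| = 10
        _, _, dice = seg_scores(gt, half)
        assert dice == pytest.approx(0.5)

    def test_single_class_gt_rejected(self):
        with pytest.raises(ValueError):
            seg_scores(np.ones((3, 3)), np.ones((3, 3)))


class TestNormalize:
    def test_linear_scaling(self):
        rec = np.array([2.0, 3.0, 4.0])
        out, _ = normalize_for_comparison(rec, np.array([0, 1, 2]))
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0])

    def test_already_unit_range_unchanged(self):
        rec = np.array([0.0, 0.25, 1.0])
        out, _ = normalize_for_comparison(rec, np.array([1, 0, 1]))
        np.testing.assert_allclose(out, rec)

    def test_gt_binarized(self):
        _, gt01 = normalize_for_comparison(np.array([0.0, 1.0]),
                                           np.array([0, 3]))
        assert set(np.unique(gt01)) <= {0.0, 1.0}

    def test_constant_recon_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            out, _ = normalize_for_comparison(np.full((3, 3), 2.0),
                                              np.zeros((3, 3)))
        assert np.all(out == 0.0)


class TestMSSSIM:
    def test_identical_volumes_give_one(self):
        v = np.random.default_rng(2).random((24, 24, 4))
        assert msssim_volume(v, v.copy()) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.random((24, 24, 4))
        b = rng.random((24, 24, 4))
        assert msssim_volume(a, b) == pytest.approx(msssim_volume(b, a),
                                                    rel=1e-12)

    def test_inversion_scores_below_noisy_copy(self):
        rng = np.random.default_rng(4)
        gt = np.zeros((32, 32, 4))
        gt[8:24, 8:24, :] = 1.0
        noisy = np.clip(gt + 0.05 * rng.standard_normal(gt.shape), 0, 1)
        assert msssim_volume(1.0 - gt, gt) < msssim_volume(noisy, gt)

    def test_scale_auto_reduction_warns(self):
        v = np.random.default_rng(5).random((16, 16, 2))
        with pytest.warns(UserWarning, match="scales"):
            msssim_volume(v, v.copy(), MSSSIMConfig(n_scales=5))


def test_evaluate_case_perfect_reconstruction():
    gt = np.zeros((20, 20, 10), dtype=bool)
    gt[8:12, 8:12, :3] = True
    rep = evaluate_case(gt.astype(float), gt, gt, (0.5, 0.5, 0.2))
    assert rep.rmse == 0.0
    assert rep.bhattacharyya == pytest.approx(0.0, abs=1e-12)
    assert rep.specificity == rep.sensitivity == rep.dice == 1.0
    assert rep.msssim == pytest.approx(1.0, abs=1e-9)
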