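"""Hand-crafted C/K/G features, P-vector assembly and the F4 net."""

import numpy as np
import pytest

from strokeloc import features as F, phantom as ph, preprocess as pp
from strokeloc.errors import (GeometryError, ParameterError, StateError,
                              TrainingError)

from oracles import (brute_bilateral, brute_cell_stats, brute_global_stats,
                     brute_window_stats)


# ---------------------------------------------------------------------------
# Cell statistics


def test_toy_cell_statistics():
    sl = np.arange(1, 17, dtype=float).reshape(4, 4)
    g = F.cell_statistics(sl, np.ones((4, 4), bool), 2)
    assert g.stat_max[0, 0] == 6.0          # max of {1, 2, 5, 6}
    assert g.stat_mean[0, 0] == 3.5
    assert g.stat_median[0, 0] == 3.5


def test_constant_slice_cells_all_equal():
    g = F.cell_statistics(np.full((32, 32), 40.0), np.ones((32, 32), bool),
                          16)
    assert (g.stat_max == 40).all() and (g.stat_mean == 40).all() \
        and (g.stat_median == 40).all()


def test_empty_mask_cells_are_sentinel():
    g = F.cell_statistics(np.zeros((8, 8)), np.zeros((8, 8), bool), 4)
    assert np.isnan(g.stat_max).all()
    assert (g.occupancy == 0).all()


def test_oversized_cell_is_a_parameter_error():
    with pytest.raises(ParameterError):
        F.cell_statistics(np.zeros((8, 8)), np.ones((8, 8), bool), 16)


# ---------------------------------------------------------------------------
# Contralateral pairing


def test_mirror_pairing_in_centered_grid():
    mask = np.ones((32, 128), bool)          # midline at 63.5, 8 columns
    grid = F.cell_statistics(np.zeros((32, 128)), mask, 16)
    mid = F.mask_midline(mask)
    assert F.contralateral_pair((0, 1), mid, grid) == (0, 6)
    assert F.contralateral_pair((2, 0), mid, grid) == (2, 7)


def test_cell_on_midline_pairs_with_itself():
    mask = np.ones((16, 48), bool)           # 3 columns, middle on midline
    grid = F.cell_statistics(np.zeros((16, 48)), mask, 16)
    assert F.contralateral_pair((0, 1), F.mask_midline(mask), grid) == (0, 1)


def test_off_grid_mirror_is_sentinel():
    mask = np.zeros((16, 64), bool)
    mask[:, :16] = True                      # brain far image-left
    grid = F.cell_statistics(np.zeros((16, 64)), mask, 16)
    # mirror of the rightmost cell falls left of the grid start
    assert F.contralateral_pair((0, 3), F.mask_midline(mask), grid) is None


# ---------------------------------------------------------------------------
# Local window and global features


def test_constant_slice_local_stats():
    sl = np.full((24, 24), 42.0)
    k = F.local_window_features(sl, np.ones((24, 24), bool), (8,))
    np.testing.assert_allclose(k[..., 0], 42.0)
    np.testing.assert_allclose(k[..., 1], 42.0)
    np.testing.assert_allclose(k[..., 2], 42.0)
    np.testing.assert_allclose(k[..., 3], 42.0, atol=1e-9)  # bilateral


def test_impulse_window_stats():
    sl = np.full((64, 64), 40.0)
    sl[32, 32] = 100.0
    k = F.local_window_features(sl, np.ones((64, 64), bool), (8,))
    # symmetric radius-4 window: 81 pixels
    assert k[32, 32, 0] == 100.0
    assert k[32, 32, 1] == pytest.approx(40.0 + 60.0 / 81.0, abs=1e-12)
    assert k[32, 32, 2] == 40.0


def test_window_spanning_slice_equals_global(medium_case):
    sl = medium_case.ct.slices[1][:24, :24]
    mask = pp.extract_brain_mask(medium_case.ct.slices[1]).mask[:24, :24]
    mask[0, 0] = True                        # ensure non-empty
    k = F.local_window_features(sl, mask, (2 * max(sl.shape),))
    g = F.global_features(sl, mask)
    for ch in range(3):
        np.testing.assert_allclose(k[..., ch][mask], g[ch], atol=1e-9)


def test_odd_or_tiny_window_rejected():
    with pytest.raises(ParameterError):
        F.local_window_features(np.zeros((8, 8)), np.ones((8, 8), bool),
                                (7,))


def test_global_feature_example():
    m = np.zeros((2, 4), bool)
    m[0] = True
    g = F.global_features(np.array([[10.0, 20, 30, 100], [5, 5, 5, 5]]), m)
    np.testing.assert_array_equal(g, [100.0, 40.0, 25.0])
    # adding out-of-mask pixels changes nothing
    g2 = F.global_features(np.array([[10.0, 20, 30, 100],
                                     [999, -999, 0, 1]]), m)
    np.testing.assert_array_equal(g, g2)


def test_global_features_empty_mask_raises():
    with pytest.raises(GeometryError):
        F.global_features(np.zeros((4, 4)), np.zeros((4, 4), bool))


# ---------------------------------------------------------------------------
# Assembly


def test_vector_lengths():
    sl = np.random.default_rng(0).normal(35, 3, (64, 64))
    mask = np.ones((64, 64), bool)
    f13, names13 = F.assemble_pixel_features(
        sl, mask, F.FeatureConfig(scales=(16,)))
    assert f13.shape[-1] == 13 and len(names13) == 13
    f21, names21 = F.assemble_pixel_features(sl, mask, F.FeatureConfig())
    assert f21.shape[-1] == 21 and len(names21) == 21
    assert np.isfinite(f21).all()


def test_symmetric_slice_has_equal_own_and_contralateral():
    rng = np.random.default_rng(1)
    half = rng.normal(35, 3, (32, 32))
    sl = np.concatenate([half, half[:, ::-1]], axis=1)
    mask = np.ones((32, 64), bool)
    f, _ = F.assemble_pixel_features(sl, mask,
                                     F.FeatureConfig(scales=(16,)))
    np.testing.assert_array_equal(f[..., :3], f[..., 3:6])


def test_features_match_brute_force_enumeration():
    """Two-route check of C/K/G on random masked slices."""
    rng = np.random.default_rng(11)
    cfg = F.FeatureConfig(scales=(8, 16))
    for _ in range(3):
        sl = rng.normal(35, 6, (64, 64))
        mask = rng.random((64, 64)) < 0.9
        grid = F.cell_statistics(sl, mask, cfg.cell_size)
        oc = brute_cell_stats(sl, mask, cfg.cell_size)
        np.testing.assert_array_equal(grid.stat_max, oc[..., 0])
        np.testing.assert_allclose(grid.stat_mean, oc[..., 1], atol=1e-9)
        np.testing.assert_array_equal(grid.stat_median, oc[..., 2])
        g = F.global_features(sl, mask)
        og = brute_global_stats(sl, mask)
        assert g[0] == og[0] and g[2] == og[2]
        assert abs(g[1] - og[1]) <= 1e-9
        k = F.local_window_features(sl, mask, cfg.scales)
        for r, c in rng.integers(0, 64, (25, 2)):
            for si, w in enumerate(cfg.scales):
                om, omean, omed = brute_window_stats(sl, mask, w, r, c)
                got = k[r, c, 4 * si:4 * si + 3]
                if np.isnan(om):
                    assert np.isnan(got).all()
                else:
                    assert got[0] == om and got[2] == omed
                    assert abs(got[1] - omean) <= 1e-9
            ob = brute_bilateral(sl, r, c)
            assert abs(k[r, c, 3] - ob) <= 1e-9


def test_mirror_equivariance_is_exact(medium_case):
    sl = medium_case.ct.slices[2]
    mask = pp.extract_brain_mask(sl).mask
    cfg = F.FeatureConfig()
    f, _ = F.assemble_pixel_features(sl, mask, cfg)
    fm, _ = F.assemble_pixel_features(sl[:, ::-1], mask[:, ::-1], cfg)
    np.testing.assert_array_equal(f, fm[:, ::-1, :])


# ---------------------------------------------------------------------------
# F4 network


def _blob_data(rng, n=1000, d=6):
    X = np.concatenate([rng.normal(-1.5, 1.0, (n // 2, d)),
                        rng.normal(+1.5, 1.0, (n // 2, d))])
    y = np.repeat([0, 1], n // 2)
    perm = rng.permutation(n)
    return X[perm], y[perm]


def test_pixel_net_separates_gaussian_blobs_like_logistic_oracle():
    rng = np.random.default_rng(3)
    X, y = _blob_data(rng)
    Xte, yte = _blob_data(rng, 600)
    model = F.train_pixel_net(X, y, tuple(f"x{i}" for i in range(6)),
                              seed=1)
    acc = ((model.predict_proba(Xte)[:, 1] >= 0.5) == yte).mean()
    from sklearn.linear_model import LogisticRegression
    lr = LogisticRegression().fit(X, y)
    oracle_acc = lr.score(Xte, yte)
    assert oracle_acc >= 0.95                 # the task is separable
    assert acc >= 0.95


def test_pixel_net_single_class_raises():
    rng = np.random.default_rng(4)
    with pytest.raises(TrainingError):
        F.train_pixel_net(rng.normal(size=(100, 3)), np.zeros(100),
                          ("a", "b", "c"), seed=0)


def test_untrained_pixel_net_is_near_uniform():
    rng = np.random.default_rng(5)
    X, y = _blob_data(rng, 400)
    cfg = F.PixelNetConfig(epochs=0)
    model = F.train_pixel_net(X, y, tuple(f"x{i}" for i in range(6)),
                              seed=2, config=cfg)
    p = model.predict_proba(X)
    assert np.abs(p - 0.5).max() < 0.2
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


def test_pixel_net_training_is_bit_reproducible():
    rng = np.random.default_rng(6)
    X, y = _blob_data(rng, 400)
    kw = dict(seed=7, config=F.PixelNetConfig(epochs=25))
    m1 = F.train_pixel_net(X, y, ("a",) * 6, **kw)
    m2 = F.train_pixel_net(X, y, ("a",) * 6, **kw)
    assert m1.loss_curve == m2.loss_curve
    for l1, l2 in zip(m1.layers, m2.layers):
        for p1, p2 in zip(l1.params, l2.params):
            np.testing.assert_array_equal(p1.value, p2.value)


def test_predict_f4_contract(medium_case):
    sl = medium_case.ct.slices[2]
    mask = pp.extract_brain_mask(sl).mask
    cfg = F.FeatureConfig(scales=(8, 16))
    feats, names = F.assemble_pixel_features(sl, mask, cfg)
    y = medium_case.truth[2][mask].astype(int)
    model = F.train_pixel_net(feats[mask], y, names, seed=3,
                              config=F.PixelNetConfig(epochs=30,
                                                      max_samples=3000))
    f4 = F.predict_f4(model, sl, mask, cfg)
    assert f4.shape == sl.shape
    assert (f4[~mask] == 0).all()
    assert f4.min() >= 0 and f4.max() <= 1
    # empty mask -> all zeros
    z = F.predict_f4(model, sl, np.zeros_like(mask), cfg)
    assert (z == 0).all()
    # mismatched feature config is a versioning error
    with pytest.raises(StateError):
        F.predict_f4(model, sl, mask, F.FeatureConfig(scales=(8,)))


def test_f4_separates_lesion_on_held_out_phantoms():
    """Train on 10 strong-contrast phantoms, check separation on 2 more."""
    specs = [ph._case_spec(7000 + i, "left" if i % 2 == 0 else "right",
                           "easy", 3, (64, 64), (88, 88))
             for i in range(12)]
    cases = [ph.generate_phantom(s) for s in specs]
    cfg = F.FeatureConfig(scales=(8, 16))
    names = F.feature_names(cfg)
    Xs, ys = [], []
    for case in cases[:10]:
        for s in range(3):
            mask = pp.extract_brain_mask(case.ct.slices[s]).mask
            f, _ = F.assemble_pixel_features(case.ct.slices[s], mask, cfg)
            Xs.append(f[mask])
            ys.append(case.truth[s][mask].astype(int))
    model = F.train_pixel_net(np.concatenate(Xs), np.concatenate(ys),
                              names, seed=4,
                              config=F.PixelNetConfig(epochs=60,
                                                      max_samples=8000))
    diffs = []
    for case in cases[10:]:
        for s in range(3):
            mask = pp.extract_brain_mask(case.ct.slices[s]).mask
            f4 = F.predict_f4(model, case.ct.slices[s], mask, cfg)
            inside = case.truth[s] & mask
            outside = mask & ~case.truth[s]
            diffs.append(f4[inside].mean() - f4[outside].mean())
    assert np.mean(diffs) >= 0.3
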