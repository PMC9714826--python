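"""Ensemble fuser: block assembly, forward pass, training."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from strokeloc import ensemble as E, nn
from strokeloc.errors import DependencyError, GeometryError, TrainingError


def _toy_features(k=4, H=16, W=16, seed=0):
    rng = np.random.default_rng(seed)
    f = rng.random((k, 4, H, W)).astype(np.float32)
    m = np.ones((k, H, W), bool)
    return f, m


@pytest.mark.parametrize("block_size,channels", [(1, 5), (3, 15), (5, 25)])
def test_block_channel_counts(block_size, channels):
    f, m = _toy_features()
    b = E.build_input_block(f, m, 2, block_size)
    assert b.shape == (channels, 16, 16)


def test_block_edge_replication():
    f, m = _toy_features()
    b = E.build_input_block(f, m, 0, 3)
    # slice -1 replaced by slice 0: first two 5-channel groups identical
    np.testing.assert_array_equal(b[:5], b[5:10])


def test_block_center_group_position():
    f, m = _toy_features(k=6)
    b = E.build_input_block(f, m, 3, 5)
    # center group occupies channels 10-14: [F1..F4, mask] of slice 3
    np.testing.assert_array_equal(b[10:14], f[3])
    np.testing.assert_array_equal(b[14], m[3].astype(np.float32))
    # neighbours in order c-2..c+2
    np.testing.assert_array_equal(b[0:4], f[1])
    np.testing.assert_array_equal(b[20:24], f[5])


def test_block_rejects_bad_inputs():
    f, m = _toy_features()
    with pytest.raises(GeometryError):
        E.build_input_block(f, m, 0, 2)
    with pytest.raises(DependencyError):
        E.build_input_block(f, m, 9, 3)
    f[1] = np.nan
    with pytest.raises(DependencyError):
        E.build_input_block(f, m, 0, 3)


def test_zero_weights_give_uniform_probabilities():
    net = E.EnsembleNet(5, seed=0)
    for p in net.params:
        p.value[...] = 0.0
    f, m = _toy_features()
    b = E.build_input_block(f, m, 1, 1)
    probs = E.ensemble_forward(net, b)
    np.testing.assert_allclose(probs, 1.0 / 3.0, atol=1e-7)


def test_probabilities_sum_to_one_on_random_weights():
    net = E.EnsembleNet(15, seed=3)
    f, m = _toy_features()
    b = E.build_input_block(f, m, 2, 3)
    probs = E.ensemble_forward(net, b)
    np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-6)
    assert probs.min() >= 0 and probs.max() <= 1


def test_forward_matches_direct_convolution_oracle():
    """Hand-checkable path: 1-channel 5x5 block vs scipy correlate."""
    rng = np.random.default_rng(4)
    net = E.EnsembleNet(5, seed=1)
    x = rng.random((5, 5, 5)).astype(np.float32)
    x[4] = 1.0                                   # mask channel all-on
    logits = net.forward_logits(x[None], np.ones((1, 5, 5), np.float32))
    a1 = np.zeros((64, 5, 5))
    for o in range(64):
        acc = np.zeros((5, 5))
        for c in range(5):
            acc += correlate2d(x[c].astype(np.float64),
                               net.conv1.W.value[o, c].astype(np.float64),
                               mode="same")
        a1[o] = np.maximum(acc + net.conv1.b.value[o], 0.0)
    z = np.einsum("oc,chw->ohw", net.conv2.W.value[:, :, 0, 0]
                  .astype(np.float64), a1) + \
        net.conv2.b.value[:, None, None]
    oracle = np.maximum(z, 0.0)
    np.testing.assert_allclose(logits[0], oracle, atol=1e-5)


def test_channel_mismatch_is_a_shape_error():
    net = E.EnsembleNet(15, seed=0)
    with pytest.raises(GeometryError):
        net.forward_logits(np.zeros((1, 5, 8, 8), np.float32),
                           np.ones((1, 8, 8), np.float32))


def _training_problem(seed=0, k=6, H=32, W=32):
    rng = np.random.default_rng(seed)
    m = np.zeros((k, H, W), bool)
    m[:, 4:-4, 4:-4] = True
    truth = np.zeros((k, H, W), bool)
    truth[:, 8:16, 6:14] = True
    f = np.empty((k, 4, H, W), np.float32)
    for j in range(4):
        noise = rng.normal(0, 0.3, (k, H, W))
        f[:, j] = (truth * 0.8 + 0.1 + noise) * m
    t3 = np.where(m, np.where(truth, 2, 1), 0)
    blocks = np.stack([E.build_input_block(f, m, c, 3) for c in range(k)])
    return blocks, m, t3, truth


def test_overfit_one_volume():
    blocks, m, t3, truth = _training_problem()
    net = E.train_ensemble(blocks, m, t3,
                           E.EnsembleTrainConfig(steps=80, batch=3, seed=2))
    logits = net.forward_logits(blocks, m.astype(np.float32))
    pred = nn.softmax(logits.astype(np.float64), axis=1).argmax(axis=1)
    acc = (pred == t3)[m].mean()
    assert acc >= 0.95


def test_loss_mostly_non_increasing():
    blocks, m, t3, _ = _training_problem(seed=5)
    net = E.train_ensemble(blocks, m, t3,
                           E.EnsembleTrainConfig(steps=60, batch=3, seed=3))
    curve = np.asarray(net.loss_curve)
    frac_down = (np.diff(curve) <= 1e-6).mean()
    assert frac_down >= 0.9


def test_same_seed_twice_identical_weights():
    blocks, m, t3, _ = _training_problem(seed=6)
    cfg = E.EnsembleTrainConfig(steps=10, batch=2, seed=4)
    n1 = E.train_ensemble(blocks, m, t3, cfg)
    n2 = E.train_ensemble(blocks, m, t3, cfg)
    for p1, p2 in zip(n1.params, n2.params):
        np.testing.assert_array_equal(p1.value, p2.value)


def test_single_class_targets_raise():
    blocks, m, t3, _ = _training_problem()
    with pytest.raises(TrainingError):
        E.train_ensemble(blocks, m, np.zeros_like(t3))


def test_predict_volume_contract():
    blocks, m, t3, truth = _training_problem(seed=7)
    f = np.stack([blocks[c][5:9] for c in range(blocks.shape[0])])
    net = E.train_ensemble(blocks, m, t3,
                           E.EnsembleTrainConfig(steps=30, batch=3, seed=5))
    m2 = m.copy()
    m2[0] = False                            # one empty-mask slice
    L = E.predict_volume(net, f, m2, 3)
    assert L.shape == m.shape                # exactly k maps
    assert (L[0] == 0).all()                 # empty mask -> zero infarct
    assert (L[~m2] == 0).all()


def test_constant_volume_block3_equals_block1():
    """On a volume of identical slices the 3-block equals the 1-block."""
    rng = np.random.default_rng(8)
    one = rng.random((4, 16, 16)).astype(np.float32)
    f = np.repeat(one[None], 3, axis=0)[:, :4]
    m = np.ones((3, 16, 16), bool)
    b3 = E.build_input_block(f, m, 1, 3)
    b1 = E.build_input_block(f, m, 1, 1)
    for g in range(3):
        np.testing.assert_array_equal(b3[5 * g:5 * g + 5], b1)


def test_save_load_round_trip(tmp_path):
    blocks, m, t3, _ = _training_problem()
    net = E.train_ensemble(blocks, m, t3,
                           E.EnsembleTrainConfig(steps=5, batch=2, seed=6))
    path = str(tmp_path / "fuser.npz")
    net.save(path)
    back = E.EnsembleNet.load(path)
    l1 = net.forward_logits(blocks[:2], m[:2].astype(np.float32))
    l2 = back.forward_logits(blocks[:2], m[:2].astype(np.float32))
    np.testing.assert_array_equal(l1, l2)
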