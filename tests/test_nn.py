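"""FCRes-CNN architecture contracts, gradients, training behaviour."""

import numpy as np
import pytest

from sparsebci import nn


def tiny_config(**kw):
    base = dict(
        input_length=24, fds_kernel=3, fds_filters=4, res_blocks=1,
        res_filters=(4,), head_filters=2, dropout_rate=0.0, epochs=0, seed=1,
    )
    base.update(kw)
    return nn.NetworkConfig(**base)


def test_config_validation():
    with pytest.raises(ValueError):
        nn.NetworkConfig(input_length=100, fds_stride=1)
    with pytest.raises(ValueError):
        nn.NetworkConfig(input_length=100, dropout_rate=1.0)
    with pytest.raises(ValueError):
        nn.NetworkConfig(input_length=100, res_blocks=0)
    with pytest.raises(ValueError):
        nn.NetworkConfig(input_length=3)  # shorter than the first kernel


def test_too_short_input_reports_minimum():
    with pytest.raises(ValueError, match="at least"):
        nn.build_network(nn.NetworkConfig(input_length=8, fds_kernel=3))


def test_layer_inventory_matches_architecture():
    net = nn.build_network(nn.NetworkConfig(input_length=280))
    inv = net.layer_inventory()
    assert inv.count("ResidualBlock") == 3
    assert inv[0] == "Conv1d"  # fast down-sampling conv
    assert inv.count("Flatten") == 1
    assert inv[-1] == "Dense"  # softmax head


def test_fast_downsampling_stride_arithmetic():
    net = nn.build_network(nn.NetworkConfig(input_length=280))
    assert net.net.fds[0].out_len(280) == 94  # ceil(280 / 3)


def test_parameter_count_is_desk_scale():
    net = nn.build_network(nn.NetworkConfig(input_length=280))
    assert net.parameter_count() < 10**6


def test_residual_block_identity_when_branch_zeroed(rng):
    net = nn.build_network(nn.NetworkConfig(input_length=90))
    blk = net.net.blocks[0]
    blk.zero_residual_branch()
    x = rng.normal(size=(4, 16, 30))
    out = blk.forward(x, training=False, rng=net.rng)
    assert np.array_equal(blk.prepool, x)  # exact identity before pooling
    pooled = x[:, :, :30].reshape(4, 16, 15, 2).max(axis=3)
    assert np.array_equal(out, pooled)


def test_gradients_match_finite_differences(rng):
    trained = nn.build_network(tiny_config())
    X = rng.normal(size=(5, 1, 24))
    y0 = np.array([0, 1, 0, 1, 1])

    def loss_fn():
        logits = trained.net.forward(X, training=True, rng=np.random.default_rng(9))
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        return -np.log(p[np.arange(5), y0]).mean(), p

    for _, g in trained.net.params:
        g[:] = 0.0
    _, p = loss_fn()
    onehot = np.zeros_like(p)
    onehot[np.arange(5), y0] = 1.0
    trained.net.backward((p - onehot) / 5)

    h = 1e-5
    for par, grad in trained.net.params:
        flat, gflat = par.ravel(), grad.ravel()
        for j in range(0, flat.size, max(1, flat.size // 3)):
            old = flat[j]
            flat[j] = old + h
            l1, _ = loss_fn()
            flat[j] = old - h
            l2, _ = loss_fn()
            flat[j] = old
            num = (l1 - l2) / (2 * h)
            assert abs(num - gflat[j]) < 1e-5 * max(1.0, abs(num))


def test_uniform_probabilities_with_zeroed_head(rng):
    trained = nn.build_network(tiny_config())
    head = trained.net.head[-1]
    head.W[:] = 0.0
    head.b[:] = 0.0
    probs, labels = nn.predict(trained, rng.normal(size=(7, 24)))
    np.testing.assert_allclose(probs, 0.5, atol=1e-12)
    assert np.all(labels == 1)  # argmax tie broken toward the lower class
    # uniform prediction on balanced two-class data gives loss ln 2 exactly
    y0 = np.array([0, 1, 0, 1, 0, 1, 0])
    loss = -np.log(probs[np.arange(7), y0]).mean()
    assert abs(loss - np.log(2)) < 1e-12


def test_predict_shape_and_row_sums(rng):
    trained = nn.build_network(tiny_config())
    probs, labels = nn.predict(trained, rng.normal(size=(11, 24)))
    assert probs.shape == (11, 2) and labels.shape == (11,)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(probs >= 0)
    with pytest.raises(ValueError):
        nn.predict(trained, rng.normal(size=(3, 25)))


def test_zero_epochs_is_noop(rng):
    trained = nn.build_network(tiny_config())
    before = [p.copy() for p, _ in trained.net.params]
    nn.train(trained, rng.normal(size=(6, 24)), np.array([1, 2, 1, 2, 1, 2]), epochs=0)
    assert trained.history == []
    for b, (p, _) in zip(before, trained.net.params):
        assert np.array_equal(b, p)


def test_single_class_labels_rejected(rng):
    trained = nn.build_network(tiny_config())
    with pytest.raises(ValueError):
        nn.train(trained, rng.normal(size=(4, 24)), np.ones(4, int), epochs=1)


def test_oversized_batch_runs_full_batch(rng):
    trained = nn.build_network(tiny_config(batch_size=2500, epochs=2))
    X = rng.normal(size=(20, 24))
    y = np.r_[np.ones(10, int), np.full(10, 2)]
    nn.train(trained, X, y)
    assert len(trained.history) == 2


def test_separable_blobs_reach_high_accuracy(rng):
    n = 200
    codes = np.vstack(
        [rng.normal(-1, 0.5, size=(n // 2, 60)), rng.normal(1, 0.5, size=(n // 2, 60))]
    )
    labels = np.r_[np.ones(n // 2, int), np.full(n // 2, 2)]
    trained = nn.build_network(nn.NetworkConfig(input_length=60, epochs=80, seed=0))
    nn.train(trained, codes, labels)
    assert trained.history[-1]["train_acc"] >= 0.99
    assert all(h["train_loss"] >= 0 for h in trained.history)


def test_checkpoint_round_trip_preserves_predictions(tmp_path, rng):
    codes = rng.normal(size=(20, 24))
    labels = np.r_[np.ones(10, int), np.full(10, 2)]
    trained = nn.build_network(tiny_config(dropout_rate=0.3, epochs=4, seed=2))
    nn.train(trained, codes, labels)
    p1, l1 = nn.predict(trained, codes)
    path = tmp_path / "ckpt.npz"
    nn.save_checkpoint(trained, path)
    restored = nn.load_checkpoint(path)
    p2, l2 = nn.predict(restored, codes)
    np.testing.assert_array_equal(p1, p2)
    np.testing.assert_array_equal(l1, l2)


def test_training_is_seed_deterministic(rng):
    codes = rng.normal(size=(30, 24))
    labels = np.r_[np.ones(15, int), np.full(15, 2)]
    runs = []
    for _ in range(2):
        t = nn.build_network(tiny_config(dropout_rate=0.3, epochs=5, seed=7))
        nn.train(t, codes, labels, val_fraction=0.2)
        runs.append(t.history)
    assert runs[0] == runs[1]
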