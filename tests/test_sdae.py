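"""Stacked denoising autoencoder: corruption, forward maps, losses,
gradient correctness, greedy pretraining and supervised fine-tuning."""

import numpy as np
import pytest

from harsdae import sdae
from harsdae.sdae import (
    DaeLayer,
    SdaeModel,
    TrainConfig,
    TrainingDiverged,
    corrupt,
    decode,
    encode,
    fine_tune,
    init_layer,
    load_model,
    predict,
    pretrain_layer,
    pretrain_stack,
    recon_loss,
    save_model,
)


class TestCorrupt:
    def test_zero_factor_is_identity(self, rng):
        x = rng.random(100)
        np.testing.assert_array_equal(corrupt(x, 0.0, rng), x)

    def test_unit_factor_zeroes_everything(self, rng):
        x = rng.random(100) + 0.5
        assert np.all(corrupt(x, 1.0, rng) == 0.0)

    def test_half_factor_zeroes_about_half(self):
        zero_fracs = [
            np.mean(corrupt(np.ones(10_000), 0.5, np.random.default_rng(s)) == 0.0)
            for s in range(10)
        ]
        assert abs(np.mean(zero_fracs) - 0.5) < 0.02
        # surviving components are kept unchanged
        rng = np.random.default_rng(0)
        x = np.arange(1.0, 11.0)
        out = corrupt(x, 0.5, rng)
        assert set(out[out != 0.0]) <= set(x)


class TestEncodeDecode:
    def test_zero_parameters_give_half_everywhere(self):
        layer = DaeLayer(np.zeros((4, 3)), np.zeros(3), np.zeros((3, 4)), np.zeros(4))
        np.testing.assert_allclose(encode(layer, np.ones((2, 4))), 0.5)
        np.testing.assert_allclose(decode(layer, np.ones((2, 3))), 0.5)

    def test_one_dimensional_hand_computation(self):
        layer = DaeLayer(np.array([[2.0]]), np.zeros(1), np.array([[1.0]]), np.zeros(1))
        hidden = encode(layer, np.array([[1.0]]))
        assert hidden[0, 0] == pytest.approx(1 / (1 + np.exp(-2.0)), abs=1e-9)
        assert hidden[0, 0] == pytest.approx(0.8808, abs=1e-4)

    def test_outputs_strictly_inside_unit_interval(self, rng):
        layer = init_layer(8, 5, 0.5, rng)
        X = rng.normal(size=(20, 8)) * 10
        y = encode(layer, X)
        z = decode(layer, y)
        assert np.all((y > 0) & (y < 1)) and np.all((z > 0) & (z < 1))

    def test_dimension_mismatch_raises(self, rng):
        layer = init_layer(8, 5, 0.5, rng)
        with pytest.raises(ValueError):
            encode(layer, np.ones((2, 9)))
        with pytest.raises(ValueError):
            decode(layer, np.ones((2, 4)))


class TestReconLoss:
    def test_perfect_binary_reconstruction_is_zero(self):
        x = np.array([0.0, 1.0, 1.0, 0.0])
        assert recon_loss(x, x) == pytest.approx(0.0, abs=1e-9)

    def test_half_prediction_hand_values(self):
        assert recon_loss(np.array([1.0]), np.array([0.5])) == pytest.approx(
            -np.log(0.5), abs=1e-12
        )
        # symmetry of the two cross-entropy terms
        assert recon_loss(np.array([0.0]), np.array([0.5])) == pytest.approx(
            -np.log(0.5), abs=1e-12
        )

    def test_nonnegative_for_unit_interval_inputs(self, rng):
        x, z = rng.random(50), rng.random(50)
        assert recon_loss(x, z) >= 0.0


def _fd_grad(f, arr, eps=1e-6):
    """Central finite differences of scalar f w.r.t. every entry of arr."""
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        old = arr[i]
        arr[i] = old + eps
        hi = f()
        arr[i] = old - eps
        lo = f()
        arr[i] = old
        g[i] = (hi - lo) / (2 * eps)
        it.iternext()
    return g


def _rel_err(a, b):
    return np.max(np.abs(a - b)) / max(1e-12, np.max(np.abs(a) + np.abs(b)))


class TestGradients:
    def test_reconstruction_gradients_match_finite_differences(self, rng):
        layer = init_layer(5, 4, 0.5, rng)
        X = rng.random((6, 5))
        Xc = corrupt(X, 0.5, rng)
        loss, dW1, db1, dW2, db2 = sdae.dae_gradients(layer, X, Xc)
        f = lambda: sdae.dae_gradients(layer, X, Xc)[0]
        for analytic, param in [
            (dW1, layer.W1), (db1, layer.b1), (dW2, layer.W2), (db2, layer.b2),
        ]:
            assert _rel_err(analytic, _fd_grad(f, param)) < 1e-5

    def test_classification_gradients_match_finite_differences(self, rng):
        config = TrainConfig(hidden_sizes=(4, 3), corruption=0.0, iterations=1, seed=0)
        model, _ = pretrain_stack(rng.random((8, 5)), config)
        X = rng.random((8, 5))
        y_idx = rng.integers(0, 3, size=8)
        rng2 = np.random.default_rng(1)
        model.head_W = rng2.normal(size=(3, 3)) * 0.5
        model.head_b = np.zeros(3)
        model.classes = ["a", "b", "c"]
        loss, enc_grads, dHW, dHb = sdae.classification_gradients(model, X, y_idx)
        f = lambda: sdae.classification_loss(model, X, y_idx)
        assert _rel_err(dHW, _fd_grad(f, model.head_W)) < 1e-5
        assert _rel_err(dHb, _fd_grad(f, model.head_b)) < 1e-5
        for (dW1, db1), layer in zip(enc_grads, model.layers):
            assert _rel_err(dW1, _fd_grad(f, layer.W1)) < 1e-5
            assert _rel_err(db1, _fd_grad(f, layer.b1)) < 1e-5


def _clone_layer(layer):
    return DaeLayer(layer.W1.copy(), layer.b1.copy(), layer.W2.copy(),
                    layer.b2.copy(), layer.corruption)


def _reference_plain_ae(W1, b1, W2, b2, X, lr, epochs, batch, rng):
    """Independent plain (non-denoising) autoencoder trainer.

    Written with explicit per-parameter update formulas (no shared code with
    the implementation under test) to serve as the a=0 reduction oracle.
    """
    eps = 1e-12
    trace = []
    n = X.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        tot = 0.0
        for lo in range(0, n, batch):
            B = X[order[lo: lo + batch]]
            m = B.shape[0]
            # corrupt() at a=0 returns a copy without consuming the stream
            Y = 1.0 / (1.0 + np.exp(-(B @ W1 + b1)))
            Z = 1.0 / (1.0 + np.exp(-(Y @ W2 + b2)))
            Zc = np.clip(Z, eps, 1 - eps)
            tot += float(-np.sum(B * np.log(Zc) + (1 - B) * np.log(1 - Zc)))
            delta_out = Z - B  # batch-sum reduction
            delta_hid = (delta_out @ W2.T) * Y * (1 - Y)
            W2 -= lr * (Y.T @ delta_out)
            b2 -= lr * delta_out.sum(0)
            W1 -= lr * (B.T @ delta_hid)
            b1 -= lr * delta_hid.sum(0)
        trace.append(tot / n)
    return (W1, b1, W2, b2), trace


class TestPretraining:
    def test_vanishing_learning_rate_leaves_parameters_unchanged(self, rng):
        layer = init_layer(6, 4, 0.5, rng)
        before = _clone_layer(layer)
        config = TrainConfig(pretrain_lr=1e-300, iterations=3, batch_size=4, seed=0)
        pretrain_layer(rng.random((12, 6)), layer, config)
        np.testing.assert_array_equal(layer.W1, before.W1)
        np.testing.assert_array_equal(layer.W2, before.W2)

    def test_loss_trace_decreases_over_training(self, rng):
        X = rng.random((64, 10))
        layer = init_layer(10, 6, 0.3, rng)
        config = TrainConfig(pretrain_lr=0.02, iterations=200, batch_size=16, seed=1)
        _, trace = pretrain_layer(X, layer, config, seed=2)
        assert trace[-1] <= trace[0]

    def test_stack_chains_hidden_shapes(self, rng):
        config = TrainConfig(hidden_sizes=(500, 500), iterations=1, seed=0)
        model, traces = pretrain_stack(rng.random((10, 3072)), config)
        assert [(l.d_in, l.d_hidden) for l in model.layers] == [(3072, 500), (500, 500)]
        assert len(traces) == 2

    def test_single_layer_stack_equals_direct_layer_training(self, rng):
        X = rng.random((20, 7))
        config = TrainConfig(hidden_sizes=(4,), pretrain_lr=0.02, iterations=5,
                             batch_size=8, seed=9)
        model, traces = pretrain_stack(X, config)
        # replicate the stack's per-layer seeding by hand
        seed_seq = np.random.SeedSequence(9, spawn_key=(0,))
        g = np.random.default_rng(seed_seq)
        layer = init_layer(7, 4, config.corruption, g, config.dtype)
        layer, trace = pretrain_layer(X, layer, config, seed=g)
        np.testing.assert_array_equal(model.layers[0].W1, layer.W1)
        np.testing.assert_array_equal(model.layers[0].W2, layer.W2)
        assert traces[0] == trace

    def test_zero_corruption_reduces_to_plain_autoencoder(self, rng):
        """With a = 0 the denoising autoencoder IS a plain autoencoder: loss
        trace and final weights must match an independent reference run."""
        X = rng.random((40, 9))
        config = TrainConfig(hidden_sizes=(5,), corruption=0.0, pretrain_lr=0.02,
                             iterations=20, batch_size=8, seed=4)
        model, traces = pretrain_stack(X, config)

        seed_seq = np.random.SeedSequence(4, spawn_key=(0,))
        g = np.random.default_rng(seed_seq)
        init = init_layer(9, 5, 0.0, g, config.dtype)
        (W1, b1, W2, b2), ref_trace = _reference_plain_ae(
            init.W1.copy(), init.b1.copy(), init.W2.copy(), init.b2.copy(),
            X, lr=0.02, epochs=20, batch=8, rng=g,
        )
        np.testing.assert_allclose(traces[0], ref_trace, rtol=1e-10)
        np.testing.assert_allclose(model.layers[0].W1, W1, rtol=1e-10)
        np.testing.assert_allclose(model.layers[0].W2, W2, rtol=1e-10)

    def test_divergence_raises_with_diagnostic(self, rng):
        X = rng.random((16, 4))
        layer = init_layer(4, 3, 0.0, rng)
        layer.W1 += 1e200  # force overflow in the forward pass
        config = TrainConfig(pretrain_lr=1e6, iterations=2, batch_size=8, seed=0)
        with pytest.raises(TrainingDiverged, match="pretrain_lr"):
            pretrain_layer(np.nan * X, layer, config)


def _separable_toy(n_per=40, seed=0):
    rng = np.random.default_rng(seed)
    a = np.clip(rng.normal(0.2, 0.05, size=(n_per, 6)), 0, 1)
    b = np.clip(rng.normal(0.8, 0.05, size=(n_per, 6)), 0, 1)
    X = np.vstack([a, b])
    y = np.array(["low"] * n_per + ["high"] * n_per, dtype=object)
    return X, y


class TestFineTuneAndPredict:
    def test_linearly_separable_classes_reach_full_training_accuracy(self):
        X, y = _separable_toy()
        config = TrainConfig(hidden_sizes=(8,), corruption=0.1, pretrain_lr=0.01,
                             finetune_lr=0.05, iterations=200, batch_size=16, seed=0)
        model, _ = pretrain_stack(X, config)
        model, history = fine_tune(model, X, y, ["high", "low"], config)
        labels, _ = predict(model, X)
        assert np.mean(labels == y) == 1.0
        assert history["train_loss"][-1] < history["train_loss"][0]

    def test_vanishing_finetune_rate_stays_at_chance(self, rng):
        X = rng.random((120, 10))
        y = np.array([f"c{i % 12}" for i in range(120)], dtype=object)
        classes = [f"c{i}" for i in range(12)]
        config = TrainConfig(hidden_sizes=(6,), pretrain_lr=1e-300,
                             finetune_lr=1e-300, iterations=3, batch_size=16, seed=0)
        model, _ = pretrain_stack(X, config)
        model, history = fine_tune(model, X, y, classes, config, X_val=X, y_val=y)
        assert history["val_accuracy"][-1] == pytest.approx(1 / 12, abs=0.1)

    def test_label_outside_class_set_is_error(self, rng):
        X = rng.random((10, 4))
        config = TrainConfig(hidden_sizes=(3,), iterations=1, seed=0)
        model, _ = pretrain_stack(X, config)
        with pytest.raises(ValueError, match="outside"):
            fine_tune(model, X, ["weird"] * 10, ["a", "b"], config)

    def test_zero_head_gives_uniform_probabilities_and_first_class(self, rng):
        config = TrainConfig(hidden_sizes=(5,), iterations=1, seed=0)
        model, _ = pretrain_stack(rng.random((6, 8)), config)
        model.head_W = np.zeros((5, 12))
        model.head_b = np.zeros(12)
        model.classes = [f"c{i}" for i in range(12)]
        labels, proba = predict(model, rng.random((4, 8)))
        np.testing.assert_allclose(proba, 1 / 12, atol=1e-12)
        assert all(l == "c0" for l in labels)

    def test_probabilities_sum_to_one(self, rng):
        config = TrainConfig(hidden_sizes=(5,), iterations=1, seed=2)
        model, _ = pretrain_stack(rng.random((6, 8)), config)
        model.head_W = rng.normal(size=(5, 4))
        model.head_b = rng.normal(size=4)
        model.classes = list("abcd")
        _, proba = predict(model, rng.normal(size=(30, 8)) * 5)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(proba >= 0)

    def test_seed_determinism_of_final_weights(self, rng):
        X, y = _separable_toy(n_per=20, seed=3)
        config = TrainConfig(hidden_sizes=(4,), pretrain_lr=0.01, finetune_lr=0.02,
                             iterations=5, batch_size=8, seed=11)
        runs = []
        for _ in range(2):
            model, _ = pretrain_stack(X, config)
            model, _ = fine_tune(model, X, y, ["high", "low"], config)
            runs.append(model)
        np.testing.assert_array_equal(runs[0].layers[0].W1, runs[1].layers[0].W1)
        np.testing.assert_array_equal(runs[0].head_W, runs[1].head_W)


class TestSerialization:
    def test_round_trip_preserves_weights_classes_and_predictions(self, tmp_path, rng):
        X, y = _separable_toy(n_per=15, seed=5)
        config = TrainConfig(hidden_sizes=(6, 4), pretrain_lr=0.01, finetune_lr=0.05,
                             iterations=10, batch_size=8, seed=1)
        model, _ = pretrain_stack(X, config)
        model, _ = fine_tune(model, X, y, ["high", "low"], config)
        path = tmp_path / "model.npz"
        save_model(model, config, path)
        loaded, meta = load_model(path)
        assert loaded.classes == ["high", "low"]
        assert meta["config"]["hidden_sizes"] == [6, 4]
        for l0, l1 in zip(model.layers, loaded.layers):
            np.testing.assert_array_equal(l0.W1, l1.W1)
        np.testing.assert_array_equal(
            predict(model, X)[0], predict(loaded, X)[0]
        )

    def test_shape_chain_validated_on_load(self, tmp_path, rng):
        model = SdaeModel(layers=[
            init_layer(4, 3, 0.5, rng), init_layer(3, 2, 0.5, rng),
        ])
        path = tmp_path / "m.npz"
        save_model(model, None, path)
        # corrupting the chain must be caught
        import numpy as _np
        with _np.load(path) as d:
            arrays = {k: d[k] for k in d.files}
        arrays["W1_1"] = _np.zeros((5, 2))
        _np.savez(path, **arrays)
        with pytest.raises(ValueError):
            load_model(path)
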