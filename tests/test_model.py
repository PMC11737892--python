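"""Masked network: construction, forward, training, prediction, persistence.

The dense-equivalence oracle is an independently written fully connected
network (its own forward pass, backprop and Adam) used to check that with
all-ones masks the masked implementation is exactly an ordinary MLP.
"""

from __future__ import annotations

import numpy as np
import pytest

import sparsego as sg
from sparsego.knowledge import MaskSet
from sparsego.model import _batch_gradients


def ones_masks(G=6, T=3, K=4):
    return MaskSet(
        genes=[f"g{i}" for i in range(G)],
        tfs=[f"g{i}" for i in range(T)],
        go_terms=[f"GO:{j + 1:07d}" for j in range(K)],
        M_gene_go=np.ones((G, K)),
        M_gene_tf=np.ones((G, T)),
        M_tf_go=np.ones((T, K)),
    )


def random_masks(rng, G=10, T=4, K=5, density=0.4):
    def m(shape):
        out = (rng.random(shape) < density).astype(float)
        out[rng.integers(shape[0]), :] = 1.0  # no empty column
        return out

    return MaskSet(
        genes=[f"g{i}" for i in range(G)],
        tfs=[f"t{i}" for i in range(T)],
        go_terms=[f"GO:{j + 1:07d}" for j in range(K)],
        M_gene_go=m((G, K)),
        M_gene_tf=m((G, T)),
        M_tf_go=m((T, K)),
    )


class TestInit:
    def test_parameter_count_arithmetic(self):
        rng = np.random.default_rng(0)
        masks = random_masks(rng)
        model = sg.init_model(masks, ["a", "b", "c", "d"], seed=0)
        sparse, dense = model.count_parameters()
        nnz = sum(masks.nnz)
        n_bias = 4 + 5 + 4  # tf + go + out
        assert sparse == nnz + 5 * 4 + n_bias
        assert dense == 10 * 5 + 10 * 4 + 4 * 5 + 5 * 4 + n_bias

    def test_determinism_and_seed_sensitivity(self):
        masks = ones_masks()
        a = sg.init_model(masks, ["x", "y"], seed=7)
        b = sg.init_model(masks, ["x", "y"], seed=7)
        c = sg.init_model(masks, ["x", "y"], seed=8)
        np.testing.assert_array_equal(a.W_gene_go, b.W_gene_go)
        assert not np.array_equal(a.W_gene_go, c.W_gene_go)

    def test_masked_positions_zero_after_init(self):
        masks = random_masks(np.random.default_rng(3))
        model = sg.init_model(masks, ["x", "y"], seed=0)
        assert (model.W_gene_go[masks.M_gene_go == 0] == 0).all()
        assert (model.W_gene_tf[masks.M_gene_tf == 0] == 0).all()
        assert (model.W_tf_go[masks.M_tf_go == 0] == 0).all()

    def test_empty_labels_rejected(self):
        with pytest.raises(ValueError, match="non-empty label"):
            sg.init_model(ones_masks(), [], seed=0)


class TestForward:
    def test_zero_weights_give_uniform_probabilities(self):
        model = sg.SparseGOModel(ones_masks(), ["a", "b", "c", "d"])
        probs = model.forward(np.ones(6))
        np.testing.assert_allclose(probs, np.full((1, 4), 0.25))

    def test_zero_input_zero_bias_uniform(self):
        model = sg.init_model(ones_masks(), ["a", "b", "c"], seed=1)
        probs = model.forward(np.zeros(6))
        np.testing.assert_allclose(probs, np.full((1, 3), 1 / 3), atol=1e-12)

    def test_matches_dense_reference_with_all_ones_masks(self):
        """With all-ones masks the forward pass is an ordinary MLP."""
        model = sg.init_model(ones_masks(), ["a", "b"], seed=5, activation="tanh")
        rng = np.random.default_rng(0)
        X = rng.random((7, 6))
        # independent dense computation
        H1 = np.tanh(X @ model.W_gene_tf + model.b_tf)
        H2 = np.tanh(X @ model.W_gene_go + H1 @ model.W_tf_go + model.b_go)
        logits = H2 @ model.W_go_out + model.b_out
        expected = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        np.testing.assert_allclose(model.forward(X), expected, rtol=1e-12)

    def test_dimension_mismatch(self):
        model = sg.init_model(ones_masks(), ["a", "b"], seed=0)
        with pytest.raises(ValueError, match="genes"):
            model.forward(np.ones(5))

    def test_probabilities_normalized(self, small_classifier, small_data):
        probs = small_classifier.forward(small_data["expr"].values)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert probs.min() >= 0


class TestLoss:
    def test_printed_formula_values(self):
        assert sg.cross_entropy([1, 0], [0.5, 0.5]) == pytest.approx(
            -np.log(0.5), abs=1e-12
        )
        assert sg.cross_entropy([0, 1, 0], [0, 1, 0]) == 0.0

    def test_batch_loss_matches_formula(self):
        model = sg.init_model(ones_masks(), ["a", "b"], seed=3)
        X = np.random.default_rng(1).random((4, 6))
        y = np.array([0, 1, 0, 1])
        loss, _ = _batch_gradients(model, X, y)
        probs = model.forward(X)
        expected = np.mean([sg.cross_entropy(np.eye(2)[t], p) for t, p in zip(y, probs)])
        assert loss == pytest.approx(expected, rel=1e-12)


class TestGradients:
    @pytest.mark.parametrize("activation", ["relu", "tanh"])
    @pytest.mark.parametrize("mode", ["classification", "regression"])
    def test_finite_difference_check(self, activation, mode):
        """Analytic gradients agree with central finite differences."""
        rng = np.random.default_rng(9)
        masks = random_masks(rng)
        labels = ["a", "b", "c"] if mode == "classification" else None
        model = sg.init_model(masks, labels, mode=mode, seed=2, activation=activation)
        X = rng.random((5, 10)) + 0.1
        y = np.array([0, 1, 2, 0, 1]) if mode == "classification" else rng.random(5)
        _, grads = _batch_gradients(model, X, y)
        eps = 1e-6
        for name in ("W_gene_go", "W_tf_go", "W_go_out", "b_go"):
            w = getattr(model, name)
            flat_idx = np.flatnonzero(np.abs(grads[name]) > 1e-12)[:5]
            for k in flat_idx:
                orig = w.flat[k]
                w.flat[k] = orig + eps
                lp, _ = _batch_gradients(model, X, y)
                w.flat[k] = orig - eps
                lm, _ = _batch_gradients(model, X, y)
                w.flat[k] = orig
                numeric = (lp - lm) / (2 * eps)
                assert numeric == pytest.approx(grads[name].flat[k], rel=1e-4, abs=1e-8)


def _train_dense_reference(model, X, y, lr, n_steps):
    """Independent fully connected trainer (own backprop + Adam), full batch."""
    W = {k: getattr(model, k).copy() for k in
         ("W_gene_tf", "W_gene_go", "W_tf_go", "W_go_out", "b_tf", "b_go", "b_out")}
    m = {k: np.zeros_like(v) for k, v in W.items()}
    v = {k: np.zeros_like(v) for k, v in W.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    n = X.shape[0]
    losses = []
    for t in range(1, n_steps + 1):
        Z1 = X @ W["W_gene_tf"] + W["b_tf"]
        H1 = np.tanh(Z1)
        Z2 = X @ W["W_gene_go"] + H1 @ W["W_tf_go"] + W["b_go"]
        H2 = np.tanh(Z2)
        L = H2 @ W["W_go_out"] + W["b_out"]
        P = np.exp(L - L.max(1, keepdims=True))
        P /= P.sum(1, keepdims=True)
        losses.append(float(-np.log(P[np.arange(n), y]).mean()))
        dL = P.copy()
        dL[np.arange(n), y] -= 1
        dL /= n
        g = {
            "W_go_out": H2.T @ dL, "b_out": dL.sum(0),
        }
        dH2 = dL @ W["W_go_out"].T
        dZ2 = dH2 * (1 - H2 ** 2)
        g["W_gene_go"] = X.T @ dZ2
        g["W_tf_go"] = H1.T @ dZ2
        g["b_go"] = dZ2.sum(0)
        dH1 = dZ2 @ W["W_tf_go"].T
        dZ1 = dH1 * (1 - H1 ** 2)
        g["W_gene_tf"] = X.T @ dZ1
        g["b_tf"] = dZ1.sum(0)
        for k in W:
            m[k] = b1 * m[k] + (1 - b1) * g[k]
            v[k] = b2 * v[k] + (1 - b2) * g[k] ** 2
            W[k] -= lr * (m[k] / (1 - b1 ** t)) / (np.sqrt(v[k] / (1 - b2 ** t)) + eps)
    return losses


class TestTraining:
    def test_dense_equivalence_per_step_losses(self):
        """All-ones masks + same seed reproduce a fully connected network's
        per-step Adam losses to 1e-5 relative over 50 steps."""
        masks = ones_masks(G=12, T=4, K=5)
        rng = np.random.default_rng(4)
        X = rng.random((30, 12))
        y = rng.integers(0, 3, 30)
        labels = ["a", "b", "c"]
        model = sg.init_model(masks, labels, seed=6)
        ref_model = sg.init_model(masks, labels, seed=6)
        ref_losses = _train_dense_reference(ref_model, X, y, lr=0.001, n_steps=50)

        cfg = sg.TrainingConfig(
            seed=0, learning_rate=0.001, max_epochs=50, batch_size=30,
            validation_fraction=0.0, shuffle=False, weight_decay=0.0,
        )
        hist = sg.train(model, X, np.array(labels)[y], cfg)
        np.testing.assert_allclose(hist["loss"], ref_losses, rtol=1e-5)

    def test_mask_invariance_after_init_one_and_many_steps(self):
        rng = np.random.default_rng(10)
        masks = random_masks(rng, G=20, T=5, K=6)
        X = rng.random((40, 20))
        y = np.array(["a", "b"] * 20)
        model = sg.init_model(masks, ["a", "b"], seed=1)

        def assert_masked_zero():
            assert (model.W_gene_go[masks.M_gene_go == 0] == 0).all()
            assert (model.W_gene_tf[masks.M_gene_tf == 0] == 0).all()
            assert (model.W_tf_go[masks.M_tf_go == 0] == 0).all()

        assert_masked_zero()
        cfg1 = sg.TrainingConfig(seed=0, max_epochs=1, batch_size=40,
                                 validation_fraction=0.0)
        sg.train(model, X, y, cfg1)
        assert_masked_zero()
        cfg100 = sg.TrainingConfig(seed=0, max_epochs=100, batch_size=40,
                                   validation_fraction=0.0)
        sg.train(model, X, y, cfg100)
        assert_masked_zero()

    def test_training_is_deterministic(self, small_data):
        d = small_data
        cfg = sg.TrainingConfig(seed=3, max_epochs=20)
        models = []
        for _ in range(2):
            m = sg.init_model(d["masks"], sorted(set(d["labels"])), seed=1)
            sg.train(m, d["expr"].values, d["labels"], cfg)
            models.append(m)
        for name in models[0]._WEIGHTS + models[0]._BIASES:
            np.testing.assert_array_equal(getattr(models[0], name), getattr(models[1], name))

    def test_loss_trend_decreases_on_separable_data(self, small_data):
        d = small_data
        model = sg.init_model(d["masks"], sorted(set(d["labels"])), seed=0)
        hist = sg.train(model, d["expr"].values, d["labels"],
                        sg.TrainingConfig(seed=0, max_epochs=60))
        loss = np.array(hist["loss"])
        smoothed = np.convolve(loss, np.ones(5) / 5, mode="valid")
        assert smoothed[-1] < smoothed[0]

    def test_label_outside_map_rejected(self, small_data):
        d = small_data
        model = sg.init_model(d["masks"], ["type0", "type1"], seed=0)
        with pytest.raises(ValueError, match="not in the model's label map"):
            sg.train(model, d["expr"].values, d["labels"], sg.TrainingConfig(seed=0, max_epochs=1))

    def test_mode_mismatch_rejected(self, small_data):
        d = small_data
        model = sg.init_model(d["masks"], None, mode="regression", seed=0)
        with pytest.raises(ValueError, match="mode"):
            sg.train(model, d["expr"].values, np.zeros(d["expr"].n_cells),
                     sg.TrainingConfig(seed=0, mode="classification"))


class TestPredict:
    def test_novelty_threshold_rule(self):
        model = sg.SparseGOModel(ones_masks(), ["a", "b", "c"])
        # craft logits via the output bias so probabilities are known
        model.b_out[:] = np.log([0.96, 0.02, 0.02])
        res = sg.predict(model, np.zeros((1, 6)), novelty_threshold=0.95)
        assert res.predicted_label == ["a"]
        assert not res.novelty_flag[0]
        model.b_out[:] = np.log([0.5, 0.3, 0.2])
        res = sg.predict(model, np.zeros((1, 6)), novelty_threshold=0.95)
        assert res.novelty_flag[0]
        res0 = sg.predict(model, np.zeros((3, 6)), novelty_threshold=0.0)
        assert not res0.novelty_flag.any()

    def test_argmax_tie_breaks_to_lowest_index(self):
        model = sg.SparseGOModel(ones_masks(), ["a", "b", "c"])
        res = sg.predict(model, np.zeros((1, 6)))  # uniform probabilities
        assert res.predicted_label == ["a"]

    def test_mode_errors(self, small_data):
        d = small_data
        clf = sg.init_model(d["masks"], ["x", "y"], seed=0)
        reg = sg.init_model(d["masks"], None, mode="regression", seed=0)
        with pytest.raises(ValueError, match="predict_score"):
            sg.predict(reg, d["expr"].values)
        with pytest.raises(ValueError, match="use predict"):
            sg.predict_score(clf, d["expr"].values)

    def test_zero_weight_regression_outputs_bias(self):
        model = sg.SparseGOModel(ones_masks(), None, mode="regression")
        model.b_out[:] = 1.5
        scores = sg.predict_score(model, np.random.default_rng(0).random((4, 6)))
        np.testing.assert_allclose(scores, 1.5)
        single = sg.predict_score(model, np.ones(6))
        assert single.shape == (1,)


class TestCountParameters:
    def test_sparse_vs_dense_identity_with_ones(self):
        model = sg.SparseGOModel(ones_masks(), ["a", "b"])
        sparse, dense = model.count_parameters()
        assert sparse == dense

    def test_low_density_ratio(self):
        G, K = 100, 50
        rng = np.random.default_rng(0)
        M = np.zeros((G, K))
        M[rng.integers(0, G, size=K), np.arange(K)] = 1  # 1% density, no empty column
        masks = MaskSet(genes=[f"g{i}" for i in range(G)], tfs=[],
                        go_terms=[f"GO:{j + 1:07d}" for j in range(K)],
                        M_gene_go=M, M_gene_tf=np.zeros((G, 0)),
                        M_tf_go=np.zeros((0, K)))
        model = sg.SparseGOModel(masks, ["a", "b"])
        sparse, dense = model.count_parameters()
        head_and_bias = K * 2 + (0 + K + 2)
        assert sparse - head_and_bias == int(M.sum())
        assert (sparse - head_and_bias) / (dense - head_and_bias) == pytest.approx(
            0.01, rel=0.25
        )


class TestPersistence:
    def test_roundtrip_bit_exact(self, tmp_path, small_classifier, small_data):
        model = small_classifier
        path = tmp_path / "model.zip"
        sg.save_model(model, path)
        back = sg.load_model(path)
        X = small_data["expr"].values[:5]
        np.testing.assert_array_equal(model.forward(X), back.forward(X))
        for name in model._WEIGHTS + model._BIASES:
            np.testing.assert_array_equal(getattr(model, name), getattr(back, name))
        assert back.label_map == model.label_map
        assert back.mode == model.mode

    def test_truncated_archive_errors(self, tmp_path, small_classifier):
        path = tmp_path / "model.zip"
        sg.save_model(small_classifier, path)
        path.write_bytes(path.read_bytes()[:100])
        with pytest.raises(Exception):
            sg.load_model(path)

    def test_manifest_missing_mode_errors(self, tmp_path, small_classifier):
        import json
        import shutil
        import zipfile

        src = tmp_path / "model.zip"
        sg.save_model(small_classifier, src)
        dst = tmp_path / "tampered.zip"
        with zipfile.ZipFile(src) as zin, zipfile.ZipFile(dst, "w") as zout:
            for item in zin.namelist():
                data = zin.read(item)
                if item == "manifest.json":
                    manifest = json.loads(data)
                    del manifest["mode"]
                    data = json.dumps(manifest).encode()
                zout.writestr(item, data)
        with pytest.raises((ValueError, KeyError)):
            sg.load_model(dst)
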