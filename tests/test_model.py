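"""The masked autoencoder/classifier: forward pass, training contract, CV."""

import numpy as np
import pytest

import gsae
from gsae.data import ExpressionMatrix, MembershipMask
from gsae.model import (
    NetworkConfig,
    cross_validate,
    encode,
    fit_autoencoder,
    fit_classifier,
    initialize,
    layer_forward,
    load_model,
    predict,
    relu,
    save_model,
    train,
)


def small_mask(rng, n_genes=30, n_sets=6):
    m = (rng.random((n_genes, n_sets)) < 0.3).astype(float)
    m[np.arange(n_sets), np.arange(n_sets)] = 1.0  # every column non-empty
    return MembershipMask(m, [f"g{i}" for i in range(n_genes)], [f"s{j}" for j in range(n_sets)])


def small_expr(rng, n=60, p=30):
    return ExpressionMatrix(
        np.abs(rng.normal(2.0, 1.0, size=(n, p))),
        [f"c{i}" for i in range(n)],
        [f"g{j}" for j in range(p)],
    )


class TestActivations:
    @pytest.mark.parametrize("x,expected", [(3.0, 3.0), (-2.0, 0.0), (0.0, 0.0)])
    def test_relu(self, x, expected):
        assert relu(x) == expected

    def test_layer_forward_relu(self):
        out = layer_forward([2.0, 3.0], np.array([[1.0], [1.0]]), np.array([0.0]), "relu")
        assert out[0, 0] == pytest.approx(5.0)

    def test_layer_forward_relu_clips(self):
        out = layer_forward([2.0, 3.0], np.array([[1.0], [1.0]]), np.array([-6.0]), "relu")
        assert out[0, 0] == 0.0

    def test_linear_returns_preactivation(self):
        out = layer_forward([2.0, 3.0], np.array([[1.0], [1.0]]), np.array([-6.0]), "linear")
        assert out[0, 0] == pytest.approx(-1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="width"):
            layer_forward([1.0], np.ones((2, 3)), np.zeros(3), "relu")


class TestInitialize:
    def test_deterministic_given_seed(self, rng):
        mask = small_mask(rng)
        cfg = NetworkConfig(superset_size=4, seed=9)
        a, b = initialize(cfg, mask), initialize(cfg, mask)
        for la, lb in zip(a.layers, b.layers):
            np.testing.assert_array_equal(la.W, lb.W)

    def test_masked_entries_exactly_zero_and_count_matches(self, rng):
        mask = small_mask(rng)
        model = initialize(NetworkConfig(superset_size=4, seed=0), mask)
        W1 = model.layers[0].W
        assert (W1[mask.mask == 0] == 0).all()
        assert (W1 != 0).sum() == mask.mask.sum()

    def test_he_uniform_bound(self, rng):
        mask = small_mask(rng)
        model = initialize(NetworkConfig(superset_size=4, seed=0), mask)
        for layer in model.layers:
            assert np.abs(layer.W).max() <= np.sqrt(6.0 / layer.W.shape[0])

    def test_architecture_shapes(self, rng):
        mask = small_mask(rng)
        ae = initialize(NetworkConfig(superset_size=4, seed=0), mask)
        assert [l.W.shape for l in ae.layers] == [(30, 6), (6, 4), (4, 6), (6, 30)]
        assert [l.activation for l in ae.layers] == ["relu", "relu", "relu", "linear"]
        clf = initialize(NetworkConfig(superset_size=4, seed=0, mode="classifier"), mask, n_classes=3)
        assert [l.W.shape for l in clf.layers] == [(30, 6), (6, 4), (4, 3)]
        assert clf.layers[-1].activation == "softmax"

    def test_fully_connected_variant_has_no_mask(self):
        cfg = NetworkConfig(encoder_variant=[10, 4], seed=0)
        model = initialize(cfg, n_genes=30)
        assert model.mask is None
        assert [l.W.shape for l in model.layers] == [(30, 10), (10, 4), (4, 10), (10, 30)]


class TestTraining:
    def test_mask_conserved_and_loss_improves(self, rng):
        mask = small_mask(rng)
        expr = small_expr(rng)
        cfg = NetworkConfig(superset_size=4, seed=3, learning_rate=0.01,
                            validation_fraction=0.1, max_epochs=150, patience=150)
        model = initialize(cfg, mask)
        init_loss = float(((model.forward(expr.values) - expr.values) ** 2).mean())
        model = train(model, expr)
        assert model.check_mask() == 0.0
        assert model.history["train_loss"][-1] < init_loss

    def test_training_is_deterministic(self, rng):
        mask = small_mask(rng)
        expr = small_expr(rng)
        cfg = NetworkConfig(superset_size=4, seed=3, validation_fraction=0.1, max_epochs=20)
        runs = []
        for _ in range(2):
            runs.append(train(initialize(cfg, mask), expr))
        for la, lb in zip(runs[0].layers, runs[1].layers):
            np.testing.assert_array_equal(la.W, lb.W)

    def test_early_stopping_bound(self, rng):
        mask = small_mask(rng)
        expr = small_expr(rng)
        cfg = NetworkConfig(superset_size=4, seed=3, validation_fraction=0.1,
                            max_epochs=400, patience=5)
        model = train(initialize(cfg, mask), expr)
        n_epochs = len(model.history["train_loss"])
        assert n_epochs <= model.history["best_epoch"] + cfg.patience

    def test_too_small_validation_split_rejected(self, rng):
        mask = small_mask(rng)
        expr = small_expr(rng, n=10)
        cfg = NetworkConfig(superset_size=4, seed=0, validation_fraction=0.05)
        with pytest.raises(ValueError, match="validation"):
            train(initialize(cfg, mask), expr)


class TestEncodePredict:
    def test_scores_nonnegative_with_expected_shapes(self, rng):
        mask = small_mask(rng)
        expr = small_expr(rng)
        model = initialize(NetworkConfig(superset_size=4, seed=0), mask)
        scores = encode(model, expr)
        assert scores.gene_set_scores.shape == (60, 6)
        assert scores.superset_scores.shape == (60, 4)
        assert (scores.gene_set_scores >= 0).all()
        assert (scores.superset_scores >= 0).all()

    def test_zero_sample_encodes_to_relu_of_bias(self, rng):
        mask = small_mask(rng)
        model = initialize(NetworkConfig(superset_size=4, seed=0), mask)
        model.layers[0].b = rng.normal(size=6)
        zero = ExpressionMatrix(np.zeros((1, 30)), ["z"], [f"g{j}" for j in range(30)])
        scores = encode(model, zero)
        np.testing.assert_allclose(scores.gene_set_scores[0], np.maximum(model.layers[0].b, 0))

    def test_gene_order_mismatch_rejected(self, rng):
        mask = small_mask(rng)
        model = initialize(NetworkConfig(superset_size=4, seed=0), mask)
        shuffled = ExpressionMatrix(
            np.ones((2, 30)), ["a", "b"], [f"g{j}" for j in reversed(range(30))]
        )
        with pytest.raises(ValueError, match="gene order"):
            encode(model, shuffled)

    def test_predict_rows_sum_to_one_and_requires_classifier(self, rng):
        mask = small_mask(rng)
        expr = small_expr(rng)
        clf = initialize(NetworkConfig(superset_size=4, seed=0, mode="classifier"), mask, n_classes=3)
        clf.classes = ["a", "b", "c"]
        probs, labels = predict(clf, expr)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0)
        assert set(labels) <= {"a", "b", "c"}
        ae = initialize(NetworkConfig(superset_size=4, seed=0), mask)
        with pytest.raises(ValueError, match="classifier"):
            predict(ae, expr)


class TestCrossValidate:
    def test_perfect_predictor_stub(self, rng):
        expr = small_expr(rng, n=80)
        labels = np.repeat(["a", "b", "c", "d"], 20)
        cv = cross_validate(
            expr, labels, NetworkConfig(seed=0, mode="classifier"), k=5,
            predictor=lambda etr, ytr, ete: np.array(
                labels[[expr.samples.index(s) for s in ete.samples]]
            ),
        )
        assert cv["accuracy"] == 1.0
        assert all(v == 1.0 for v in cv["sensitivity"].values())
        assert all(v == 1.0 for v in cv["specificity"].values())

    def test_constant_predictor_on_balanced_classes(self, rng):
        expr = small_expr(rng, n=80)
        labels = np.repeat(["a", "b", "c", "d"], 20)
        cv = cross_validate(
            expr, labels, NetworkConfig(seed=0, mode="classifier"), k=5,
            predictor=lambda etr, ytr, ete: np.array(["a"] * ete.n_samples),
        )
        assert cv["accuracy"] == pytest.approx(0.25)
        assert cv["sensitivity"]["a"] == 1.0
        assert cv["sensitivity"]["b"] == 0.0

    def test_metrics_match_confusion_matrix_oracle(self, rng):
        expr = small_expr(rng, n=60)
        labels = np.array(list("abc") * 20)

        def noisy(etr, ytr, ete):
            r = np.random.default_rng(len(ete.samples))
            true = labels[[expr.samples.index(s) for s in ete.samples]]
            flip = r.random(len(true)) < 0.3
            wrong = r.choice(list("abc"), size=len(true))
            return np.where(flip, wrong, true)

        cv = cross_validate(expr, labels, NetworkConfig(seed=1, mode="classifier"), k=5, predictor=noisy)

        # oracle: re-run the same folds and count the confusion explicitly
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=1)
        accs, sens, spec = [], {c: [] for c in "abc"}, {c: [] for c in "abc"}
        for tr, te in skf.split(expr.values, labels):
            ete = expr.subset_samples(te)
            y_hat = noisy(None, None, ete)
            y_te = labels[te]
            accs.append(np.mean(y_hat == y_te))
            for c in "abc":
                tp = np.sum((y_te == c) & (y_hat == c))
                fn = np.sum((y_te == c) & (y_hat != c))
                tn = np.sum((y_te != c) & (y_hat != c))
                fp = np.sum((y_te != c) & (y_hat == c))
                sens[c].append(tp / (tp + fn))
                spec[c].append(tn / (tn + fp))
        assert cv["accuracy"] == pytest.approx(np.mean(accs))
        for c in "abc":
            assert cv["sensitivity"][c] == pytest.approx(np.mean(sens[c]))
            assert cv["specificity"][c] == pytest.approx(np.mean(spec[c]))

    def test_class_smaller_than_k_rejected(self, rng):
        expr = small_expr(rng, n=12)
        labels = np.array(["a"] * 9 + ["b"] * 3)
        with pytest.raises(ValueError, match="members"):
            cross_validate(expr, labels, NetworkConfig(seed=0, mode="classifier"), k=5)


class TestPersistence:
    def test_save_load_round_trips_encode_bit_identically(self, rng, tmp_path):
        mask = small_mask(rng)
        expr = small_expr(rng)
        cfg = NetworkConfig(superset_size=4, seed=3, validation_fraction=0.1, max_epochs=15)
        model = train(initialize(cfg, mask), expr)
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        a, b = encode(model, expr), encode(back, expr)
        np.testing.assert_array_equal(a.gene_set_scores, b.gene_set_scores)
        np.testing.assert_array_equal(a.superset_scores, b.superset_scores)
        assert back.config == model.config
        assert back.history["best_epoch"] == model.history["best_epoch"]
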