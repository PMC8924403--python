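"""Architecture contracts, gradients, training behavior of the neural nets."""

import math

import numpy as np
import pytest

from metmap.nn.classifiers import (
    AugmentedCNNClassifier,
    BiLSTMClassifier,
    SimpleCNNClassifier,
    load_classifier,
)
from metmap.nn.models import (
    AttentionSpec,
    BilstmSpec,
    CnnSpec,
    TrainConfig,
    build_model,
    sigmoid,
    train_model,
)
from metmap.nn.tokenize import pad_batch


def small_cnn(attention=None, seed=0, vocab=25, L=10):
    return build_model(CnnSpec(max_len=L), vocab, attention=attention, seed=seed), L


class TestArchitectureContracts:
    def test_conv_layer_parameter_count(self):
        net, _ = small_cnn()
        counts = net.parameter_counts()
        # kernel 3 x embedding 50 x 64 filters + 64 biases
        assert counts["Wc"] + counts["bc"] == 3 * 50 * 64 + 64 == 9664

    def test_dense_head_parameter_counts(self):
        net, _ = small_cnn()
        counts = net.parameter_counts()
        assert counts["W1"] + counts["b1"] == 64 * 10 + 10
        assert counts["W2"] + counts["b2"] == 10 + 1

    def test_bilstm_combined_output_dimension(self):
        net = build_model(BilstmSpec(), vocab_size=40, seed=0)
        counts = net.parameter_counts()
        # per direction: Wx (64 x 4*32), Wh (32 x 4*32), b (4*32)
        assert counts["Wx_f"] == 64 * 128
        assert counts["Wh_f"] == 32 * 128
        # dense input is the 64-dim concatenation of both directions
        assert net.params["W1"].shape == (64, 64)

    def test_cnn_output_is_probability(self, rng):
        net, L = small_cnn()
        X = rng.integers(0, 26, size=(8, L))
        p = net.forward(X)
        assert ((p > 0) & (p < 1)).all()

    def test_bilstm_logit_unbounded_sigmoid_bounded(self, rng):
        net = build_model(BilstmSpec(), vocab_size=30, seed=1)
        X, mask = pad_batch([rng.integers(2, 30, size=5).tolist() for _ in range(6)])
        z = net.forward(X, mask)
        assert z.dtype == float  # raw logits, no activation
        p = sigmoid(z)
        assert ((p > 0) & (p < 1)).all()


class TestAttention:
    def test_normalized_width_one_is_identity_with_simple_cnn(self, rng):
        cnn, L = small_cnn(seed=3)
        acnn, _ = small_cnn(attention=AttentionSpec(width=1, normalize=True), seed=3)
        for k in cnn.params:
            acnn.params[k] = cnn.params[k].copy()
        X = rng.integers(0, 26, size=(5, L))
        assert np.allclose(cnn.forward(X), acnn.forward(X))

    def test_unnormalized_width_one_changes_activations(self, rng):
        cnn, L = small_cnn(seed=3)
        acnn, _ = small_cnn(attention=AttentionSpec(width=1, normalize=False), seed=3)
        for k in cnn.params:
            acnn.params[k] = cnn.params[k].copy()
        X = rng.integers(0, 26, size=(5, L))
        assert not np.allclose(cnn.forward(X), acnn.forward(X))

    def test_window_weights_sum_to_one_in_normalized_mode(self, rng):
        net, L = small_cnn(attention=AttentionSpec(width=3, normalize=True), seed=0)
        X = rng.integers(0, 26, size=(4, L))
        net.forward(X)
        _, _, _, A, _, offsets = net._cache["att"]
        total = sum(A[d] for d in offsets)
        assert np.allclose(total, 1.0)
        assert all((A[d] >= 0).all() for d in offsets)

    def test_even_width_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            small_cnn(attention=AttentionSpec(width=2))


def numeric_grad(net, X, y, key, index, mask=None, eps=1e-6):
    flat = net.params[key].reshape(-1)
    orig = flat[index]
    out = []
    for delta in (eps, -eps):
        flat[index] = orig + delta
        o = net.forward(X, mask) if mask is not None else net.forward(X)
        out.append(net.loss(o, y))
    flat[index] = orig
    return (out[0] - out[1]) / (2 * eps)


class TestGradients:
    @pytest.mark.parametrize(
        "attention",
        [None, AttentionSpec(1, True), AttentionSpec(3, True), AttentionSpec(3, False)],
        ids=["plain", "w1-norm", "w3-norm", "w3-unnorm"],
    )
    def test_cnn_backprop_matches_numeric(self, attention, rng):
        net = build_model(
            CnnSpec(embedding_dim=7, filters=6, dense_units=4, max_len=9),
            19,
            attention=attention,
            seed=2,
        )
        X = rng.integers(0, 20, size=(5, 9))
        y = (rng.random(5) > 0.5).astype(float)
        net.forward(X)
        grads = {k: v.copy() for k, v in net.backward(y).items()}
        check = np.random.default_rng(1)
        for key, g in grads.items():
            for index in check.choice(g.size, size=min(4, g.size), replace=False):
                num = numeric_grad(net, X, y, key, index)
                assert abs(num - g.reshape(-1)[index]) < 1e-4 * max(1.0, abs(num))

    def test_bilstm_backprop_matches_numeric(self, rng):
        net = build_model(
            BilstmSpec(embedding_dim=6, units_per_direction=5, dense_units=4),
            20,
            seed=3,
        )
        X, mask = pad_batch([[3, 4, 5], [6, 7, 8, 9], [2]])
        y = np.array([1.0, 0.0, 1.0])
        net.forward(X, mask)
        grads = {k: v.copy() for k, v in net.backward(y).items()}
        check = np.random.default_rng(2)
        for key, g in grads.items():
            for index in check.choice(g.size, size=min(4, g.size), replace=False):
                num = numeric_grad(net, X, y, key, index, mask=mask)
                assert abs(num - g.reshape(-1)[index]) < 1e-4 * max(1.0, abs(num))


class TestBiLSTMPaddingInvariance:
    def test_output_independent_of_batch_partners(self, rng):
        net = build_model(BilstmSpec(), vocab_size=30, seed=4)
        seq = rng.integers(2, 30, size=6).tolist()
        short_partner = [rng.integers(2, 30, size=4).tolist()]
        long_partner = [rng.integers(2, 30, size=40).tolist()]
        outs = []
        for partner in (short_partner, long_partner):
            X, mask = pad_batch([seq] + partner)
            outs.append(net.forward(X, mask)[0])
        assert abs(outs[0] - outs[1]) < 1e-5


def make_separable(n, seed):
    rng = np.random.default_rng(seed)
    texts, labels = [], []
    pos_words = ["metastasis", "suspicious", "measurement", "nodule"]
    neg_words = ["unremarkable", "clear", "normal", "stable"]
    for i in range(n):
        y = int(rng.random() < 0.5)
        bank = pos_words if y else neg_words
        words = [bank[int(rng.integers(len(bank)))] for _ in range(6)]
        texts.append(" ".join(words))
        labels.append(y)
    return texts, labels


class TestTraining:
    def test_initial_loss_near_chance_for_balanced_labels(self, rng):
        net, L = small_cnn(seed=5)
        X = rng.integers(0, 26, size=(64, L))
        y = np.array([0.0, 1.0] * 32)
        assert abs(net.loss(net.forward(X), y) - math.log(2)) < 0.15

    def test_same_seed_training_is_bit_reproducible(self):
        texts, labels = make_separable(40, seed=0)
        runs = []
        for _ in range(2):
            clf = SimpleCNNClassifier(seed=9)
            clf.fit(texts, labels, texts[:10], labels[:10],
                    TrainConfig(epochs=3, seed=9))
            runs.append({k: v.copy() for k, v in clf.net.params.items()})
        assert all(np.array_equal(runs[0][k], runs[1][k]) for k in runs[0])

    def test_single_class_labels_rejected(self):
        net, L = small_cnn()
        X = np.zeros((8, L), dtype=int)
        with pytest.raises(ValueError, match="single class"):
            train_model(net, X, np.ones(8), X, np.ones(8), TrainConfig(epochs=1))

    @pytest.mark.parametrize(
        "cls", [SimpleCNNClassifier, AugmentedCNNClassifier, BiLSTMClassifier]
    )
    def test_separable_corpus_reaches_high_validation_f1(self, cls):
        texts, labels = make_separable(160, seed=3)
        val_texts, val_labels = make_separable(60, seed=4)
        clf = cls(seed=0)
        clf.fit(texts, labels, val_texts, val_labels, TrainConfig(epochs=10, seed=0))
        pred = clf.predict_texts(val_texts)
        y = np.asarray(val_labels)
        tp = int(((y == 1) & (pred.labels == 1)).sum())
        fp = int(((y == 0) & (pred.labels == 1)).sum())
        fn = int(((y == 1) & (pred.labels == 0)).sum())
        f1 = 2 * tp / (2 * tp + fp + fn)
        assert f1 >= 0.95

    def test_labels_follow_probability_threshold(self):
        texts, labels = make_separable(60, seed=6)
        clf = SimpleCNNClassifier(seed=1)
        clf.fit(texts, labels, texts[:20], labels[:20], TrainConfig(epochs=3, seed=1))
        pred = clf.predict_texts(texts[:30])
        assert ((pred.probabilities >= 0.5) == pred.labels.astype(bool)).all()


class TestPredictEdgeCases:
    @pytest.mark.parametrize(
        "cls", [SimpleCNNClassifier, BiLSTMClassifier]
    )
    def test_empty_encoded_sequence_is_flagged(self, cls):
        texts, labels = make_separable(40, seed=7)
        clf = cls(seed=0)
        clf.fit(texts, labels, texts[:10], labels[:10], TrainConfig(epochs=2, seed=0))
        # for the CNN scheme the unknown word is dropped -> empty sequence;
        # for the alphabetical scheme it maps to the unknown index
        pred = clf.predict_texts(["zzzz qqqq"])
        assert 0.0 <= pred.probabilities[0] <= 1.0
        if isinstance(clf, SimpleCNNClassifier):
            assert pred.empty_input[0]
        else:
            assert not pred.empty_input[0]
            assert clf.vocab.encode("zzzz qqqq") == [1, 1]

    @pytest.mark.parametrize(
        "cls",
        [SimpleCNNClassifier, AugmentedCNNClassifier, BiLSTMClassifier],
    )
    def test_save_load_roundtrip(self, cls, tmp_path):
        texts, labels = make_separable(50, seed=8)
        clf = cls(seed=2)
        clf.fit(texts, labels, texts[:15], labels[:15], TrainConfig(epochs=2, seed=2))
        clf.save(tmp_path / "bundle")
        back = load_classifier(tmp_path / "bundle")
        probe = texts[:7]
        a = clf.predict_texts(probe)
        b = back.predict_texts(probe)
        assert np.allclose(a.probabilities, b.probabilities)
        assert (a.labels == b.labels).all()
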