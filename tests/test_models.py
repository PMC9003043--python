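"""Classifier contracts: gradients, determinism, capacity, context sensitivity."""

import numpy as np
import pytest

from posturekit import nn
from posturekit.exceptions import ConfigError, SchemaError
from posturekit.models import (
    LSTMSequenceClassifier,
    MLPPostureClassifier,
    kfold_validate,
    predict_frames,
    train_mlp,
)


def separable_frames(seed, n_per_class=60, n_features=6, margin=3.0):
    """Linearly separable 5-class frame data with wide margins."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for cls in range(1, 6):
        center = np.zeros(n_features)
        center[cls % n_features] = margin
        center[(cls + 2) % n_features] = -margin
        X.append(center + 0.3 * rng.standard_normal((n_per_class, n_features)))
        y.append(np.full(n_per_class, cls))
    return np.vstack(X), np.concatenate(y)


def tiny_sequences(seed, n_seq=10, T=20, D=4, n_classes=3):
    """Small noiseless sequence set where the label tracks a step signal."""
    rng = np.random.default_rng(seed)
    X = 0.05 * rng.standard_normal((n_seq, T, D))
    y = np.empty((n_seq, T), dtype=int)
    for s in range(n_seq):
        cls = int(rng.integers(1, n_classes + 1))
        flip = int(rng.integers(T // 4, 3 * T // 4))
        other = cls % n_classes + 1
        X[s, :flip, 0] += cls
        X[s, flip:, 0] += other
        y[s, :flip] = cls
        y[s, flip:] = other
    return X, y


class TestGradients:
    def test_bptt_matches_numerical_gradients(self, monkeypatch):
        monkeypatch.setattr(nn, "_DT", np.float64)
        rng = np.random.default_rng(0)
        net = nn.build_variant(
            "2BLSTM2D", rng, input_dim=3, n_classes=4, hidden1=5, hidden2=4, dropout=0.0
        )
        X = rng.standard_normal((2, 7, 3))
        y = rng.integers(0, 4, (2, 7))
        r = np.random.default_rng(1)
        loss, dl = nn.softmax_cross_entropy(net.forward(X, train=False, rng=r), y)
        net.backward(dl)
        eps = 1e-6
        check_rng = np.random.default_rng(2)
        for p, g in net.params_grads():
            flat, gflat = p.reshape(-1), g.reshape(-1)
            for idx in check_rng.integers(0, flat.size, 3):
                orig = flat[idx]
                flat[idx] = orig + eps
                l1, _ = nn.softmax_cross_entropy(net.forward(X, train=False, rng=r), y)
                flat[idx] = orig - eps
                l2, _ = nn.softmax_cross_entropy(net.forward(X, train=False, rng=r), y)
                flat[idx] = orig
                num = (l1 - l2) / (2 * eps)
                assert abs(num - gflat[idx]) <= 1e-4 * max(1.0, abs(num))


class TestMLP:
    def test_five_output_classes(self):
        X, y = separable_frames(0)
        model = MLPPostureClassifier(max_epochs=50, random_state=0).fit(X, y)
        assert list(model.classes_) == [1, 2, 3, 4, 5]
        assert model.predict_proba(X[:3]).shape == (3, 5)

    def test_separable_data_reaches_95_percent(self):
        X, y = separable_frames(1)
        Xt, yt = separable_frames(99)
        model = MLPPostureClassifier(random_state=1).fit(X, y)
        assert np.mean(model.predict(Xt) == yt) >= 0.95

    def test_same_seed_identical_fit(self):
        X, y = separable_frames(2)
        p1 = MLPPostureClassifier(max_epochs=60, random_state=7).fit(X, y).predict_proba(X)
        p2 = MLPPostureClassifier(max_epochs=60, random_state=7).fit(X, y).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_feature_subset_mask_applied(self):
        X, y = separable_frames(3)
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[:3] = True
        model = MLPPostureClassifier(max_epochs=30, random_state=0, feature_subset=mask)
        model.fit(X, y)
        assert model._mlp_.n_features_in_ == 3

    def test_kfold_protocol_returns_k_scores(self):
        X, y = separable_frames(4, n_per_class=30)
        model, folds = train_mlp(X, y, k_folds=5, max_epochs=40, random_state=0)
        assert folds.shape == (5,)
        assert np.all((folds >= 0) & (folds <= 1))
        assert hasattr(model, "classes_")


class TestLSTMContracts:
    def test_one_label_per_frame_including_sentinels(self):
        X, y = tiny_sequences(0)
        X[0, 3:6] = 999.0  # embedded sentinel frames
        model = LSTMSequenceClassifier(
            variant="LSTM", hidden1=8, dropout=0.0, epochs=2, random_state=0
        ).fit(X, y)
        pred = model.predict(X)
        assert pred.shape == y.shape

    def test_probabilities_normalized_and_consistent_with_labels(self):
        X, y = tiny_sequences(1)
        model = LSTMSequenceClassifier(
            variant="BLSTM", hidden1=8, dropout=0.2, epochs=2, random_state=0
        ).fit(X, y)
        labels, probs = predict_frames(model, X)
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-6)
        assert np.array_equal(labels, model.classes_[probs.argmax(axis=-1)])

    def test_same_seed_bit_identical_training(self):
        X, y = tiny_sequences(2)
        kw = dict(variant="2LSTM", hidden1=8, hidden2=6, dropout=0.3, epochs=3, random_state=11)
        p1 = LSTMSequenceClassifier(**kw).fit(X, y).predict_proba(X)
        p2 = LSTMSequenceClassifier(**kw).fit(X, y).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_unknown_variant_rejected(self):
        X, y = tiny_sequences(3)
        with pytest.raises(ConfigError):
            LSTMSequenceClassifier(variant="GRU", epochs=1).fit(X, y)

    def test_shape_mismatch_rejected(self):
        X, y = tiny_sequences(4)
        with pytest.raises(SchemaError):
            LSTMSequenceClassifier(epochs=1).fit(X, y[:, :-1])

    @pytest.mark.parametrize("variant", nn.VARIANTS)
    def test_every_variant_memorizes_a_tiny_noiseless_set(self, variant):
        X, y = tiny_sequences(5, n_seq=8, T=15)
        model = LSTMSequenceClassifier(
            variant=variant, hidden1=24, hidden2=12, dropout=0.0, epochs=120,
            learning_rate=2e-2, random_state=3,
        ).fit(X, y)
        assert model.score(X, y) >= 0.99

    def test_lstm_prediction_depends_on_context_but_mlp_does_not(self):
        X, y = tiny_sequences(6, n_seq=12, T=20)
        model = LSTMSequenceClassifier(
            variant="BLSTM", hidden1=16, dropout=0.0, epochs=30,
            learning_rate=1e-2, random_state=4,
        ).fit(X, y)
        probe = X[:1].copy()
        p_before = model.predict_proba(probe)[0, 10]
        probe[0, :8] = X[1, :8]  # change only the context of frame 10
        probe[0, 12:] = X[1, 12:]
        p_after = model.predict_proba(probe)[0, 10]
        assert np.max(np.abs(p_before - p_after)) > 1e-3

        # frame classifier: prediction of one frame is a pure function of it
        Xf, yf = separable_frames(7)
        mlp = MLPPostureClassifier(max_epochs=40, random_state=0).fit(Xf, yf)
        single = mlp.predict_proba(Xf[5:6])
        in_batch = mlp.predict_proba(Xf)[5:6]
        assert np.allclose(single, in_batch, atol=1e-12)

    def test_shuffling_changes_trajectory_but_not_seeded_reproducibility(self):
        X, y = tiny_sequences(8, n_seq=12)
        kw = dict(variant="LSTM", hidden1=8, dropout=0.0, epochs=3, batch_size=4)
        shuffled = LSTMSequenceClassifier(**kw, shuffle_each_epoch=True, random_state=5).fit(X, y)
        plain = LSTMSequenceClassifier(**kw, shuffle_each_epoch=False, random_state=5).fit(X, y)
        assert not np.allclose(shuffled.history_["loss"], plain.history_["loss"])

    def test_standardize_option_fits_on_training_data(self):
        X, y = tiny_sequences(9)
        model = LSTMSequenceClassifier(
            variant="LSTM", hidden1=8, dropout=0.0, epochs=2,
            standardize=True, random_state=0,
        ).fit(X, y)
        assert model._mean_ is not None
        assert model.predict(X).shape == y.shape


class TestDirectionalProperties:
    def test_bidirectional_beats_unidirectional_on_transition_rich_data(self):
        """Mean accuracy over paired seeds: BLSTM >= LSTM on step-label data."""
        uni, bi = [], []
        for seed in range(10):
            X, y = tiny_sequences(100 + seed, n_seq=16, T=24)
            Xt, yt = tiny_sequences(200 + seed, n_seq=8, T=24)
            kw = dict(hidden1=10, dropout=0.0, epochs=12, learning_rate=1e-2,
                      random_state=seed)
            uni.append(LSTMSequenceClassifier(variant="LSTM", **kw).fit(X, y).score(Xt, yt))
            bi.append(LSTMSequenceClassifier(variant="BLSTM", **kw).fit(X, y).score(Xt, yt))
        assert np.mean(bi) >= np.mean(uni)
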