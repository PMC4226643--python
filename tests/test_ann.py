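"""Perceptron: activation, backprop gradients, training, prediction."""

import numpy as np
import pytest

import taxofeat as tf
from taxofeat.ann import _forward, _gradients


def finite_difference_check(rng, eps=1e-5):
    """Norm-relative error between analytic and central-difference
    gradients for one random 15-5-3 network and pattern."""
    w1 = rng.uniform(-.5, .5, (15, 5))
    b1 = rng.uniform(-.5, .5, 5)
    w2 = rng.uniform(-.5, .5, (5, 3))
    b2 = rng.uniform(-.5, .5, 3)
    x = rng.normal(0, 1, 15)
    t = rng.uniform(0, 1, 3)
    _, gw1, gb1, gw2, gb2 = _gradients(x, t, w1, b1, w2, b2)
    analytic = np.concatenate([g.ravel() for g in (gw1, gb1, gw2, gb2)])

    def loss():
        _, y = _forward(x, w1, b1, w2, b2)
        return 0.5 * float((y - t) @ (y - t))

    numeric = []
    for arr in (w1, b1, w2, b2):
        flat = arr.ravel()
        for i in range(flat.size):
            old = flat[i]
            flat[i] = old + eps
            lp = loss()
            flat[i] = old - eps
            lm = loss()
            flat[i] = old
            numeric.append((lp - lm) / (2 * eps))
    numeric = np.array(numeric)
    return (np.linalg.norm(analytic - numeric)
            / max(np.linalg.norm(analytic), np.linalg.norm(numeric)))


def toy_table(rng, n_per=20, gap=4.0):
    """Two linearly separable Gaussian blobs padded to 15 features."""
    X = np.zeros((2 * n_per, 15))
    X[:n_per, :3] = rng.normal(0, 1, (n_per, 3))
    X[n_per:, :3] = rng.normal(gap, 1, (n_per, 3))
    labels = ["lo"] * n_per + ["hi"] * n_per
    return tf.feature_table(X, labels)


class TestSigmoid:
    def test_midpoint_and_symmetry(self):
        assert tf.sigmoid(0.0) == 0.5
        assert tf.sigmoid(3.0) + tf.sigmoid(-3.0) == pytest.approx(1.0)

    def test_saturation_without_overflow(self):
        for x in (-1e4, -750.0, 750.0, 1e4):
            y = tf.sigmoid(x)
            assert 0.0 <= y <= 1.0 and np.isfinite(y)

    def test_monotone(self, rng):
        xs = np.sort(rng.normal(0, 10, 100))
        ys = tf.sigmoid(xs)
        assert np.all(np.diff(ys) >= 0)


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        worst = max(finite_difference_check(rng) for _ in range(30))
        assert worst <= 1e-6


class TestTraining:
    def test_same_seed_bit_reproducible(self, rng):
        table = toy_table(rng)
        cfg = tf.TrainConfig(learning_rate=0.2, generations=2000, hidden=6,
                             seed=11)
        a = tf.train(table, cfg)
        b = tf.train(table, cfg)
        assert np.array_equal(a.w_hidden, b.w_hidden)
        assert np.array_equal(a.w_out, b.w_out)
        assert np.array_equal(a.loss_trace, b.loss_trace)

    def test_xor_reaches_full_training_accuracy(self):
        X = np.zeros((4, 15))
        X[:, :2] = [[0, 0], [0, 1], [1, 0], [1, 1]]
        labels = ["even", "odd", "odd", "even"]
        table = tf.feature_table(X, labels)
        model = tf.train(table, tf.TrainConfig(learning_rate=0.5,
                                               generations=20_000, hidden=4,
                                               seed=3))
        assert tf.predict_batch(model, table) == labels

    def test_loss_decreases_on_separable_data(self, rng):
        table = toy_table(rng)
        model = tf.train(table, tf.TrainConfig(learning_rate=0.3,
                                               generations=4000, hidden=5,
                                               seed=2))
        epochs = model.loss_trace.reshape(100, -1).mean(axis=1)
        assert epochs[-1] < 0.05 * epochs[0]
        # averaged loss trends down: overwhelming majority of epoch steps
        assert np.mean(np.diff(epochs) < 0) > 0.9

    def test_training_unit_is_pattern_presentations(self, rng):
        table = toy_table(rng, n_per=10)
        model = tf.train(table, tf.TrainConfig(generations=7, seed=0))
        assert model.loss_trace.shape == (7,)

    def test_single_species_errors(self, rng):
        X = rng.normal(size=(4, 15))
        with pytest.raises(ValueError, match="2 species"):
            tf.train(tf.feature_table(X, ["only"] * 4))

    def test_non_finite_feature_names_row(self, rng):
        X = rng.normal(size=(4, 15))
        X[2, 5] = np.nan
        with pytest.raises(ValueError, match="row 2"):
            tf.train(tf.feature_table(X, ["a", "a", "b", "b"]))

    def test_rescaled_features_give_identical_predictions(self, rng):
        """z-scoring makes the fit invariant to per-feature affine unit
        changes: train on rescaled data, predict rescaled patterns, get
        the same species."""
        table = toy_table(rng)
        scale = rng.uniform(0.5, 200.0, 15)
        shift = rng.normal(0, 10, 15)
        rescaled = table.copy()
        rescaled[tf.FEATURE_NAMES] = (table[tf.FEATURE_NAMES] * scale
                                      + shift)
        cfg = tf.TrainConfig(learning_rate=0.2, generations=3000, hidden=5,
                             seed=4)
        m0 = tf.train(table, cfg)
        m1 = tf.train(rescaled, cfg)
        assert (tf.predict_batch(m0, table)
                == tf.predict_batch(m1, rescaled))


@pytest.fixture(scope="module")
def model():
    rng = np.random.default_rng(5)
    return tf.train(toy_table(rng),
                    tf.TrainConfig(learning_rate=0.3, generations=4000,
                                   hidden=5, seed=5))


class TestPrediction:

    def test_argmax_and_binary_outputs(self, model):
        X = np.zeros((1, 15))
        p = tf.predict(model, X[0])
        assert p.species in model.labels
        assert p.species == model.labels[int(np.argmax(p.raw))]
        assert np.array_equal(p.binary, (p.raw >= 0.5).astype(int))

    def test_unconfident_flag(self, model):
        # push far outside the training cloud: both sigmoids near 0
        fv = np.full(15, 1e6)
        p = tf.predict(model, fv)
        if not p.binary.any():
            assert not p.confident
        assert p.species in model.labels  # argmax class still returned

    def test_dimension_mismatch_errors(self, model):
        with pytest.raises(ValueError, match="shape"):
            tf.predict(model, np.zeros(7))


class TestSerialization:
    def test_round_trip(self, tmp_path, rng):
        table = toy_table(rng)
        model = tf.train(table, tf.TrainConfig(generations=500, hidden=4,
                                               seed=9))
        path = tmp_path / "model.tfm"
        tf.save_model(model, path)
        back = tf.load_model(path)
        assert back.labels == model.labels
        np.testing.assert_array_equal(back.w_hidden, model.w_hidden)
        np.testing.assert_array_equal(back.scaler_sd, model.scaler_sd)
        assert back.config == model.config
        assert (tf.predict_batch(back, table)
                == tf.predict_batch(model, table))

    def test_rejects_foreign_file(self, tmp_path):
        path = tmp_path / "x.json"
        path.write_text("{}")
        with pytest.raises(ValueError, match="not a taxofeat model"):
            tf.load_model(path)
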