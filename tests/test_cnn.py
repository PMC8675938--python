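"""Channel classifier: architecture contracts, gradients, training."""

import numpy as np
import pytest

from cardiomech.cnn import (
    ChannelClassifier,
    Cnn1d,
    CnnSpec,
    build_model,
    predict_cycles,
    predict_proba,
    train_channel,
)
from cardiomech.errors import ModelStateError, ShapeError, TrainingError


def _separable(n=120, seed=0, gap=0.6):
    rng = np.random.default_rng(seed)
    x = rng.random((n, 750)).astype(np.float32) * 0.3
    y = rng.integers(0, 2, n)
    x[y == 1, 210:240] += gap
    return x, y


def test_forward_pass_is_a_probability_pair():
    net = Cnn1d(CnnSpec(), seed=0)
    x = np.random.default_rng(1).random((7, 750))
    probs = net.forward(x.astype(np.float32))
    assert probs.shape == (7, 2)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(probs >= 0)


def test_same_seed_gives_identical_initial_weights():
    a = Cnn1d(CnnSpec(), seed=5).get_weights()
    b = Cnn1d(CnnSpec(), seed=5).get_weights()
    for key in a:
        np.testing.assert_array_equal(a[key], b[key])


def test_wrong_input_length_rejected():
    net = Cnn1d(CnnSpec(), seed=0)
    with pytest.raises(ShapeError):
        net.forward(np.zeros((3, 700), dtype=np.float32))


def test_backprop_matches_finite_differences():
    """Analytic gradients agree with central differences on a tiny net."""
    spec = CnnSpec(
        input_len=48, n_filters=(4, 3, 3), kernel_size=5, fc_units=12,
        conv_dropout=0.0, fc_dropout=0.0, batch_size=6,
    )
    net = Cnn1d(spec, seed=3)
    rng = np.random.default_rng(7)
    x = rng.standard_normal((6, 48)).astype(np.float32)
    y = rng.integers(0, 2, 6)
    eye = np.eye(2, dtype=np.float32)

    def loss():
        p = net.forward(x, train=True)
        return -np.log(np.clip(p[np.arange(6), y], 1e-12, None)).mean()

    base_probs = net.forward(x, train=True)
    net.backward(base_probs, eye[y])
    checked, mismatches = 0, 0
    for name, obj, attr in net._param_items():
        flat_w = getattr(obj, attr).reshape(-1)
        flat_g = getattr(obj, "d" + attr).reshape(-1)
        for idx in rng.choice(flat_w.size, size=min(3, flat_w.size), replace=False):
            eps = 5e-3
            orig = flat_w[idx]
            flat_w[idx] = orig + eps
            up = loss()
            flat_w[idx] = orig - eps
            down = loss()
            flat_w[idx] = orig
            numeric = (up - down) / (2 * eps)
            rel = abs(numeric - flat_g[idx]) / max(1e-4, abs(numeric) + abs(flat_g[idx]))
            mismatches += rel > 0.05
            checked += 1
    # ReLU/max-pool kinks can corrupt the odd finite difference in float32
    assert checked >= 30 and mismatches <= 2


def test_training_separates_separable_features():
    x, y = _separable(160)
    model = train_channel(x[:120], y[:120], x[120:], y[120:], epochs=15, seed=1)
    assert max(model.history["val_accuracy"]) >= 0.95
    assert model.selected_epoch == int(
        np.argmax(model.history["val_accuracy"])) + 1


def test_permuted_labels_stay_at_chance():
    rng = np.random.default_rng(3)
    x, _ = _separable(200, seed=3)
    y = rng.permutation(np.repeat([0, 1], 100))
    model = train_channel(x[:140], y[:140], x[140:], y[140:], epochs=5, seed=2)
    acc = model.history["val_accuracy"][model.selected_epoch - 1]
    n = 60
    band = 3 * np.sqrt(0.25 / n)
    # selection over epochs biases upward; allow the selection maximum
    assert 0.5 - band <= acc <= 0.5 + 2 * band


def test_one_epoch_history():
    x, y = _separable(60)
    model = train_channel(x, y, x, y, epochs=1, seed=0)
    assert model.selected_epoch == 1
    assert len(model.history["train_loss"]) == 1


def test_single_class_training_rejected():
    x, _ = _separable(40)
    with pytest.raises(TrainingError):
        train_channel(x, np.zeros(40, int), x, np.zeros(40, int), epochs=1, seed=0)


def test_training_is_bit_reproducible():
    x, y = _separable(80)
    a = train_channel(x[:60], y[:60], x[60:], y[60:], epochs=3, seed=9)
    b = train_channel(x[:60], y[:60], x[60:], y[60:], epochs=3, seed=9)
    assert a.history == b.history
    for key in a.weights:
        np.testing.assert_array_equal(a.weights[key], b.weights[key])


def test_network_can_memorise_50_vectors():
    rng = np.random.default_rng(13)
    x = rng.random((50, 750)).astype(np.float32)
    y = rng.integers(0, 2, 50)
    spec = CnnSpec(conv_dropout=0.0, fc_dropout=0.0, batch_size=50)
    model = train_channel(x, y, x, y, spec=spec, epochs=100, seed=4)
    assert min(model.history["train_loss"]) < 0.05


def test_prediction_contract():
    x, y = _separable(80)
    model = train_channel(x[:60], y[:60], x[60:], y[60:], epochs=10, seed=1)
    probs = predict_cycles(model, np.vstack([x[:5], x[:5]]))
    np.testing.assert_array_equal(probs[:5], probs[5:])
    assert np.all((probs >= 0) & (probs <= 1))
    held_x, held_y = _separable(60, seed=21)
    held = predict_cycles(model, held_x)
    assert held[held_y == 1].mean() > held[held_y == 0].mean()


def test_untrained_model_cannot_predict():
    model = build_model(CnnSpec(), seed=0, channel="scg_x")
    with pytest.raises(ModelStateError):
        predict_cycles(model, np.zeros((2, 750)))


def test_save_load_round_trip(tmp_path):
    x, y = _separable(60)
    model = train_channel(x[:40], y[:40], x[40:], y[40:], epochs=2, seed=6,
                          channel="gcg_y")
    path = tmp_path / "model.npz"
    model.save(path)
    back = ChannelClassifier.load(path)
    assert back.channel == "gcg_y"
    assert back.selected_epoch == model.selected_epoch
    np.testing.assert_array_equal(
        predict_cycles(back, x[:10]), predict_cycles(model, x[:10])
    )
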