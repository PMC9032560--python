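"""Sequence network: preprocessing, shape algebra, training behavior."""

import numpy as np
import pytest

from capnopred.errors import NotFittedError, PreprocessingError
from capnopred.seqnet import (
    NetworkConfig, build_network, count_parameters, load_network,
    predict_sequence, preprocess_sequence, save_network, train_network,
)


def shape_recurrence(length, kernel, pool, blocks=3):
    """Independent one-line oracle for the conv/pool length algebra."""
    out = []
    for _ in range(blocks):
        length = (length - kernel + 1)
        conv = length
        length = length // pool
        out.append((conv, length))
    return out


class TestPreprocess:
    def test_constant_series_scaled(self):
        out = preprocess_sequence(np.full(5000, 10.0))
        assert out.shape == (2400,)
        np.testing.assert_allclose(out, 0.25)

    def test_onset_alignment(self):
        raw = np.zeros(5000)
        raw[100:] = 30.0
        out = preprocess_sequence(raw)
        assert out[0] == pytest.approx(30.0 / 40.0)

    def test_padding_with_final_value(self):
        raw = np.concatenate([np.zeros(10), np.linspace(5, 38, 1990)])
        out = preprocess_sequence(raw)
        np.testing.assert_allclose(out[-400:], 38.0 / 40.0, rtol=1e-6)

    def test_no_onset_is_error(self):
        with pytest.raises(PreprocessingError):
            preprocess_sequence(np.zeros(5000))


class TestArchitecture:
    def test_default_layer_lengths_match_recurrence_oracle(self):
        cfg = NetworkConfig()
        assert cfg.layer_lengths() == shape_recurrence(2400, 5, 5)
        assert cfg.layer_lengths()[0][0] == 2396

    @pytest.mark.parametrize("length", [250, 300, 1000, 2400, 7777])
    def test_shape_algebra_any_valid_length(self, length):
        cfg = NetworkConfig(input_length=length)
        assert cfg.layer_lengths() == shape_recurrence(length, 5, 5)

    def test_flatten_width_default(self):
        assert NetworkConfig().flatten_width == 576

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            build_network(NetworkConfig(input_length=10))

    def test_parameter_counts_match_weight_arrays(self):
        net = build_network(NetworkConfig())
        counts = count_parameters(net)
        assert counts["C1"] == net.conv1.w.size + net.conv1.b.size
        assert counts["C2"] == 5 * 32 * 64 + 64
        assert counts["F2"] == 576 * 2 + 2
        assert counts["P1"] == counts["D2"] == counts["F1"] == 0


@pytest.fixture(scope="module")
def toy_training_data():
    """Sequences whose plateau timing/height encode the targets."""
    rng = np.random.default_rng(8)
    n = 30
    x = np.zeros((n, 2400), dtype=np.float32)
    y = np.zeros((n, 2))
    for i in range(n):
        level = rng.uniform(0.5, 1.2)
        knee = rng.integers(200, 1200)
        x[i, :knee] = np.linspace(0, level, knee)
        x[i, knee:] = level
        y[i] = (2.0 * level, 2.5 * level + knee / 2400.0)
    return x, y


class TestTraining:
    def test_loss_trend_decreases(self, toy_training_data):
        x, y = toy_training_data
        net = build_network(NetworkConfig(epochs=30, seed=0))
        hist = train_network(net, x, y)
        losses = hist["train_loss"]
        assert np.mean(losses[-10:]) < np.mean(losses[:10])
        assert losses[-1] <= losses[0]

    def test_constant_targets_near_zero_loss(self, toy_training_data):
        x, _ = toy_training_data
        y = np.full((x.shape[0], 2), 3.0)
        net = build_network(NetworkConfig(epochs=25, seed=0))
        hist = train_network(net, x, y)
        assert hist["train_loss"][-1] < 0.05

    def test_fixed_seed_reproducible_history(self, toy_training_data):
        x, y = toy_training_data
        hists = []
        for _ in range(2):
            net = build_network(NetworkConfig(epochs=5, seed=11))
            hists.append(train_network(net, x, y)["train_loss"])
        assert hists[0] == hists[1]

    def test_needs_two_subjects(self):
        net = build_network(NetworkConfig(epochs=1))
        with pytest.raises(ValueError):
            train_network(net, np.zeros((1, 2400)), np.zeros((1, 2)))


class TestPrediction:
    def test_output_shape_and_floor(self, toy_training_data):
        x, y = toy_training_data
        net = build_network(NetworkConfig(epochs=5, seed=0))
        train_network(net, x, y)
        preds = predict_sequence(net, x)
        assert preds.shape == (x.shape[0], 2)
        assert np.all(preds >= 0.1)

    def test_duplicate_rows_identical_predictions(self, toy_training_data):
        x, y = toy_training_data
        net = build_network(NetworkConfig(epochs=5, seed=0))
        train_network(net, x, y)
        batch = np.vstack([x[:1], x[:1], x[:1]])
        preds = predict_sequence(net, batch)
        assert np.all(preds[0] == preds[1]) and np.all(preds[1] == preds[2])

    def test_untrained_network_rejected(self):
        net = build_network(NetworkConfig())
        with pytest.raises(NotFittedError):
            predict_sequence(net, np.zeros((2, 2400)))

    def test_wrong_length_rejected(self, toy_training_data):
        x, y = toy_training_data
        net = build_network(NetworkConfig(epochs=2, seed=0))
        train_network(net, x, y)
        with pytest.raises(ValueError):
            predict_sequence(net, np.zeros((2, 100)))

    def test_save_load_round_trip(self, toy_training_data, tmp_path):
        x, y = toy_training_data
        net = build_network(NetworkConfig(epochs=3, seed=0))
        train_network(net, x, y)
        save_network(net, tmp_path / "net")
        loaded = load_network(tmp_path / "net")
        np.testing.assert_array_equal(
            predict_sequence(net, x[:5]), predict_sequence(loaded, x[:5])
        )


class TestGeneralization:
    def test_heldout_r2_on_synthetic_cohort(self, cohort300):
        """The network extracts real spirometric signal from the CO2 series.

        Scaled-down fit (240 training subjects, 30 epochs); thresholds
        are correspondingly soft.
        """
        from capnopred.metrics import rmse_r2
        seqs = np.stack([preprocess_sequence(r.sequence) for r in cohort300])
        y = np.array([[r.fev1, r.fvc] for r in cohort300])
        tr, te = np.arange(240), np.arange(240, 300)
        net = build_network(NetworkConfig(epochs=30, seed=0))
        train_network(net, seqs[tr], y[tr])
        preds = predict_sequence(net, seqs[te])
        _, r2_fev1 = rmse_r2(preds[:, 0], y[te, 0])
        _, r2_fvc = rmse_r2(preds[:, 1], y[te, 1])
        assert r2_fev1 > 0.15
        assert r2_fvc > 0.05
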