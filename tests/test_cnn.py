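"""Patch-classifier architecture, training behaviour and prediction contracts."""

import numpy as np
import pytest

from blcb.cnn import (
    ModelConfig,
    TrainConfig,
    build_classifier,
    load_model,
    predict_vessel_prob,
    save_model,
    train_classifier,
)

# small configurations keep these tests fast without changing the topology
TINY = ModelConfig(input_size=16, base_filters=2, fc_sizes=(8, 4, 4))
SMALL = ModelConfig(input_size=32, base_filters=4, fc_sizes=(16, 8, 8))


def separable_patches(n, size, rng):
    """Dark-ridge (vessel-like) vs flat windows: trivially separable."""
    x = rng.normal(0.5, 0.05, size=(n, size, size)).astype(np.float32)
    y = np.zeros(n, dtype=np.int8)
    y[: n // 2] = 1
    x[: n // 2, :, size // 2 - 1: size // 2 + 1] -= 0.3
    return np.clip(x, 0, 1), y


class TestArchitecture:
    def test_ten_weighted_layers_and_filter_doubling(self):
        model = build_classifier(ModelConfig())
        assert len(model.weighted_layers) == 10
        assert model.conv_filter_counts == [32, 32, 64, 64, 128, 128]
        assert model.dropout_rates == [0.25] * 6

    def test_trainable_parameter_count_matches_hand_tally(self):
        # independent layer-by-layer tally for the default configuration:
        # conv W = 9*cin*cout, conv b = cout, BN = 2*channels,
        # dense W = nin*nout, dense b = nout; flatten side 64/2^3 = 8.
        conv = [(1, 32), (32, 32), (32, 64), (64, 64), (64, 128), (128, 128)]
        tally = sum(9 * ci * co + co + 2 * co for ci, co in conv)
        fc = [(8 * 8 * 128, 256), (256, 128), (128, 64)]
        tally += sum(ni * no + no + 2 * no for ni, no in fc)
        tally += 64 * 1 + 1
        assert tally == 2_426_849  # frozen
        assert build_classifier(ModelConfig()).count_params() == tally

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(input_size=60)

    def test_custom_dropout_propagates(self):
        model = build_classifier(ModelConfig(dropout_rate=0.1))
        assert model.dropout_rates == [0.1] * 6


class TestTraining:
    def test_contradictory_labels_cap_accuracy_at_half(self, rng):
        """A window duplicated with labels 0 and 1 can never beat chance."""
        x = np.tile(rng.random((1, 16, 16), dtype=np.float32), (30, 1, 1))
        y = np.arange(30) % 2
        model = build_classifier(TINY, seed=0)
        train_classifier(model, x, y, TrainConfig(epochs=5, batch_size=10, seed=0))
        p = predict_vessel_prob(model, x)
        acc = np.mean((p >= 0.5) == (y == 1))
        assert acc == 0.5  # identical windows -> identical predictions

    def test_overfits_separable_patches(self, rng):
        """Capacity check: 3-seed majority reaches >= 0.95 accuracy on its
        own training set (measured in evaluation mode after training)."""
        wins = 0
        for seed in (0, 1, 2):
            x, y = separable_patches(200, 32, rng)
            model = build_classifier(SMALL, seed=seed)
            train_classifier(model, x, y,
                            TrainConfig(epochs=30, batch_size=64, seed=seed))
            p = predict_vessel_prob(model, x)
            if np.mean((p >= 0.5) == (y == 1)) >= 0.95:
                wins += 1
        assert wins >= 2

    def test_seed_determinism(self, rng):
        x, y = separable_patches(60, 16, rng)
        losses = []
        for _ in range(2):
            model = build_classifier(TINY, seed=9)
            train_classifier(model, x, y, TrainConfig(epochs=2, seed=9))
            losses.append(model.history[-1]["loss"])
        assert losses[0] == losses[1]

    def test_provenance_recorded(self, rng):
        x, y = separable_patches(20, 16, rng)
        model = build_classifier(TINY, seed=0)
        cfg = TrainConfig(epochs=1, batch_size=8, seed=4)
        train_classifier(model, x, y, cfg)
        assert model.train_provenance == {
            "epochs": 1, "batch_size": 8, "learning_rate": 1e-3, "seed": 4}
        assert len(model.history) == 1

    def test_empty_training_set_rejected(self):
        model = build_classifier(TINY)
        with pytest.raises(ValueError):
            train_classifier(model, np.empty((0, 16, 16)), np.empty(0))


class TestPrediction:
    def test_probabilities_bounded_and_replicable(self, rng):
        model = build_classifier(SMALL, seed=1)
        w = rng.random((9, 32, 32), dtype=np.float32)
        p = predict_vessel_prob(model, w)
        assert np.all((p >= 0) & (p <= 1))
        dup = predict_vessel_prob(model, np.stack([w[0], w[0]]))
        assert dup[0] == dup[1]

    def test_batch_partition_invariance(self, rng):
        model = build_classifier(SMALL, seed=2)
        w = rng.random((23, 32, 32), dtype=np.float32)
        a = predict_vessel_prob(model, w, batch_size=1)
        b = predict_vessel_prob(model, w, batch_size=64)
        assert np.allclose(a, b, atol=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        model = build_classifier(SMALL)
        with pytest.raises(ValueError):
            predict_vessel_prob(model, rng.random((3, 16, 16)))


class TestSerialization:
    def test_roundtrip_preserves_predictions(self, rng, tmp_path):
        x, y = separable_patches(40, 16, rng)
        model = build_classifier(TINY, seed=5)
        train_classifier(model, x, y, TrainConfig(epochs=2, seed=5))
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        w = rng.random((5, 16, 16), dtype=np.float32)
        assert np.array_equal(predict_vessel_prob(model, w),
                              predict_vessel_prob(loaded, w))
        assert loaded.train_provenance == model.train_provenance
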