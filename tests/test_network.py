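"""Classifier networks: construction, training behavior, inference contracts."""

import numpy as np
import pytest

from somaticnet.network import (
    NetSpec,
    TrainConfig,
    build_model,
    forward_logits,
    load_model,
    predict,
    save_model,
    train_model,
)
from somaticnet.nn import sigmoid

# a small input shape for fast optimization-behavior tests
TOY_SPEC = NetSpec(
    input_shape=(12, 12, 5), conv_blocks=3, pool_positions=(1,), pool_sizes=(2,),
    dense_units=(16, 8), scale=0.1,
)


def toy_problem(n, seed=0):
    """Separable toy data: class 1 carries a positive offset in channel 0 of
    the central patch."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 0.3, size=(n, 12, 12, 5)).astype(np.float32)
    y = (rng.random(n) < 0.5).astype(np.float32)
    X[y == 1, 4:8, 4:8, 0] += 1.0
    return X, y


class TestBuild:
    def test_full_scale_parameter_count_near_target(self):
        model = build_model(NetSpec(scale=1.0))
        assert abs(model.n_params - 3_500_000) / 3_500_000 < 0.15

    def test_introspection_reports_blocks_and_shape(self):
        model = build_model(NetSpec(scale=0.1))
        assert model.spec.conv_blocks == 10
        assert model.spec.input_shape == (100, 70, 5)

    def test_small_scale_model_is_small_and_runs(self):
        model = build_model(NetSpec(scale=0.1))
        assert model.n_params < 200_000
        out = predict(model, np.zeros((2, 100, 70, 5), dtype=np.float32))
        assert out.shape == (2,)

    def test_all_zero_input_gives_finite_probability(self):
        model = build_model(NetSpec(scale=0.1), seed=3)
        p = predict(model, np.zeros((1, 100, 70, 5), dtype=np.float32))
        assert np.isfinite(p).all()
        assert 0.0 < p[0] < 1.0

    def test_probabilities_bounded(self):
        model = build_model(TOY_SPEC, seed=1)
        X, _ = toy_problem(64)
        p = predict(model, X)
        assert ((p >= 0.0) & (p <= 1.0)).all()

    def test_shape_mismatch_rejected(self):
        model = build_model(TOY_SPEC)
        with pytest.raises(ValueError, match="shape"):
            predict(model, np.zeros((1, 10, 10, 5), dtype=np.float32))

    def test_unknown_arch_rejected(self):
        with pytest.raises(ValueError, match="arch_style"):
            build_model(NetSpec(arch_style="transformer"))


class TestTraining:
    def test_loss_decreases_on_learnable_problem(self):
        X, y = toy_problem(400, seed=2)
        model = build_model(TOY_SPEC, seed=2)
        hist = train_model(model, X, y, TrainConfig(epochs=3, learning_rate=1e-3, seed=2))
        losses = hist["train_loss"]
        assert losses[1] < losses[0] and losses[2] < losses[1]

    def test_learns_to_high_heldout_accuracy(self):
        X, y = toy_problem(600, seed=3)
        Xt, yt = toy_problem(300, seed=4)
        model = build_model(TOY_SPEC, seed=3)
        train_model(model, X, y, TrainConfig(epochs=10, learning_rate=1e-3, seed=3))
        acc = np.mean((predict(model, Xt) >= 0.5) == (yt >= 0.5))
        assert acc >= 0.95

    def test_permuted_labels_give_chance_accuracy(self):
        """No-signal control: shuffling labels leaves held-out accuracy at
        chance level."""
        rng = np.random.default_rng(5)
        X, y = toy_problem(600, seed=5)
        y_perm = rng.permutation(y)
        Xt, yt = toy_problem(1000, seed=6)
        model = build_model(TOY_SPEC, seed=5)
        # kept short: long training can memorize the permuted labels into a
        # systematic (anti-)bias on held-out data
        train_model(model, X, y_perm,
                    TrainConfig(epochs=2, min_epochs=2, learning_rate=1e-3, seed=5))
        acc = np.mean((predict(model, Xt) >= 0.5) == (yt >= 0.5))
        assert abs(acc - 0.5) <= 0.05

    def test_single_class_rejected(self):
        X, _ = toy_problem(64)
        model = build_model(TOY_SPEC)
        with pytest.raises(ValueError, match="single class"):
            train_model(model, X, np.ones(64), TrainConfig(epochs=1))

    def test_history_records_all_series(self):
        X, y = toy_problem(200)
        model = build_model(TOY_SPEC, seed=7)
        hist = train_model(model, X, y, TrainConfig(epochs=2, seed=7))
        assert set(hist) == {"train_loss", "val_loss", "val_acc"}
        assert len(hist["train_loss"]) == len(hist["val_loss"]) == 2

    def test_deterministic_given_seed(self):
        X, y = toy_problem(200, seed=8)
        cfgs = TrainConfig(epochs=2, learning_rate=1e-3, seed=8)
        m1 = build_model(TOY_SPEC, seed=8)
        train_model(m1, X, y, cfgs)
        m2 = build_model(TOY_SPEC, seed=8)
        train_model(m2, X, y, cfgs)
        assert np.array_equal(predict(m1, X[:16]), predict(m2, X[:16]))


class TestInference:
    def test_batching_does_not_change_scores(self):
        model = build_model(TOY_SPEC, seed=9)
        X, _ = toy_problem(33, seed=9)
        single = np.array([predict(model, X[i : i + 1])[0] for i in range(33)])
        batched = predict(model, X, batch_size=32)
        assert np.allclose(single, batched, atol=1e-6)

    def test_duplicated_encoding_scores_identical(self):
        model = build_model(TOY_SPEC, seed=10)
        X, _ = toy_problem(4, seed=10)
        Xdup = np.concatenate([X, X])
        p = predict(model, Xdup)
        assert np.array_equal(p[:4], p[4:])

    def test_save_load_round_trip(self, tmp_path):
        X, y = toy_problem(200, seed=11)
        model = build_model(TOY_SPEC, seed=11)
        train_model(model, X, y, TrainConfig(epochs=2, seed=11))
        before = predict(model, X[:20])
        path = str(tmp_path / "toy.ckpt")
        save_model(model, path)
        restored = load_model(path)
        assert np.array_equal(before, predict(restored, X[:20]))

    def test_gradient_flows_to_input(self):
        X, y = toy_problem(200, seed=12)
        model = build_model(TOY_SPEC, seed=12)
        train_model(model, X, y, TrainConfig(epochs=2, learning_rate=1e-3, seed=12))
        model.forward(X[:1], train=False)
        dx = model.backward(np.ones(1, dtype=np.float32))
        assert np.abs(dx).max() > 0

    def test_trained_snv_model_scores_spiked_site_high(self, toy_snv_model, sim_small):
        from somaticnet.encoder import encode_site
        from somaticnet.sites import VariantClass

        model = toy_snv_model["model"]
        high = [
            v for v in sim_small["truth"].somatic
            if v.site.variant_class == VariantClass.SNV and v.designed_vaf >= 0.4
        ]
        enc = encode_site(high[0].site, sim_small["tumor"], sim_small["normal"],
                          sim_small["reference"])
        assert predict(model, [enc])[0] > 0.9
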