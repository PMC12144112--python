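import numpy as np
import pytest

from qdosim import (
    Adam,
    ArchitectureSpec,
    LayerSpec,
    LossConfig,
    SGD,
    TrainingConfig,
    build_network,
    composite_loss,
    mc_dropout_uncertainty,
    predict_dose,
    reference_architecture,
    train,
)

PRINTED_COUNTS = [0, 1728, 256, 0, 221184, 512, 73728, 256, 0, 32768, 27648, 128, 289]


class TestArchitecture:
    def test_default_architecture_reproduces_printed_counts(self):
        _model, counts = build_network(reference_architecture(input_shape=(16, 16, 16, 1)))
        assert counts == PRINTED_COUNTS

    def test_counts_independent_of_spatial_size(self):
        a = reference_architecture(input_shape=(64, 64, 64, 1)).parameter_counts()
        b = reference_architecture(input_shape=(16, 16, 16, 1)).parameter_counts()
        assert a == b

    def test_first_conv_and_batchnorm_counts(self):
        counts = reference_architecture().parameter_counts()
        assert counts[1] == 1728       # 1 -> 64 channels, 3x3x3, no bias
        assert counts[2] == 256        # batch norm: 4 x 64
        assert counts[3] == 0          # pooling is parameter-free

    def test_model_parameter_total_matches_closed_form(self):
        model, counts = build_network(reference_architecture(input_shape=(8, 8, 8, 1)))
        assert model.parameter_count() == sum(counts)

    def test_shape_chaining_error_names_layers(self):
        spec = reference_architecture(input_shape=(15, 15, 15, 1))  # odd: pool fails
        with pytest.raises(ValueError, match="maxpool"):
            build_network(spec)

    def test_unknown_layer_kind_rejected(self):
        spec = ArchitectureSpec(layers=[LayerSpec("input"), LayerSpec("attention")],
                                input_shape=(8, 8, 8, 1))
        with pytest.raises(ValueError, match="attention"):
            spec.parameter_counts()


class TestCompositeLoss:
    def test_perfect_prediction_zero_loss(self):
        x = np.random.default_rng(0).random((2, 4, 4, 4))
        total, comps = composite_loss(x, x, [], LossConfig(lam=0.0))
        assert total == 0.0
        assert comps["mse"] == 0.0 and comps["mae"] == 0.0

    def test_hand_computed_example(self):
        total, comps = composite_loss(np.array([1.0, 2.0]), np.array([0.0, 2.0]),
                                      [], LossConfig(lam=0.0))
        assert comps["mse"] == pytest.approx(0.5)
        assert comps["mae"] == pytest.approx(0.5)
        assert total == pytest.approx(1.0)

    def test_linear_in_lambda(self):
        theta = [np.array([1.0, 2.0])]
        pred, true = np.array([1.0]), np.array([0.0])
        t1, _ = composite_loss(pred, true, theta, LossConfig(lam=0.1))
        t2, _ = composite_loss(pred, true, theta, LossConfig(lam=0.2))
        assert t2 - t1 == pytest.approx(0.1 * 5.0)  # lambda * R, R = 1+4

    def test_components_nonnegative_and_monotone_in_lambda(self):
        rng = np.random.default_rng(1)
        pred, true = rng.random(10), rng.random(10)
        theta = [rng.random(5)]
        totals = [composite_loss(pred, true, theta, LossConfig(lam=l))[0]
                  for l in (0.0, 0.01, 0.1)]
        assert totals == sorted(totals)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            composite_loss(np.zeros(3), np.zeros(4))


class TestOptimizers:
    def test_plain_gradient_step_quadratic(self):
        # C(theta) = theta^2, theta0 = 1, eta = 0.1: theta1 = 1 - 0.1*2 = 0.8
        theta = np.array([1.0])
        SGD(lr=0.1).step([theta], [2.0 * theta])
        assert theta[0] == pytest.approx(0.8, abs=1e-12)

    def test_momentum_accumulates(self):
        theta = np.array([1.0])
        opt = SGD(lr=0.1, momentum=0.9)
        opt.step([theta], [np.array([1.0])])
        assert theta[0] == pytest.approx(0.9)
        opt.step([theta], [np.array([1.0])])
        assert theta[0] == pytest.approx(0.9 - 0.1 * 1.9)

    def test_adam_first_step_magnitude(self):
        theta = np.array([1.0])
        Adam(lr=0.001).step([theta], [np.array([5.0])])
        assert theta[0] == pytest.approx(1.0 - 0.001, rel=1e-6)


class TestTraining:
    def test_loss_halves_on_slab_dataset(self, slab_dose_dataset):
        model, _ = build_network(reference_architecture(input_shape=(16, 16, 16, 1)),
                                 seed=1, dropout_rate=0.3)
        cfg = TrainingConfig(learning_rate=0.03, batch_size=4, epochs=10,
                             validation_split=0.2, optimizer="adam",
                             dropout_rate=0.3, seed=2)
        model = train(model, slab_dose_dataset, cfg, LossConfig())
        assert len(model.history) == 10
        assert model.history[-1]["train_loss"] < 0.5 * model.history[0]["train_loss"]
        assert np.isfinite(model.history[-1]["val_loss"])

    def test_seed_reproducibility_bitwise(self, slab_dose_dataset):
        def run():
            model, _ = build_network(reference_architecture(input_shape=(16, 16, 16, 1)),
                                     seed=3, dropout_rate=0.0)
            cfg = TrainingConfig(learning_rate=0.01, batch_size=2, epochs=2,
                                 validation_split=0.25, optimizer="sgd_momentum",
                                 dropout_rate=0.0, seed=5)
            return train(model, slab_dose_dataset[:4], cfg, LossConfig())

        a, b = run(), run()
        for pa, pb in zip(a.theta, b.theta):
            assert np.array_equal(pa, pb)
        assert a.history == b.history

    def test_empty_dataset_rejected(self):
        model, _ = build_network(reference_architecture(input_shape=(8, 8, 8, 1)))
        with pytest.raises(ValueError):
            train(model, [], TrainingConfig())

    def test_defaults_match_published_configuration(self):
        cfg = TrainingConfig()
        assert cfg.learning_rate == 0.001
        assert cfg.batch_size == 32
        assert cfg.epochs == 100
        assert cfg.validation_split == 0.2
        assert cfg.dropout_rate == 0.3
        assert cfg.momentum == 0.9
        assert LossConfig().lam == 1e-4


class TestPrediction:
    def test_untrained_model_predicts_zero(self):
        model, _ = build_network(reference_architecture(input_shape=(8, 8, 8, 1)), seed=0)
        dose = predict_dose(model, np.ones((8, 8, 8)))
        assert np.all(dose.dose == 0.0)

    def test_output_shape_matches_input(self):
        model, _ = build_network(reference_architecture(input_shape=(8, 8, 8, 1)), seed=0)
        for n in (8, 16):
            dose = predict_dose(model, np.ones((n, n, n)))
            assert dose.dose.shape == (n, n, n)

    def test_deterministic_inference(self, slab_dose_dataset):
        model, _ = build_network(reference_architecture(input_shape=(16, 16, 16, 1)), seed=4)
        feat = slab_dose_dataset[0][0]
        a = predict_dose(model, feat)
        b = predict_dose(model, feat)
        assert np.array_equal(a.dose, b.dose)

    def test_nonnegative_output(self, slab_dose_dataset):
        model, _ = build_network(reference_architecture(input_shape=(16, 16, 16, 1)), seed=4)
        cfg = TrainingConfig(learning_rate=0.05, batch_size=4, epochs=1,
                             validation_split=0.2, dropout_rate=0.0, seed=0)
        model = train(model, slab_dose_dataset[:8], cfg)
        dose = predict_dose(model, slab_dose_dataset[0][0])
        assert np.all(dose.dose >= 0)

    def test_feature_dimension_validated(self):
        model, _ = build_network(reference_architecture(input_shape=(8, 8, 8, 1)))
        with pytest.raises(ValueError):
            predict_dose(model, np.ones((8, 8)))


@pytest.fixture(scope="module")
def trained_small(slab_dose_dataset):
    model, _ = build_network(reference_architecture(input_shape=(16, 16, 16, 1)),
                             seed=6, dropout_rate=0.3)
    cfg = TrainingConfig(learning_rate=0.03, batch_size=4, epochs=2,
                         validation_split=0.2, dropout_rate=0.3, seed=6)
    return train(model, slab_dose_dataset[:8], cfg)


class TestMCDropout:
    def test_zero_rate_gives_zero_spread(self, slab_dose_dataset):
        model, _ = build_network(reference_architecture(input_shape=(16, 16, 16, 1)),
                                 seed=6, dropout_rate=0.0)
        out = mc_dropout_uncertainty(model, slab_dose_dataset[0][0], n_passes=5, seed=1)
        assert np.all(out["sd"] == 0.0)
        assert np.all(out["interval_high"] - out["interval_low"] == 0.0)

    def test_positive_spread_with_dropout(self, trained_small, slab_dose_dataset):
        out = mc_dropout_uncertainty(trained_small, slab_dose_dataset[0][0],
                                     n_passes=50, seed=2)
        assert np.any(out["sd"] > 0)

    def test_interval_contains_median_of_passes(self, trained_small, slab_dose_dataset):
        x = slab_dose_dataset[0][0]
        # replay the same dropout stream the estimator uses
        rng = np.random.default_rng(3)
        passes = np.stack([
            np.clip(trained_small.forward(x[None, None], train=False,
                                          dropout_rng=rng)[0, 0], 0, None)
            for _ in range(20)
        ])
        out = mc_dropout_uncertainty(trained_small, x, n_passes=20, seed=3)
        med = np.median(passes, axis=0)
        assert np.all(out["interval_low"] <= med + 1e-12)
        assert np.all(med <= out["interval_high"] + 1e-12)

    def test_too_few_passes_rejected(self, trained_small, slab_dose_dataset):
        with pytest.raises(ValueError):
            mc_dropout_uncertainty(trained_small, slab_dose_dataset[0][0], n_passes=1)

    def test_model_without_dropout_rejected(self, slab_dose_dataset):
        spec = reference_architecture(input_shape=(16, 16, 16, 1), with_dropout=False)
        model, _ = build_network(spec)
        with pytest.raises(ValueError, match="dropout"):
            mc_dropout_uncertainty(model, slab_dose_dataset[0][0], n_passes=5)
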