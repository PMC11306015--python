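"""Model objects: architecture contracts, training mechanics, determinism."""

import numpy as np
import pytest

from phenoyield.errors import ConfigurationError, SchemaError
from phenoyield.models import (
    AttentionLSTMModel,
    ModalityTensor,
    ModelConfig,
    MultimodalFusionModel,
    VanillaLSTMModel,
    lstm_parameter_count,
    merge_early_fusion,
)

N_PLOTS, N_DATES = 24, 5


@pytest.fixture(scope="module")
def toy_data():
    rng = np.random.default_rng(0)
    dates = np.arange(N_DATES) * 100 + 500
    tensors = {
        "hyperspectral": ModalityTensor(
            rng.normal(size=(N_PLOTS, N_DATES, 4)), dates,
            ("a", "b", "c", "d"), "hyperspectral",
        ),
        "lidar": ModalityTensor(
            rng.normal(size=(N_PLOTS, N_DATES, 3)), dates, ("h1", "h2", "h3"), "lidar"
        ),
        "weather": ModalityTensor(
            np.cumsum(rng.random(size=(N_PLOTS, N_DATES, 2)), axis=1), dates,
            ("gdd", "rad"), "weather",
        ),
    }
    y = 100 + 5 * tensors["lidar"].values[:, 1, 0] + rng.normal(0, 0.5, N_PLOTS)
    return y, tensors


TINY = dict(units_per_layer=8, attention_dim=4, context_dim=4, fusion_hidden=4,
            max_epochs=8, patience=8, batch_size=8)

TRAIN, VAL = np.arange(16), np.arange(16, 20)
TEST = np.arange(20, 24)


def fit_model(cls, y, tensors, **overrides):
    cfg = ModelConfig(**{**TINY, **overrides})
    model = cls(y, tensors, cfg)
    return model, model.fit(TRAIN, VAL)


class TestArchitectureContracts:
    def test_parameter_count_matches_closed_form(self, toy_data):
        y, tensors = toy_data
        model, _ = fit_model(VanillaLSTMModel, y, tensors)
        n_feat = 4 + 3 + 2
        expected = lstm_parameter_count(n_feat, 8, 2) + (8 * 1 + 1)
        assert model.n_parameters() == expected

    def test_forward_pass_finite_predictions(self, toy_data):
        y, tensors = toy_data
        _, res = fit_model(VanillaLSTMModel, y, tensors)
        pred = res.predict(plot_idx=TEST)
        assert pred.shape == (4,) and np.isfinite(pred).all()

    def test_same_seed_builds_identical_models(self, toy_data):
        y, tensors = toy_data
        _, res_a = fit_model(AttentionLSTMModel, y, tensors, seed=11)
        _, res_b = fit_model(AttentionLSTMModel, y, tensors, seed=11)
        np.testing.assert_array_equal(res_a.predict(), res_b.predict())
        assert res_a.best_val_loss == res_b.best_val_loss

    def test_sigmoid_head_keeps_predictions_in_training_range(self, toy_data):
        y, tensors = toy_data
        _, res = fit_model(MultimodalFusionModel, y, tensors)
        pred = res.predict()
        assert pred.min() >= y[TRAIN].min() - 1e-9
        assert pred.max() <= y[TRAIN].max() + 1e-9

    def test_missing_modality_rejected(self, toy_data):
        y, tensors = toy_data
        with pytest.raises(ConfigurationError):
            MultimodalFusionModel(y, {"lidar": tensors["lidar"]}, ModelConfig(**TINY))

    def test_vanilla_exposes_no_attention(self, toy_data):
        y, tensors = toy_data
        _, res = fit_model(VanillaLSTMModel, y, tensors)
        with pytest.raises(ConfigurationError):
            res.attention()


class TestAttentionWeights:
    def test_weights_sum_to_one_per_plot(self, toy_data):
        y, tensors = toy_data
        _, res = fit_model(AttentionLSTMModel, y, tensors)
        w = res.attention().weights
        assert np.all(w >= 0)
        np.testing.assert_allclose(w.reshape(N_PLOTS, -1).sum(axis=1), 1.0, atol=1e-6)

    def test_gate_zeroes_weights_outside_support(self, toy_data):
        y, tensors = toy_data
        dates = tensors["lidar"].dates
        _, res = fit_model(
            AttentionLSTMModel, y, tensors, gate_dates=(dates[2], dates[3])
        )
        w = res.attention().weights
        assert np.all(w[:, [0, 1, 4], :] == 0.0)
        np.testing.assert_allclose(w.reshape(N_PLOTS, -1).sum(axis=1), 1.0, atol=1e-6)

    def test_gate_dates_must_exist(self, toy_data):
        y, tensors = toy_data
        model = AttentionLSTMModel(y, tensors, ModelConfig(**TINY, gate_dates=(123,)))
        with pytest.raises(ConfigurationError):
            model.fit(TRAIN, VAL)

    def test_constant_sequence_gives_near_uniform_initial_weights(self):
        rng = np.random.default_rng(5)
        frame = rng.normal(size=(10, 1, 4))
        const = np.repeat(frame, 6, axis=1)  # all dates identical
        tensors = {
            "hyperspectral": ModalityTensor(
                const, np.arange(6), ("a", "b", "c", "d"), "hyperspectral"
            )
        }
        y = rng.normal(100, 5, size=10)
        cfg = ModelConfig(**{**TINY, "max_epochs": 1, "learning_rate": 0.0})
        model = AttentionLSTMModel(y, tensors, cfg)
        res = model.fit(np.arange(8), np.arange(8, 10))
        prof = res.attention().weights.sum(axis=2).mean(axis=0)
        assert prof.max() - prof.min() < 0.05

    def test_multimodal_branch_maps_each_normalized(self, toy_data):
        y, tensors = toy_data
        _, res = fit_model(MultimodalFusionModel, y, tensors)
        maps = res.attention()
        assert set(maps) == {"hyperspectral", "lidar"}
        for m, att in maps.items():
            np.testing.assert_allclose(
                att.weights.reshape(N_PLOTS, -1).sum(axis=1), 1.0, atol=1e-6
            )

    def test_attention_identical_across_repeated_inference(self, toy_data):
        y, tensors = toy_data
        _, res = fit_model(AttentionLSTMModel, y, tensors)
        np.testing.assert_array_equal(res.attention().weights, res.attention().weights)


class TestTrainingMechanics:
    def test_zero_learning_rate_leaves_parameters_at_initialization(self, toy_data):
        y, tensors = toy_data
        cfg = ModelConfig(**{**TINY, "learning_rate": 0.0, "restore_best": False})
        model = VanillaLSTMModel(y, tensors, cfg)
        model._build(np.random.default_rng(cfg.seed))
        before = [p.data.copy() for p in model._params]
        model.fit(TRAIN, VAL)
        model_b = VanillaLSTMModel(y, tensors, cfg)
        model_b.fit(TRAIN, VAL)
        for p0, p1 in zip(before, model_b._params):
            np.testing.assert_array_equal(p0, p1.data)

    def test_zero_blend_weight_freezes_aux_heads(self, toy_data):
        y, tensors = toy_data
        cfg = ModelConfig(**{**TINY, "blend_weights": (1.0, 0.0, 0.0)})
        model = MultimodalFusionModel(y, tensors, cfg)
        model._build(np.random.default_rng(cfg.seed))
        aux_before = {
            m: [p.data.copy() for p in model.branches[m]["aux"].parameters()]
            for m in model.branches
        }
        model.fit(TRAIN, VAL)
        cfg2 = ModelConfig(**{**TINY, "blend_weights": (1.0, 0.0, 0.0),
                              "restore_best": False})
        model2 = MultimodalFusionModel(y, tensors, cfg2)
        model2.fit(TRAIN, VAL)
        for m in model2.branches:
            for p_before, p_after in zip(
                aux_before[m], model2.branches[m]["aux"].parameters()
            ):
                np.testing.assert_array_equal(p_before, p_after.data)

    def test_empty_validation_split_rejected(self, toy_data):
        y, tensors = toy_data
        model = VanillaLSTMModel(y, tensors, ModelConfig(**TINY))
        with pytest.raises(ConfigurationError):
            model.fit(TRAIN, np.array([], dtype=int))

    def test_history_records_train_and_val_losses(self, toy_data):
        y, tensors = toy_data
        _, res = fit_model(MultimodalFusionModel, y, tensors)
        h = res.history
        for col in ("train_loss", "val_loss", "train_fusion_loss", "val_lidar_loss"):
            assert col in h.columns and np.isfinite(h[col]).all()

    def test_training_reduces_loss_on_learnable_signal(self, toy_data):
        y, tensors = toy_data
        _, res = fit_model(
            VanillaLSTMModel, y, tensors, max_epochs=60, patience=60, dropout=0.0
        )
        h = res.history["train_loss"]
        assert h.iloc[-1] < h.iloc[0] * 0.5

    def test_predict_requires_matching_feature_schema(self, toy_data):
        y, tensors = toy_data
        _, res = fit_model(VanillaLSTMModel, y, tensors)
        renamed = dict(tensors)
        t = tensors["lidar"]
        renamed["lidar"] = ModalityTensor(
            t.values, t.dates, ("x1", "x2", "x3"), "lidar"
        )
        with pytest.raises(SchemaError):
            res.predict(tensors=renamed)

    def test_summary_mentions_architecture_and_parameters(self, toy_data):
        y, tensors = toy_data
        model, res = fit_model(AttentionLSTMModel, y, tensors)
        text = res.summary()
        assert "attention" in text
        assert str(model.n_parameters()) in text


class TestEarlyFusionMerge:
    def test_shared_dates_concatenate_features(self, toy_data):
        _, tensors = toy_data
        merged = merge_early_fusion(tensors)
        assert merged.values.shape == (N_PLOTS, N_DATES, 9)
        assert len(merged.feature_names) == 9

    def test_disjoint_dates_zero_fill_on_union_axis(self, toy_data):
        _, tensors = toy_data
        lidar = tensors["lidar"].subset_dates([0, 1])
        hyper = tensors["hyperspectral"].subset_dates([2, 3])
        merged = merge_early_fusion({"lidar": lidar, "hyperspectral": hyper})
        assert merged.values.shape[1] == 4
        # hyperspectral block is zero at lidar-only dates and vice versa
        assert np.all(merged.values[:, 0, :4] == 0.0)
        assert np.all(merged.values[:, 3, 4:] == 0.0)


class TestCheckpointing:
    def test_save_and_load_round_trip(self, toy_data, tmp_path):
        from phenoyield.models import load_results

        y, tensors = toy_data
        _, res = fit_model(AttentionLSTMModel, y, tensors, seed=2)
        res.save(tmp_path / "ckpt")
        restored = load_results(tmp_path / "ckpt", y, tensors)
        np.testing.assert_array_equal(res.predict(), restored.predict())
        np.testing.assert_array_equal(
            res.attention().weights, restored.attention().weights
        )


def test_final_state_query_variant_trains_and_normalizes(toy_data):
    y, tensors = toy_data
    _, res = fit_model(AttentionLSTMModel, y, tensors, query="final_state")
    w = res.attention().weights
    np.testing.assert_allclose(w.reshape(N_PLOTS, -1).sum(axis=1), 1.0, atol=1e-6)
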