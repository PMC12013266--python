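"""Attention primitive, losses and regressor contracts."""

import math

import numpy as np
import pytest

from promodiff.fixtures import FixtureSpec, generate_fixture
from promodiff.predictor import (
    PredictorConfig,
    TrainedPredictor,
    combined_loss,
    evaluate_predictor,
    pcc,
    predict_strength,
    self_attention,
    train_cnn_baseline,
    train_predictor,
)
from promodiff.sequence_codec import (
    ConfigurationError,
    NormalizationParams,
    ValidationError,
    log_transform,
    minmax_normalize,
    split_dataset,
)


class TestSelfAttention:
    def test_single_position_returns_value_row(self):
        Q = np.array([[1.0, 2.0]])
        K = np.array([[0.3, -1.0]])
        V = np.array([[5.0, 7.0, -2.0]])
        np.testing.assert_allclose(self_attention(Q, K, V), V)

    def test_zero_query_gives_uniform_mixture(self):
        rng = np.random.default_rng(0)
        K = rng.normal(size=(6, 4))
        V = rng.normal(size=(6, 3))
        out, w = self_attention(np.zeros((6, 4)), K, V, return_weights=True)
        np.testing.assert_allclose(w, np.full((6, 6), 1 / 6), atol=1e-6)
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (6, 1)), atol=1e-5)

    def test_two_by_two_against_direct_formula(self):
        Q = np.array([[1.0, 0.0], [0.0, 2.0]])
        K = np.array([[1.0, 1.0], [0.0, 1.0]])
        V = np.array([[1.0, 2.0], [3.0, 4.0]])
        scores = Q @ K.T / math.sqrt(2)
        weights = np.exp(scores)
        weights /= weights.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(self_attention(Q, K, V), weights @ V, atol=1e-6)

    def test_weight_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        Q = rng.normal(size=(2, 5, 8))
        K = rng.normal(size=(2, 5, 8))
        V = rng.normal(size=(2, 5, 8))
        _, w = self_attention(Q, K, V, return_weights=True)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)

    def test_mask_excludes_positions(self):
        rng = np.random.default_rng(2)
        Q = rng.normal(size=(3, 4))
        K = rng.normal(size=(3, 4))
        V = rng.normal(size=(3, 2))
        mask = np.eye(3, dtype=bool)
        out, w = self_attention(Q, K, V, mask=mask, return_weights=True)
        np.testing.assert_allclose(w, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(out, V, atol=1e-5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            self_attention(np.zeros((3, 4)), np.zeros((3, 5)), np.zeros((3, 2)))


class TestCombinedLoss:
    def test_zero_iff_equal(self):
        y = np.array([0.1, 0.4, 0.8])
        assert combined_loss(y, y) == pytest.approx(0.0, abs=1e-12)

    def test_pcc_term_is_shift_invariant(self):
        y = np.array([0.1, 0.4, 0.8])
        assert combined_loss(y + 0.3, y, w_mse=0.0, w_pcc=1.0) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_anticorrelated_gives_two(self):
        y = np.array([-1.0, 0.0, 1.0])
        assert combined_loss(-y, y, w_mse=0.0, w_pcc=1.0) == pytest.approx(2.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        pred = rng.normal(size=20)
        target = rng.normal(size=20)
        perm = rng.permutation(20)
        assert combined_loss(pred, target) == pytest.approx(
            combined_loss(pred[perm], target[perm])
        )

    def test_constant_prediction_falls_back_to_mse(self, caplog):
        pred = np.array([0.5, 0.5, 0.5])
        target = np.array([0.0, 0.5, 1.0])
        with caplog.at_level("WARNING"):
            value = combined_loss(pred, target)
        assert value == pytest.approx(np.mean((pred - target) ** 2))
        assert "constant predictions" in caplog.text

    def test_invalid_weights(self):
        with pytest.raises(ConfigurationError):
            combined_loss([1, 2], [1, 2], w_mse=0.0, w_pcc=0.0)


def _fast_config(**kw):
    defaults = dict(epochs=2, d_model=16, heads=2, layers=1, ff_width=32, seed=0)
    defaults.update(kw)
    return PredictorConfig(**defaults)


@pytest.fixture(scope="module")
def tiny_split():
    ds = generate_fixture(FixtureSpec(count=150, seed=8))
    return split_dataset(ds, 0.2, seed=0)


class TestTrainingContracts:
    def test_same_seed_same_predictions(self, tiny_split):
        train, test = tiny_split
        m1 = train_predictor(train, _fast_config())
        m2 = train_predictor(train, _fast_config())
        np.testing.assert_array_equal(
            m1.predict(test.sequences), m2.predict(test.sequences)
        )

    def test_duplicates_and_permutations(self, tiny_split):
        train, test = tiny_split
        model = train_predictor(train, _fast_config())
        seqs = test.sequences[:6]
        preds = model.predict(seqs + seqs)
        np.testing.assert_allclose(preds[:6], preds[6:])
        perm = [3, 0, 5, 1, 4, 2]
        np.testing.assert_allclose(
            model.predict([seqs[i] for i in perm]), preds[perm]
        )

    def test_raw_scale_round_trips_through_normalization(self, tiny_split):
        train, test = tiny_split
        model = train_predictor(train, _fast_config())
        norm = model.predict(test.sequences)
        raw = model.predict(test.sequences, scale="raw")
        back, _ = minmax_normalize(log_transform(raw), model.norm_params)
        np.testing.assert_allclose(back, norm, atol=1e-4)

    def test_length_mismatch_rejected(self, tiny_split):
        train, _ = tiny_split
        model = train_predictor(train, _fast_config())
        with pytest.raises(ValidationError):
            predict_strength(model, ["ATCG"])

    def test_missing_strengths_rejected(self, tiny_split):
        _, test = tiny_split
        from promodiff.sequence_codec import PromoterDataset, PromoterRecord

        unlabelled = PromoterDataset([PromoterRecord("x", "A" * 50)])
        with pytest.raises(ValidationError):
            train_predictor(unlabelled, _fast_config())

    def test_cnn_same_seed_determinism(self, tiny_split):
        train, test = tiny_split
        m1 = train_cnn_baseline(train, _fast_config())
        m2 = train_cnn_baseline(train, _fast_config())
        np.testing.assert_array_equal(
            m1.predict(test.sequences), m2.predict(test.sequences)
        )

    def test_save_load_round_trip(self, tiny_split, tmp_path):
        train, test = tiny_split
        model = train_predictor(train, _fast_config())
        path = tmp_path / "model.json"
        model.save(path)
        loaded = TrainedPredictor.load(path)
        np.testing.assert_allclose(
            loaded.predict(test.sequences), model.predict(test.sequences), atol=1e-6
        )


class TestEvaluation:
    def test_oracle_model_scores_one(self, tiny_split):
        train, test = tiny_split
        model = train_predictor(train, _fast_config())

        class _Truth:
            def __init__(self, params):
                self.params = params

            def predict(self, seqs, scale="normalized"):
                lookup = {r.sequence: r.strength for r in test}
                vals = log_transform([lookup[s] for s in seqs])
                return (vals - self.params.log_min) / (
                    self.params.log_max - self.params.log_min
                )

        oracle = TrainedPredictor(
            model.model, "transformer", 50, model.norm_params, model.config
        )
        oracle.predict = _Truth(model.norm_params).predict
        assert evaluate_predictor(oracle, test) == pytest.approx(1.0)

    def test_constant_model_surfaces_degenerate_error(self, tiny_split):
        train, test = tiny_split
        model = train_predictor(train, _fast_config())
        model.predict = lambda seqs, scale="normalized": np.zeros(len(seqs))
        with pytest.raises(ValidationError):
            evaluate_predictor(model, test)

    def test_too_small_test_set_rejected(self, tiny_split):
        train, test = tiny_split
        from promodiff.sequence_codec import PromoterDataset

        model = train_predictor(train, _fast_config())
        with pytest.raises(ValidationError):
            evaluate_predictor(model, PromoterDataset(test.records[:1]))
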