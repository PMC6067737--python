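"""Classifier construction, training contracts, grey-area rule, pretraining."""

import numpy as np
import pytest

from wholemir.dataset import encode_examples, generate_synthetic_dataset
from wholemir.errors import ValidationError
from wholemir.network import (
    NetworkSpec,
    SiteClassifier,
    build_model,
    classify_output,
    predict_site,
    pretrain_autoencoder,
    train_classifier,
    _loss_value,
)


@pytest.fixture(scope="module")
def tiny_data():
    mirnas, _, _, examples = generate_synthetic_dataset(240, seed=31)
    X, y = encode_examples(examples, mirnas)
    return X[:160], y[:160], X[160:], y[160:]


class TestBuildModel:
    def test_default_shape(self):
        model = build_model(NetworkSpec(seed=0))
        assert len(model.W) == 9  # 8 hidden + softmax output
        assert model.W[0].shape == (280, 400)
        assert model.W[-1].shape == (10, 2)

    def test_over_completion_enforced(self):
        with pytest.raises(ValidationError, match="over-complete"):
            build_model(NetworkSpec(hidden_sizes=(280, 100, 40, 40, 20, 10, 8, 4)))

    def test_same_seed_bit_identical_weights(self):
        a, b = build_model(NetworkSpec(seed=5)), build_model(NetworkSpec(seed=5))
        assert all(np.array_equal(w1, w2) for w1, w2 in zip(a.W, b.W))

    def test_different_seed_differs(self):
        a, b = build_model(NetworkSpec(seed=5)), build_model(NetworkSpec(seed=6))
        assert not np.array_equal(a.W[0], b.W[0])

    @pytest.mark.parametrize("bad", [dict(dropout=1.0), dict(loss="HINGE"), dict(max_epochs=0)])
    def test_spec_validation(self, bad):
        with pytest.raises(ValidationError):
            build_model(NetworkSpec(**bad))


class TestClassifyOutput:
    @pytest.mark.parametrize(
        "o0,o1,K,expected",
        [
            (0.3, 0.7, 0.0, 1),
            (0.3, 0.7, 0.5, 0),       # inside the grey area
            (0.5, 0.5, 0.0, -1),      # tie classifies negative
            (0.7, 0.3, 0.0, -1),
            (0.2, 0.8, 0.6, 1),       # boundary score == K is positive
            (0.8, 0.2, 0.6, -1),
        ],
    )
    def test_rule(self, o0, o1, K, expected):
        assert classify_output(o0, o1, K) == expected

    def test_negative_margin_rejected(self):
        with pytest.raises(ValidationError):
            classify_output(0.5, 0.5, -0.1)

    def test_non_complementary_probabilities_rejected(self):
        with pytest.raises(ValidationError):
            classify_output(0.5, 0.6, 0.0)

    def test_grey_area_with_zero_margin_reduces_to_sign_rule(self):
        # pointwise identity of the two decision rules over a probability grid
        for o1 in np.linspace(0.0, 1.0, 101):
            o0 = 1.0 - o1
            sign_rule = 1 if (o1 - o0) > 0 else -1
            assert classify_output(o0, o1, 0.0) == sign_rule


class TestTraining:
    def test_deterministic_history(self, tiny_data):
        Xtr, ytr, Xva, yva = tiny_data
        spec = NetworkSpec(seed=3, max_epochs=4)
        h1 = train_classifier(build_model(spec), Xtr, ytr, Xva, yva, spec)
        h2 = train_classifier(build_model(spec), Xtr, ytr, Xva, yva, spec)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["valid_loss"] == h2["valid_loss"]

    def test_single_class_rejected(self, tiny_data):
        Xtr, ytr, Xva, yva = tiny_data
        spec = NetworkSpec(seed=3, max_epochs=2)
        with pytest.raises(ValidationError, match="both classes"):
            train_classifier(build_model(spec), Xtr, np.ones(len(Xtr), dtype=int), Xva, yva, spec)

    def test_best_epoch_weights_kept(self, tiny_data):
        Xtr, ytr, Xva, yva = tiny_data
        spec = NetworkSpec(seed=3, max_epochs=6)
        model = build_model(spec)
        history = train_classifier(model, Xtr, ytr, Xva, yva, spec)
        best = history["best_valid_loss"]
        assert best == min(history["valid_loss"])
        probs = model.predict_proba(Xva)
        refit = _loss_value(spec.loss, probs, (yva == 1).astype(int))
        assert refit == pytest.approx(best, abs=1e-9)

    def test_xent_and_nll_losses_coincide_on_one_hot_targets(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet((1, 1), size=50)
        targets = rng.integers(0, 2, size=50)
        assert _loss_value("XENT", probs, targets) == pytest.approx(
            _loss_value("NLL", probs, targets)
        )


class TestPrediction:
    def test_softmax_outputs_complementary(self, trained_model, tiny_data):
        X = tiny_data[0]
        out = predict_site(trained_model, X[0].astype(float))
        assert out.o0 + out.o1 == pytest.approx(1.0, abs=1e-6)
        assert -1.0 <= out.score <= 1.0

    def test_same_input_same_output(self, trained_model, tiny_data):
        X = tiny_data[0]
        a = predict_site(trained_model, X[3].astype(float))
        b = predict_site(trained_model, X[3].astype(float))
        assert (a.o0, a.o1, a.cls) == (b.o0, b.o1, b.cls)

    def test_untrained_model_refuses(self):
        model = build_model(NetworkSpec(seed=0))
        with pytest.raises(ValidationError, match="trained"):
            predict_site(model, np.zeros(280))

    def test_seed_bits_matter_for_positive_scores(self, trained_model, tiny_data):
        """Zeroing the extended-seed site region shifts scores down in bulk."""
        Xva, yva = tiny_data[2], tiny_data[3]
        pos = Xva[yva == 1].astype(float)
        probs = trained_model.predict_proba(pos)
        ablated = pos.copy()
        # the planted seed complement occupies the 3' end of the site frame:
        # site slots 25..34 -> bits 120 + 4*30 .. 120 + 4*40
        ablated[:, 120 + 100:120 + 160] = 0.0
        probs_ab = trained_model.predict_proba(ablated)
        assert (probs_ab[:, 1] - probs_ab[:, 0]).mean() < (probs[:, 1] - probs[:, 0]).mean()


class TestPersistence:
    def test_save_load_round_trip(self, trained_model, tiny_data, tmp_path):
        path = tmp_path / "model.npz"
        trained_model.save(path)
        back = SiteClassifier.load(path)
        X = tiny_data[0][:8].astype(float)
        assert np.allclose(trained_model.predict_proba(X), back.predict_proba(X))

    def test_encoding_version_mismatch_refused(self, trained_model, tmp_path):
        import json

        path = tmp_path / "model.npz"
        trained_model.save(path)
        meta_path = tmp_path / "model.npz.meta.json"
        meta = json.loads(meta_path.read_text())
        meta["encoding_version"] = "one-hot/v0"
        meta_path.write_text(json.dumps(meta))
        with pytest.raises(ValidationError, match="refusing"):
            SiteClassifier.load(path)


class TestPretraining:
    def test_constant_zero_inputs_reconstruct_trivially(self):
        spec = NetworkSpec(seed=2)
        model = build_model(spec)
        X = np.zeros((40, 280))
        history = pretrain_autoencoder(model, X, max_epochs=3)
        assert history["holdout_error"][-1] == pytest.approx(0.0, abs=1e-9)
        assert history["converged"]

    def test_transfers_encoder_weights_into_classifier(self, tiny_data):
        spec = NetworkSpec(seed=2)
        model = build_model(spec)
        before = [w.copy() for w in model.W]
        with pytest.warns(UserWarning):
            pretrain_autoencoder(model, tiny_data[0], max_epochs=2)
        for i in range(spec.pretrain_depth):
            assert not np.array_equal(before[i], model.W[i])
        for i in range(spec.pretrain_depth, len(model.W)):
            assert np.array_equal(before[i], model.W[i])

    def test_error_trace_recorded_and_decreasing_overall(self, tiny_data):
        spec = NetworkSpec(seed=2)
        model = build_model(spec)
        with pytest.warns(UserWarning):
            history = pretrain_autoencoder(model, tiny_data[0], max_epochs=6)
        assert len(history["holdout_error"]) == 6
        assert history["holdout_error"][-1] < history["holdout_error"][0]
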