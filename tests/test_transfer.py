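"""Stage-1 classifier, focal loss and pseudo-label generation."""

import numpy as np
import pytest

from spatype import (
    DnnConfig,
    focal_loss,
    generate_pseudo_labels,
    predict_probabilities,
    train_dnn,
)
from spatype.transfer import ProbabilityTable
from spatype.datasets import ValidationError


def _softmax(z):
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


class TestFocalLoss:
    def test_reduces_to_cross_entropy_at_gamma_zero(self):
        rng = np.random.default_rng(0)
        probs = _softmax(rng.normal(size=(20, 5)))
        labels = rng.integers(0, 5, size=20)
        ce = -np.mean(np.log(probs[np.arange(20), labels]))
        assert abs(focal_loss(probs, labels, gamma=0.0, alpha=1.0) - ce) < 1e-9

    def test_zero_when_perfectly_confident(self):
        probs = np.eye(3)
        assert focal_loss(probs, np.arange(3), gamma=2.0) == pytest.approx(0.0, abs=1e-9)

    def test_hand_evaluated_single_sample(self):
        # p_t = 0.5, gamma = 2, alpha = 1 -> 0.25 * log 2
        probs = np.array([[0.5, 0.5]])
        val = focal_loss(probs, np.array([0]), gamma=2.0, alpha=1.0)
        assert val == pytest.approx(0.25 * np.log(2.0), abs=1e-12)

    def test_matches_per_sample_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            probs = _softmax(rng.normal(size=(30, 7)))
            labels = rng.integers(0, 7, size=30)
            gamma, alpha = rng.uniform(0, 4), rng.uniform(0.1, 2)
            expected = np.mean([
                -alpha * (1 - probs[i, labels[i]]) ** gamma * np.log(probs[i, labels[i]])
                for i in range(30)
            ])
            assert focal_loss(probs, labels, gamma, alpha) == pytest.approx(expected, abs=1e-9)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            focal_loss(np.array([[1.0]]), np.array([0]), gamma=-1.0)


class TestTrainDnn:
    def test_high_accuracy_on_separable_reference(self, separable_pair_normalized):
        refn, _ = separable_pair_normalized
        model = train_dnn(refn, DnnConfig(epochs=60, hidden=(128, 64, 32, 16), seed=0))
        table = predict_probabilities(model, refn)
        pred = np.array(table.types)[table.probs.argmax(axis=1)]
        acc = (pred == np.array(refn.labels)).mean()
        assert acc >= 0.95

    def test_zero_epochs_returns_initialization(self, separable_pair_normalized):
        refn, _ = separable_pair_normalized
        cfg = DnnConfig(epochs=0, hidden=(32, 16, 8, 8), seed=3)
        a = train_dnn(refn, cfg)
        b = train_dnn(refn, cfg)
        for pa, pb in zip(a.net.params(), b.net.params()):
            np.testing.assert_array_equal(pa, pb)
        assert a.loss_history == []

    def test_same_seed_identical_loss_trajectory(self, separable_pair_normalized):
        refn, _ = separable_pair_normalized
        cfg = DnnConfig(epochs=5, hidden=(32, 16, 8, 8), seed=7)
        a = train_dnn(refn, cfg)
        b = train_dnn(refn, cfg)
        assert a.loss_history == b.loss_history

    def test_single_class_rejected(self, separable_pair_normalized):
        refn, _ = separable_pair_normalized
        from dataclasses import replace

        solo = replace(refn, labels=["only"] * refn.n_cells, taxonomy=["only"])
        with pytest.raises(ValidationError, match="2 classes"):
            train_dnn(solo, DnnConfig(epochs=1))

    def test_checkpoint_round_trip(self, separable_pair_normalized, tmp_path):
        refn, srtn = separable_pair_normalized
        model = train_dnn(refn, DnnConfig(epochs=3, hidden=(32, 16, 8, 8), seed=0))
        path = str(tmp_path / "dnn.npz")
        model.save(path)
        from spatype.transfer import DnnModel

        back = DnnModel.load(path)
        np.testing.assert_allclose(
            back.predict_logits(srtn.counts), model.predict_logits(srtn.counts))
        assert back.taxonomy == model.taxonomy


class TestPredictProbabilities:
    @pytest.fixture(scope="class")
    def model_and_data(self, separable_pair_normalized):
        refn, srtn = separable_pair_normalized
        return train_dnn(refn, DnnConfig(epochs=60, hidden=(128, 64, 32, 16), seed=0)), srtn

    def test_rows_sum_to_one(self, model_and_data):
        model, srtn = model_and_data
        table = predict_probabilities(model, srtn)
        np.testing.assert_allclose(table.probs.sum(axis=1), 1.0, atol=1e-6)

    def test_deterministic(self, model_and_data):
        model, srtn = model_and_data
        a = predict_probabilities(model, srtn)
        b = predict_probabilities(model, srtn)
        np.testing.assert_array_equal(a.probs, b.probs)

    def test_recovers_ground_truth_on_separable_fixture(self, model_and_data, separable_pair):
        model, srtn = model_and_data
        _, srt = separable_pair
        table = predict_probabilities(model, srtn)
        pred = np.array(table.types)[table.probs.argmax(axis=1)]
        assert (pred == np.array(srt.labels)).mean() >= 0.95

    def test_gene_mismatch_rejected(self, model_and_data):
        model, srtn = model_and_data
        from dataclasses import replace

        wrong = replace(srtn, genes=[g + "_x" for g in srtn.genes])
        with pytest.raises(ValidationError, match="gene"):
            predict_probabilities(model, wrong)


class TestPseudoLabels:
    def _table(self, logits):
        return ProbabilityTable(
            cells=[f"c{i}" for i in range(len(logits))],
            types=[f"t{j}" for j in range(logits.shape[1])],
            probs=_softmax(logits),
            logits=logits,
        )

    def test_t1_equals_distribution(self):
        rng = np.random.default_rng(2)
        table = self._table(rng.normal(size=(50, 8)))
        out = generate_pseudo_labels(table, T=1.0)
        np.testing.assert_allclose(out.probs, table.probs, atol=1e-9)

    def test_equal_logits_give_uniform(self):
        table = self._table(np.full((4, 6), 3.7))
        for T in (0.5, 1.0, 10.0):
            out = generate_pseudo_labels(table, T=T)
            np.testing.assert_allclose(out.probs, 1.0 / 6.0, atol=1e-12)

    def test_high_temperature_limit(self):
        table = self._table(np.array([[2.0, 0.0]]))
        out = generate_pseudo_labels(table, T=1000.0)
        np.testing.assert_allclose(out.probs, 0.5, atol=1e-3)

    def test_recovers_logits_from_probs_alone(self):
        rng = np.random.default_rng(3)
        table = self._table(rng.normal(size=(10, 4)))
        bare = ProbabilityTable(cells=table.cells, types=table.types, probs=table.probs)
        out = generate_pseudo_labels(bare, T=1.0)
        np.testing.assert_allclose(out.probs, table.probs, atol=1e-9)

    def test_entropy_nondecreasing_in_temperature(self):
        # smoothing property: higher T never sharpens the distribution
        rng = np.random.default_rng(4)
        logits = rng.normal(scale=3.0, size=(1000, 12))
        table = self._table(logits)
        temps = [1.0, 1.5, 2.0, 4.0, 8.0]
        prev = None
        for T in temps:
            probs = generate_pseudo_labels(table, T=T).probs
            ent = -(probs * np.log(probs + 1e-300)).sum(axis=1)
            if prev is not None:
                assert np.all(ent >= prev - 1e-9)
            prev = ent

    def test_invalid_temperature(self):
        table = self._table(np.zeros((1, 2)))
        with pytest.raises(ValueError, match="temperature"):
            generate_pseudo_labels(table, T=0.0)
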