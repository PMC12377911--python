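import itertools

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.metrics import matthews_corrcoef

from bindgraph import (
    ModelSpec,
    ResidueGraph,
    TrainSpec,
    balanced_class_weights,
    build_residue_graph,
    ensemble_vote,
    evaluate,
    improvement,
    kfold_split,
    mcc,
    predict,
    split_train_val,
    train,
    weighted_cross_entropy,
)
from bindgraph.gnn_models import PredictionResult


class TestWeightedLoss:
    def test_perfect_predictions_give_zero_loss(self):
        probs = np.array([[0.0, 1.0], [1.0, 0.0]])
        labels = np.array([1, 0])
        assert weighted_cross_entropy(probs, labels, (1, 1)) == pytest.approx(0.0)

    def test_unit_weights_equal_unweighted_cross_entropy(self):
        rng = np.random.default_rng(0)
        p1 = rng.uniform(0.01, 0.99, size=50)
        probs = np.column_stack([1 - p1, p1])
        labels = rng.integers(0, 2, size=50)
        unweighted = -np.mean(np.log(probs[np.arange(50), labels]))
        assert weighted_cross_entropy(probs, labels, (1.0, 1.0)) == pytest.approx(
            unweighted, abs=1e-8)

    def test_balanced_weights_match_hand_computation(self):
        """2 positives / 98 negatives: w = (100/196, 100/4)."""
        labels = np.array([1] * 2 + [0] * 98)
        w = balanced_class_weights(labels)
        np.testing.assert_allclose(w, [100 / 196, 100 / 4])
        rng = np.random.default_rng(1)
        p1 = rng.uniform(0.05, 0.95, size=100)
        probs = np.column_stack([1 - p1, p1])
        hand = np.mean(w[labels] * -np.log(probs[np.arange(100), labels]))
        assert weighted_cross_entropy(probs, labels, w) == pytest.approx(hand)

    def test_degenerate_probability_is_clamped(self):
        probs = np.array([[1.0, 0.0]])
        loss = weighted_cross_entropy(probs, np.array([1]), (1, 1))
        assert np.isfinite(loss) and loss > 20  # -log(eps), large but finite

    def test_balanced_loss_invariant_to_duplicating_negatives(self):
        rng = np.random.default_rng(2)
        labels = np.array([1] * 5 + [0] * 45)
        p1 = rng.uniform(0.05, 0.95, size=50)
        probs = np.column_stack([1 - p1, p1])
        base = weighted_cross_entropy(probs, labels, balanced_class_weights(labels))
        k = 3  # duplicate every negative k times
        neg = labels == 0
        labels_k = np.concatenate([labels, np.repeat(labels[neg], k - 1)])
        probs_k = np.vstack([probs, np.repeat(probs[neg], k - 1, axis=0)])
        dup = weighted_cross_entropy(probs_k, labels_k, balanced_class_weights(labels_k))
        assert dup == pytest.approx(base, rel=1e-10)


class TestMCC:
    def test_perfect_and_degenerate_cases(self):
        y = np.array([0, 1, 0, 1, 1])
        assert mcc(y, y) == pytest.approx(1.0)
        assert mcc(y, np.ones_like(y)) == 0.0  # zero-denominator convention
        assert mcc(y, np.zeros_like(y)) == 0.0

    def test_closed_form_example(self):
        # TP=2, TN=3, FP=1, FN=1 -> (2*3 - 1*1)/sqrt(3*3*4*4) = 5/12
        y = np.array([1, 1, 1, 0, 0, 0, 0])
        p = np.array([1, 1, 0, 1, 0, 0, 0])
        assert mcc(y, p) == pytest.approx(5 / 12)

    def test_matches_sklearn_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            y = rng.integers(0, 2, size=30)
            p = rng.integers(0, 2, size=30)
            assert mcc(y, p) == pytest.approx(matthews_corrcoef(y, p), abs=1e-12)

    def test_symmetric_under_class_relabeling(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, size=40)
        p = rng.integers(0, 2, size=40)
        assert mcc(y, p) == pytest.approx(mcc(1 - y, 1 - p))


class TestEvaluate:
    def _pred(self, probs):
        return PredictionResult("c", probs, (np.asarray(probs) >= 0.5).astype(int), 0.5)

    def test_perfect_probabilities(self):
        y = np.array([0, 1, 0, 1])
        rep = evaluate(self._pred(y.astype(float)), y)
        assert rep.auc_roc == pytest.approx(1.0)
        assert rep.mcc == pytest.approx(1.0)
        assert rep.aupr == pytest.approx(1.0)

    def test_constant_probabilities_have_no_ranking_information(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        rep = evaluate(self._pred(np.full(6, 0.7)), y)
        assert rep.auc_roc == pytest.approx(0.5)

    def test_auc_equals_concordant_pair_count(self):
        rng = np.random.default_rng(5)
        probs = rng.random(20)
        y = rng.integers(0, 2, size=20)
        y[0], y[1] = 0, 1  # both classes present
        rep = evaluate(self._pred(probs), y)
        pos, neg = probs[y == 1], probs[y == 0]
        pairs = [(1.0 if p > n else 0.5 if p == n else 0.0)
                 for p in pos for n in neg]
        assert rep.auc_roc == pytest.approx(np.mean(pairs))

    def test_single_class_labels_flagged(self):
        rep = evaluate(self._pred(np.array([0.2, 0.8])), np.array([0, 0]))
        assert not rep.auc_defined and np.isnan(rep.auc_roc)

    def test_confusion_counts_sum(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, size=25)
        rep = evaluate(self._pred(rng.random(25)), y)
        assert rep.tp + rep.fp + rep.tn + rep.fn == 25


class TestEnsemble:
    def test_strict_majority(self):
        votes = [np.array([1, 0]), np.array([1, 0]), np.array([1, 0]), np.array([0, 1])]
        np.testing.assert_array_equal(ensemble_vote(votes), [1, 0])

    def test_unanimity(self):
        votes = [np.ones(3, int)] * 4
        np.testing.assert_array_equal(ensemble_vote(votes), np.ones(3, int))

    def test_identical_predictors_equal_single_predictor(self):
        v = np.array([1, 0, 1, 1, 0])
        np.testing.assert_array_equal(ensemble_vote([v, v, v]), v)

    def test_all_16_patterns_match_brute_force_mode_with_positive_ties(self):
        for pattern in itertools.product([0, 1], repeat=4):
            votes = [np.array([b]) for b in pattern]
            ones = sum(pattern)
            expected = 1 if ones > 2 else (1 if ones == 2 else 0)  # tie -> positive
            assert ensemble_vote(votes)[0] == expected, pattern

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            ensemble_vote([np.array([1, 0]), np.array([1])])


def _toy_graphs(n_graphs=6, n_nodes=40, seed=0, separable=False):
    """Tiny labeled graphs; ``separable`` plants the label in feature 0."""
    rng = np.random.default_rng(seed)
    graphs = []
    for _ in range(n_graphs):
        coords = np.cumsum(rng.normal(scale=2.0, size=(n_nodes, 3)), axis=0)
        labels = (rng.random(n_nodes) < 0.2).astype(int)
        if labels.sum() == 0:
            labels[0] = 1
        feats = rng.normal(size=(n_nodes, 5))
        if separable:
            feats[:, 0] = 6.0 * labels - 3.0
        from bindgraph import ProteinChain
        chain = ProteinChain("c", "A" * n_nodes, coords, labels=labels)
        g = build_residue_graph(chain, 8.0)
        g.features = feats
        graphs.append(g)
    return graphs


class TestTrain:
    def test_single_epoch_returns_first_snapshot(self):
        graphs = _toy_graphs()
        res = train(ModelSpec(arch="mlp", hidden_units=8), graphs[:4], graphs[4:],
                    TrainSpec(epochs=1, seed=0))
        assert res.best_epoch == 1 and len(res.log) == 1

    def test_stubbed_validation_trajectory_selects_argmax_epoch(self):
        graphs = _toy_graphs()
        traj = [0.1, 0.4, 0.3]
        res = train(ModelSpec(arch="mlp", hidden_units=8), graphs[:4], graphs[4:],
                    TrainSpec(epochs=3, seed=0),
                    val_metric_fn=lambda model, epoch: traj[epoch - 1])
        assert res.best_epoch == 2
        assert res.best_val_mcc == pytest.approx(0.4)

    def test_best_snapshot_is_never_dominated(self):
        graphs = _toy_graphs(seed=1)
        res = train(ModelSpec(arch="mlp", hidden_units=16), graphs[:4], graphs[4:],
                    TrainSpec(epochs=8, seed=1))
        assert res.best_val_mcc == pytest.approx(max(e["val_mcc"] for e in res.log))

    def test_linearly_separable_features_reach_training_mcc_one(self):
        graphs = _toy_graphs(seed=2, separable=True)
        # select the final epoch's weights: the check is about the training
        # set, so validation-based snapshot selection is bypassed
        res = train(ModelSpec(arch="mlp", hidden_units=16), graphs[:4], graphs[4:],
                    TrainSpec(epochs=200, batch_size=1, seed=2),
                    val_metric_fn=lambda model, epoch: epoch)
        preds = np.concatenate(
            [predict(res.model, g).labels_pred for g in graphs[:4]])
        labels = np.concatenate([g.labels for g in graphs[:4]])
        assert mcc(labels, preds) == pytest.approx(1.0)

    def test_reproducible_given_seed(self):
        graphs = _toy_graphs(seed=3)
        kw = dict(train_spec=TrainSpec(epochs=3, seed=5))
        r1 = train(ModelSpec(arch="gat", hidden_units=8, n_heads=2),
                   graphs[:4], graphs[4:], **kw)
        r2 = train(ModelSpec(arch="gat", hidden_units=8, n_heads=2),
                   graphs[:4], graphs[4:], **kw)
        assert [e["val_mcc"] for e in r1.log] == [e["val_mcc"] for e in r2.log]

    def test_single_class_validation_falls_back_to_loss(self):
        graphs = _toy_graphs(seed=4)
        for g in graphs[4:]:
            g.labels = np.zeros_like(g.labels)
        with pytest.warns(UserWarning, match="single class"):
            res = train(ModelSpec(arch="mlp", hidden_units=8), graphs[:4], graphs[4:],
                        TrainSpec(epochs=2, seed=0))
        assert res.best_epoch in (1, 2)


class TestImprovement:
    def test_equal_folds_give_zero_deltas(self):
        rep = improvement([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert rep.delta_abs == 0.0
        assert rep.per_fold_deltas == [0.0, 0.0, 0.0]

    def test_single_pair_no_improvement(self):
        rep = improvement([0.613], [0.613])
        assert rep.delta_abs == pytest.approx(0.0)
        assert rep.delta_rel == pytest.approx(0.0)
        assert np.isnan(rep.p_value)

    def test_t_statistic_matches_closed_form(self):
        model = [0.6, 0.62, 0.58, 0.61, 0.60]
        base = [0.5, 0.52, 0.49, 0.51, 0.50]
        rep = improvement(model, base)
        rel = np.array([(m - b) / b for m, b in zip(model, base)])
        t_hand = rel.mean() / (rel.std(ddof=1) / np.sqrt(5))
        p_hand = 2 * sps.t.sf(abs(t_hand), df=4)
        assert rep.t_statistic == pytest.approx(t_hand)
        assert rep.p_value == pytest.approx(p_hand)
        assert rep.delta_abs == pytest.approx(0.602 - 0.504, abs=1e-12)

    def test_zero_baseline_fold_is_excluded_with_flag(self):
        rep = improvement([0.5, 0.6], [0.0, 0.5])
        assert rep.excluded_folds == [0]
        assert rep.per_fold_deltas == [pytest.approx(0.2)]


class TestSplits:
    def test_split_sizes_and_determinism(self):
        items = list(range(20))
        tr, va = split_train_val(items, 6, seed=1)
        assert len(va) == 6 and len(tr) == 14 and not set(tr) & set(va)
        tr2, va2 = split_train_val(items, 6, seed=1)
        assert va == va2

    def test_fractional_validation_size(self):
        tr, va = split_train_val(list(range(10)), 0.3, seed=0)
        assert len(va) == 3

    def test_kfold_covers_everything_once(self):
        items = list(range(11))
        seen = []
        for tr, va in kfold_split(items, k=5, seed=2):
            assert not set(tr) & set(va)
            seen.extend(va)
        assert sorted(seen) == items
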