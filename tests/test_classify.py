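"""Ensemble kNN: parameter sweep, iterative majority voting, greedy final choice."""

import numpy as np
import pytest

from cubicpat.classify import (
    PARAM_GRID,
    OutcomePool,
    confusion_metrics,
    iterative_majority_vote,
    make_cv,
    parameter_outcomes,
    select_final,
    tknn_classify,
)


def separable_data(rng, n_per_class=20, n_features=5, sep=6.0):
    y = np.repeat([0, 1], n_per_class)
    X = rng.normal(size=(y.size, n_features)) + sep * y[:, None]
    return X, y


def test_parameter_grid_is_the_full_cartesian_product():
    assert len(PARAM_GRID) == 30
    ks, dists, ws = zip(*PARAM_GRID)
    assert set(ks) == {1, 2, 3, 4, 5}
    assert set(dists) == {"cityblock", "chebyshev", "euclidean"}
    assert set(ws) == {"inverse", "equal"}
    assert len(set(PARAM_GRID)) == 30


class TestParameterOutcomes:
    def test_thirty_outcomes_one_prediction_per_sample(self, rng):
        X, y = separable_data(rng, sep=0.5)
        cv = make_cv(y, "kfold10", seed=1)
        pool = parameter_outcomes(X, y, cv)
        assert pool.predictions.shape == (30, y.size)
        assert pool.accuracies.shape == (30,)
        assert np.all((pool.accuracies >= 0) & (pool.accuracies <= 1))

    def test_perfectly_separable_data_all_accuracies_one(self, rng):
        X, y = separable_data(rng, sep=50.0)
        pool = parameter_outcomes(X, y, make_cv(y, "kfold10", seed=1))
        assert np.all(pool.accuracies == 1.0)

    def test_deterministic_for_fixed_folds(self, rng):
        X, y = separable_data(rng, sep=0.5)
        cv = make_cv(y, "kfold10", seed=3)
        a = parameter_outcomes(X, y, cv)
        b = parameter_outcomes(X, y, cv)
        assert np.array_equal(a.predictions, b.predictions)

    def test_inverse_and_equal_weighting_agree_at_k1(self, rng):
        X, y = separable_data(rng, sep=0.5)
        pool = parameter_outcomes(X, y, make_cv(y, "kfold10", seed=1))
        for dist in ("cityblock", "chebyshev", "euclidean"):
            i_inv = PARAM_GRID.index((1, dist, "inverse"))
            i_eq = PARAM_GRID.index((1, dist, "equal"))
            assert np.array_equal(pool.predictions[i_inv], pool.predictions[i_eq])

    def test_k_truncated_with_warning_on_tiny_folds(self, rng):
        y = np.array([0, 1, 0, 1, 0, 1])
        X = rng.normal(size=(6, 3))
        groups = np.array(["a", "a", "b", "b", "c", "c"])
        cv = make_cv(y, "loso", groups=groups)
        with pytest.warns(UserWarning, match="using k="):
            pool = parameter_outcomes(X, y, cv)
        assert pool.predictions.shape == (30, 6)


class TestIterativeMajorityVote:
    def test_twenty_eight_voted_outcomes(self, rng):
        X, y = separable_data(rng, sep=0.5)
        pool = parameter_outcomes(X, y, make_cv(y, "kfold10", seed=1))
        voted = iterative_majority_vote(pool, y)
        assert voted.voted.shape == (28, y.size)
        assert voted.order.shape == (30,)

    def test_unanimous_pool_votes_identically(self):
        y = np.array([0, 1, 0, 1])
        pred = np.tile(np.array([0, 1, 1, 0]), (30, 1))
        pool = OutcomePool(predictions=pred, accuracies=np.full(30, 0.5))
        voted = iterative_majority_vote(pool, y)
        assert np.all(voted.voted == pred[0])

    def test_mode_of_top_three(self):
        y = np.array([1, 2, 1, 2])
        pred = np.tile(np.array([2, 2, 2, 2]), (30, 1))
        # make outcomes 0..2 the most accurate; they predict [1, 1, 2] for sample 0
        pred[0] = [1, 1, 1, 2]
        pred[1] = [1, 2, 1, 2]
        pred[2] = [2, 2, 1, 2]
        accs = np.concatenate([[1.0, 0.99, 0.98], np.full(27, 0.1)])
        voted = iterative_majority_vote(OutcomePool(predictions=pred, accuracies=accs), y)
        assert voted.voted[0, 0] == 1  # q=3: mode of (1, 1, 2)

    def test_vote_tie_goes_to_most_accurate_outcome(self):
        y = np.array([1, 2, 1, 2])
        pred = np.tile(np.array([2, 2, 2, 2]), (30, 1))
        pred[0] = [1, 1, 1, 2]  # most accurate outcome predicts 1 for sample 0
        pred[1] = [2, 2, 1, 2]
        pred[2] = [1, 2, 1, 2]
        pred[3] = [2, 2, 2, 2]
        accs = np.concatenate([[1.0, 0.99, 0.98, 0.97], np.full(26, 0.1)])
        voted = iterative_majority_vote(OutcomePool(predictions=pred, accuracies=accs), y)
        # q=4 over sample 0: votes (1, 2, 1, 2) tie -> label of outcome ranked first
        assert voted.voted[1, 0] == 1

    def test_voted_labels_come_from_participating_outcomes(self, rng):
        X, y = separable_data(rng, sep=0.5)
        pool = parameter_outcomes(X, y, make_cv(y, "kfold10", seed=1))
        voted = iterative_majority_vote(pool, y)
        sorted_preds = pool.predictions[voted.order]
        for qi, q in enumerate(range(3, 31)):
            top_q = sorted_preds[:q]
            assert np.all((voted.voted[qi] == top_q).any(axis=0))


class TestSelectFinal:
    def test_fifty_eight_candidates_and_greedy_dominance(self, rng):
        X, y = separable_data(rng, sep=0.5)
        pool = parameter_outcomes(X, y, make_cv(y, "kfold10", seed=1))
        voted = iterative_majority_vote(pool, y)
        final = select_final(pool, voted, y)
        assert final.candidate_accuracies.shape == (58,)
        assert final.accuracy == final.candidate_accuracies.max()
        assert final.accuracy >= pool.accuracies.max()

    def test_perfect_parameter_outcome_gives_perfect_final(self, rng):
        X, y = separable_data(rng, sep=50.0)
        final, pool, _ = tknn_classify(X, y, scheme="kfold10", seed=1)
        assert pool.accuracies.max() == 1.0
        assert final.accuracy == 1.0

    def test_ties_resolved_to_lowest_candidate_index(self):
        y = np.array([0, 1] * 10)
        pred = np.tile(y, (30, 1))  # every outcome identical and perfect
        pool = OutcomePool(predictions=pred, accuracies=np.ones(30))
        voted = iterative_majority_vote(pool, y)
        final = select_final(pool, voted, y)
        assert final.chosen_index == 0
        assert final.chosen_source.startswith("parameter(k=1")


class TestLosoBookkeeping:
    def make_grouped(self, rng, n_subjects=6, epochs_each=4):
        subjects = np.repeat([f"s{i}" for i in range(n_subjects)], epochs_each)
        y = np.repeat([0, 1] * (n_subjects // 2), epochs_each)
        X = rng.normal(size=(subjects.size, 4)) + 0.5 * y[:, None]
        return X, y, subjects

    def test_each_fold_holds_out_exactly_one_subject(self, rng):
        X, y, subjects = self.make_grouped(rng)
        for tr, te in make_cv(y, "loso", groups=subjects):
            held_out = set(subjects[te])
            assert len(held_out) == 1
            assert held_out.isdisjoint(set(subjects[tr]))

    def test_subject_predictions_unaffected_by_own_labels(self, rng):
        # a subject's labels enter only *other* subjects' training folds,
        # so flipping them must leave that subject's predictions unchanged
        X, y, subjects = self.make_grouped(rng)
        cv = make_cv(y, "loso", groups=subjects)
        pool = parameter_outcomes(X, y, cv)
        y_poisoned = y.copy()
        mask = subjects == "s2"
        y_poisoned[mask] = 1 - y_poisoned[mask]
        pool_p = parameter_outcomes(X, y_poisoned, make_cv(y_poisoned, "loso",
                                                           groups=subjects))
        assert np.array_equal(pool.predictions[:, mask], pool_p.predictions[:, mask])


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        y = np.repeat([0, 1], 50)
        m = confusion_metrics(y, y)
        assert m["accuracy"] == 1.0
        assert m["geometric_mean"] == 1.0
        assert m["f1_macro"] == 1.0

    def test_hand_computed_two_by_two_table(self):
        # confusion matrix [[45, 5], [10, 40]]
        y_true = np.repeat([0, 1], 50)
        y_pred = np.concatenate([np.repeat([0, 1], [45, 5]), np.repeat([0, 1], [10, 40])])
        m = confusion_metrics(y_true, y_pred)
        assert m["confusion_matrix"] == [[45, 5], [10, 40]]
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["geometric_mean"] == pytest.approx(np.sqrt(0.9 * 0.8))
        assert m["f1_per_class"][0] == pytest.approx(0.857142857, abs=1e-6)

    def test_constant_prediction_zeroes_geometric_mean(self):
        y_true = np.repeat([0, 1], 10)
        m = confusion_metrics(y_true, np.zeros_like(y_true))
        assert m["geometric_mean"] == 0.0

    def test_class_absent_from_truth_warns_nan(self):
        with pytest.warns(UserWarning, match="absent"):
            m = confusion_metrics(np.zeros(4, int), np.array([0, 0, 1, 0]))
        assert np.isnan(m["geometric_mean"])


def test_unknown_cv_scheme_rejected():
    with pytest.raises(ValueError, match="unknown CV scheme"):
        make_cv(np.array([0, 1, 0, 1]), "bootstrap")
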