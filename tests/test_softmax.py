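import numpy as np
import pytest

from repotrx.softmax import (
    averaged_probability_matrix,
    confusion_counts,
    confusion_matrix,
    gradient,
    k_fold_split,
    make_label_matrix,
    normalize_targets,
    objective,
    predict_classification,
    sample_accuracy,
    softmax_probabilities,
    train,
)


class TestNormalizeTargets:
    def test_single_label_row_unchanged(self):
        np.testing.assert_array_equal(
            normalize_targets(np.array([[1.0, 0.0, 0.0]])), [[1.0, 0.0, 0.0]]
        )

    def test_multi_label_row_split_evenly(self):
        np.testing.assert_allclose(
            normalize_targets(np.array([[1.0, 1.0, 0.0]])), [[0.5, 0.5, 0.0]]
        )

    def test_rows_sum_to_one(self, rng):
        lb = (rng.random((20, 5)) < 0.4).astype(float)
        lb[lb.sum(axis=1) == 0, 0] = 1.0
        np.testing.assert_allclose(normalize_targets(lb).sum(axis=1), 1.0)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize_targets(np.array([[1.0, 0.0], [0.0, 0.0]]))


class TestSoftmaxProbabilities:
    def test_zero_theta_gives_uniform(self):
        p = softmax_probabilities(np.zeros((4, 6)), np.array([0.3, -1.2, 0.8, 2.0, -0.5]))
        np.testing.assert_allclose(p, np.full((1, 4), 0.25))

    def test_shift_invariance(self, rng):
        """Adding a constant vector to every class's weights leaves the
        probabilities unchanged (the softmax degeneracy)."""
        theta = rng.normal(size=(3, 5))
        shift = rng.normal(size=5)
        x = rng.normal(size=(4, 4))
        np.testing.assert_allclose(
            softmax_probabilities(theta, x),
            softmax_probabilities(theta + shift[None, :], x),
            atol=1e-12,
        )

    def test_two_class_reduces_to_logistic(self):
        # logits (1, 0) -> (e/(1+e), 1/(1+e))
        theta = np.array([[0.0, 1.0], [0.0, 0.0]])  # bias-only logits 1 and 0
        p = softmax_probabilities(theta, np.zeros((1, 1)))
        e = np.e
        np.testing.assert_allclose(p, [[e / (1 + e), 1 / (1 + e)]])

    def test_rows_stochastic_under_extreme_logits(self, rng):
        theta = rng.normal(size=(5, 11)) * 200
        p = softmax_probabilities(theta, rng.normal(size=(6, 10)))
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0)


class TestObjective:
    def test_perfect_onehot_predictions_zero_loss(self):
        # huge bias toward the true class, no regularization
        theta = np.zeros((2, 3))
        theta[0, -1] = 500.0
        dm = np.zeros((3, 2))
        y = np.tile([1.0, 0.0], (3, 1))
        assert objective(theta, dm, y, lam=0.0) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_predictions_onehot_targets_ln_q(self):
        q = 7
        theta = np.zeros((q, 4))
        dm = np.ones((5, 3))
        y = np.eye(q)[np.zeros(5, dtype=int)]
        assert objective(theta, dm, y, lam=0.0) == pytest.approx(np.log(q))

    def test_matches_double_loop_oracle(self, rng):
        """Vectorised objective equals naive elementwise summation."""
        theta = rng.normal(size=(3, 5))
        dm = rng.normal(size=(4, 4))
        y = normalize_targets((rng.random((4, 3)) < 0.5).astype(float) + 1e-9)
        lam = 0.7
        p = softmax_probabilities(theta, dm)
        ce = 0.0
        for i in range(4):
            for j in range(3):
                ce -= y[i, j] * np.log(p[i, j])
        expected = ce / 4 + lam * sum(
            theta[j, k] ** 2 for j in range(3) for k in range(4)  # bias col excluded
        )
        assert objective(theta, dm, y, lam) == pytest.approx(expected, abs=1e-12)


class TestGradient:
    def test_matches_central_finite_differences(self, rng):
        theta = rng.normal(size=(3, 5)) * 0.3
        dm = rng.normal(size=(5, 4))
        y = normalize_targets((rng.random((5, 3)) < 0.5).astype(float) + 1e-9)
        lam = 0.4
        g = gradient(theta, dm, y, lam)
        eps = 1e-6
        for j in range(3):
            for k in range(5):
                tp, tm = theta.copy(), theta.copy()
                tp[j, k] += eps
                tm[j, k] -= eps
                fd = (objective(tp, dm, y, lam) - objective(tm, dm, y, lam)) / (2 * eps)
                assert g[j, k] == pytest.approx(fd, rel=1e-6, abs=1e-8)

    def test_zero_gradient_at_separable_optimum(self, rng):
        """After unregularized full-batch descent on a tiny separable
        problem, the gradient norm shrinks toward zero."""
        dm = np.array([[4.0, 0.0], [0.0, 4.0], [-4.0, -4.0]])
        lb = np.eye(3)
        theta, _ = train(
            dm, lb, learning_rate=0.5, lam=0.0, batch_size=3,
            iterations=2000, averaging_window=1, seed=0,
        )
        g = gradient(theta, dm, normalize_targets(lb), 0.0)
        assert np.linalg.norm(g) < 1e-3

    def test_regularizer_contribution_is_weight_decay(self, rng):
        """When P == Y the data term vanishes and the gradient is exactly
        2*lam*theta on non-bias columns, 0 on the bias column."""
        theta = rng.normal(size=(2, 4))
        theta[1] = theta[0]  # equal logits -> P = (0.5, 0.5) everywhere
        dm = rng.normal(size=(3, 3))
        y = np.full((3, 2), 0.5)
        lam = 0.9
        g = gradient(theta, dm, y, lam)
        np.testing.assert_allclose(g[:, :-1], 2 * lam * theta[:, :-1], atol=1e-12)
        np.testing.assert_allclose(g[:, -1], 0.0, atol=1e-12)


class TestTrain:
    def test_zero_iterations_leaves_theta_zero(self):
        dm = np.array([[1.0, 2.0]])
        theta, hist = train(dm, np.array([[1.0, 0.0]]), iterations=0, averaging_window=0)
        np.testing.assert_array_equal(theta, 0.0)
        assert len(hist) == 0

    def test_separable_data_reaches_full_training_accuracy(self):
        """Three well-separated classes reach sample accuracy 1.0 at the
        0.30 training threshold within 500 epochs at default learning
        hyper-parameters."""
        rng = np.random.default_rng(2)
        centers = np.array([[6.0, 0.0, 0.0], [0.0, 6.0, 0.0], [0.0, 0.0, 6.0]])
        dm = np.vstack([centers[i] + 0.2 * rng.normal(size=(10, 3)) for i in range(3)])
        lb = np.eye(3)[np.repeat(np.arange(3), 10)]
        _, hist = train(dm, lb, iterations=500, averaging_window=1, seed=0)
        assert max(hist.train_accuracy) == 1.0

    def test_full_batch_descent_is_monotone(self, rng):
        """Full-batch mode with a small learning rate never increases the
        objective (convexity sanity)."""
        dm = rng.normal(size=(12, 4))
        lb = np.eye(3)[rng.integers(3, size=12)]
        _, hist = train(
            dm, lb, learning_rate=0.01, lam=0.1, batch_size=12,
            iterations=60, averaging_window=1, seed=0,
        )
        diffs = np.diff(hist.loss)
        assert np.all(diffs <= 1e-12)

    def test_fixed_seed_reproduces_training(self, rng):
        dm = rng.normal(size=(20, 6))
        lb = np.eye(4)[rng.integers(4, size=20)]
        t1, h1 = train(dm, lb, iterations=30, averaging_window=5, batch_size=8, seed=3)
        t2, h2 = train(dm, lb, iterations=30, averaging_window=5, batch_size=8, seed=3)
        np.testing.assert_array_equal(t1, t2)
        assert h1.loss == h2.loss


class TestThresholding:
    def test_threshold_030(self):
        # probabilities ~(0.5, 0.3, 0.2): classes at or above 0.30 are called
        theta = np.hstack([np.zeros((3, 1)), np.log([[0.5], [0.3], [0.2]])])
        x = np.zeros((1, 1))
        p = softmax_probabilities(theta, x)
        cf = predict_classification(theta, x, float(p[0, 1]))  # closed boundary
        np.testing.assert_array_equal(cf, [[1.0, 1.0, 0.0]])
        # strictly above the middle probability, only the 0.5 class survives
        cf = predict_classification(theta, x, float(p[0, 1]) + 1e-12)
        np.testing.assert_array_equal(cf, [[1.0, 0.0, 0.0]])

    def test_validation_threshold_boundary(self):
        """p = 0.07 is called positive at the 0.06 validation threshold;
        p = 0.05 is not."""
        probs = np.array([0.07, 0.05, 0.88])
        theta = np.hstack([np.zeros((3, 1)), np.log(probs)[:, None]])
        cf = predict_classification(theta, np.zeros((1, 1)), 0.06)
        np.testing.assert_array_equal(cf, [[1.0, 0.0, 1.0]])

    def test_threshold_above_one_gives_all_zero(self, rng):
        theta = rng.normal(size=(4, 3))
        cf = predict_classification(theta, rng.normal(size=(5, 2)), 1.5)
        np.testing.assert_array_equal(cf, 0.0)


class TestAccuracyAndConfusion:
    def test_perfect_prediction_no_errors(self, rng):
        lb = (rng.random((8, 4)) < 0.5).astype(float)
        counts = confusion_counts(lb, lb)
        assert np.all(counts["FP"] == 0) and np.all(counts["FN"] == 0)

    def test_swapped_single_sample(self):
        lb = np.array([[1.0, 0.0]])
        cf = np.array([[0.0, 1.0]])
        counts = confusion_counts(lb, cf)
        assert counts["FN"][0] == 1 and counts["FP"][1] == 1
        assert counts["TP"].sum() == 0

    def test_counts_match_cell_oracle_and_sum_to_m(self, rng):
        lb = (rng.random((6, 3)) < 0.5).astype(float)
        cf = (rng.random((6, 3)) < 0.5).astype(float)
        counts = confusion_counts(lb, cf)
        for j in range(3):
            tp = tn = fp = fn = 0
            for i in range(6):
                if lb[i, j] == 1 and cf[i, j] == 1:
                    tp += 1
                elif lb[i, j] == 0 and cf[i, j] == 0:
                    tn += 1
                elif cf[i, j] == 1:
                    fp += 1
                else:
                    fn += 1
            assert (counts["TP"][j], counts["TN"][j], counts["FP"][j], counts["FN"][j]) == (
                tp, tn, fp, fn,
            )
            assert tp + tn + fp + fn == 6

    def test_one_true_positive_suffices_for_sample(self):
        lb = np.array([[1.0, 1.0, 0.0]])
        cf = np.array([[1.0, 0.0, 1.0]])
        assert sample_accuracy(lb, cf) == 1.0

    def test_all_zero_predictions_score_zero(self, rng):
        lb = np.eye(3)[rng.integers(3, size=5)]
        assert sample_accuracy(lb, np.zeros((5, 3))) == 0.0

    def test_accuracy_matches_enumeration(self):
        lb = np.array(
            [[1, 0, 0], [1, 1, 0], [0, 0, 1], [0, 1, 0], [1, 0, 1]], dtype=float
        )
        cf = np.array(
            [[1, 1, 0], [0, 0, 1], [0, 0, 1], [0, 1, 1], [0, 0, 0]], dtype=float
        )
        # by hand: samples 0, 2, 3 have a coinciding positive; 1 and 4 do not
        assert sample_accuracy(lb, cf) == pytest.approx(3 / 5)

    def test_confusion_matrix_perfect_predictor_is_diagonal(self):
        lb = np.eye(4)[[0, 1, 2, 3, 1, 2]]
        pred = np.array([0, 1, 2, 3, 1, 2])
        cm = confusion_matrix(lb, pred)
        assert np.all(cm == np.diag(np.diag(cm)))
        np.testing.assert_array_equal(np.diag(cm), [1, 2, 2, 1])

    def test_confusion_matrix_conserves_instances(self, rng):
        lb = (rng.random((10, 4)) < 0.4).astype(float)
        lb[lb.sum(axis=1) == 0, 0] = 1.0
        pred = rng.integers(4, size=10)
        cm = confusion_matrix(lb, pred)
        assert cm.sum() == int(lb.sum())  # one entry per (sample, actual label)
        np.testing.assert_array_equal(cm.sum(axis=1), lb.sum(axis=0).astype(int))

    def test_confusion_matrix_matches_tally(self):
        lb = np.array([[1, 1, 0], [0, 1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        pred = np.array([1, 1, 0, 0])
        expected = np.zeros((3, 3), dtype=int)
        # sample 0: actual {0,1} -> pred 1 twice; sample 1: {1}->1;
        # sample 2: {0}->0; sample 3: {2}->0
        expected[0, 1] += 1
        expected[1, 1] += 2
        expected[0, 0] += 1
        expected[2, 0] += 1
        np.testing.assert_array_equal(confusion_matrix(lb, pred), expected)


class TestKFold:
    def test_even_fold_sizes(self):
        drugs = [f"d{i}" for i in range(10)]
        splits = k_fold_split(drugs, 5, seed=0)
        assert all(len(val) == 2 for _, val in splits)

    def test_partition_properties(self):
        drugs = [f"d{i}" for i in range(13)]
        splits = k_fold_split(drugs, 4, seed=1)
        vals = [set(v) for _, v in splits]
        assert set().union(*vals) == set(drugs)
        for i in range(4):
            for j in range(i + 1, 4):
                assert not vals[i] & vals[j]
        for train_drugs, val in splits:
            assert set(train_drugs) | set(val) == set(drugs)
            assert not set(train_drugs) & set(val)

    def test_no_drug_replicate_leakage(self, small_cohort):
        """All samples of a multi-trial drug land on one side of every split."""
        _, table, _, _ = small_cohort
        splits = k_fold_split(table.drugs, 3, seed=0)
        for train_drugs, val_drugs in splits:
            tr, va = set(train_drugs), set(val_drugs)
            for sid in table.sample_ids:
                drug = table.drug_of_sample[sid]
                assert (drug in tr) != (drug in va)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            k_fold_split(["a", "b", "c"], 1)
        with pytest.raises(ValueError):
            k_fold_split(["a", "b", "c"], 4)


class TestAveragedProbabilityMatrix:
    def test_constant_history_is_identity(self):
        p = np.array([[0.6, 0.4], [0.1, 0.9]])
        out = averaged_probability_matrix([p, p, p], ["d1", "d2"], ["A", "B"])
        np.testing.assert_allclose(out.to_numpy(), p)

    def test_window_arithmetic(self):
        p = np.array([[0.2, 0.8]])
        out = averaged_probability_matrix([p, 3 * p], ["d1"], ["A", "B"])
        np.testing.assert_allclose(out.to_numpy(), 2 * p)

    def test_per_drug_sample_averaging_and_stochastic_rows(self, rng):
        mats = [
            np.apply_along_axis(lambda r: r / r.sum(), 1, rng.random((6, 3)))
            for _ in range(4)
        ]
        drugs = ["d1", "d1", "d2", "d2", "d2", "d3"]
        out = averaged_probability_matrix(mats, drugs, ["A", "B", "C"])
        assert list(out.index) == ["d1", "d2", "d3"]
        np.testing.assert_allclose(out.sum(axis=1), 1.0)
        mean_all = np.mean(np.stack(mats), axis=0)
        np.testing.assert_allclose(out.loc["d2"].to_numpy(), mean_all[2:5].mean(axis=0))
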