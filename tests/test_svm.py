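"""Kernel evaluation, binary SVM in support-vector form, and the phase tree."""

import numpy as np
import pytest

from cyclephase.svm import (
    KernelSpec,
    decision_values,
    kernel_eval,
    kernel_grid_report,
    predict_binary,
    predict_tree,
    train_binary,
    train_tree,
    tree_from_json,
    tree_to_json,
)


class TestKernelEval:
    def test_rbf_at_zero_distance(self):
        u = np.array([1.0, 2.0, 3.0])
        assert kernel_eval(KernelSpec("rbf", gamma=2.0), u, u) == pytest.approx(1.0)

    def test_linear_orthogonal(self):
        assert kernel_eval(
            KernelSpec("linear"), np.array([1.0, 0.0]), np.array([0.0, 1.0])
        ) == pytest.approx(0.0)

    def test_rbf_direct_evaluation(self):
        u = np.array([0.0])
        v = np.array([np.sqrt(np.log(4.0))])
        assert kernel_eval(KernelSpec("rbf", gamma=1.0), u, v) == pytest.approx(0.25)

    def test_polynomial_and_sigmoid_forms(self):
        u, v = np.array([1.0, 2.0]), np.array([3.0, 1.0])
        dot = 5.0
        assert kernel_eval(
            KernelSpec("polynomial", gamma=0.5, degree=3, coef0=1.0), u, v
        ) == pytest.approx((0.5 * dot + 1.0) ** 3)
        assert kernel_eval(
            KernelSpec("sigmoid", gamma=0.1, coef0=-0.2), u, v
        ) == pytest.approx(np.tanh(0.1 * dot - 0.2))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kernel_eval(KernelSpec("rbf"), np.ones(3), np.ones(4))

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            KernelSpec("rbf", gamma=0.0)


class TestTrainBinary:
    def test_separates_two_points(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array([-1, 1])
        m = train_binary(X, y, C=10.0, kernel=KernelSpec("linear"))
        labels, _ = predict_binary(m, X)
        np.testing.assert_array_equal(labels, y)

    def test_xor_with_rbf(self):
        X = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        y = np.array([1, 1, -1, -1])
        m = train_binary(X, y, C=10.0, kernel=KernelSpec("rbf", gamma=1.0))
        labels, _ = predict_binary(m, X)
        np.testing.assert_array_equal(labels, y)

    def test_label_flip_negates_decision_values(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 3))
        y = np.where(X[:, 0] + 0.3 * rng.normal(size=40) > 0, 1, -1)
        P = rng.normal(size=(10, 3))
        m1 = train_binary(X, y, C=1.0, kernel=KernelSpec("rbf", gamma=0.5))
        m2 = train_binary(X, -y, C=1.0, kernel=KernelSpec("rbf", gamma=0.5))
        # agreement is limited by the QP solver's convergence tolerance
        np.testing.assert_allclose(
            decision_values(m1, P), -np.asarray(decision_values(m2, P)), atol=5e-3
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_binary(np.ones((5, 2)), np.ones(5, int), 1.0, KernelSpec("rbf"))

    def test_dual_constraints_hold(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 4))
        y = np.where(X[:, 1] > 0, 1, -1)
        m = train_binary(X, y, C=2.0, kernel=KernelSpec("rbf", gamma=1.0))
        assert abs(np.sum(m.Q * m.alpha)) < 1e-8
        assert np.all(m.alpha >= -1e-12)
        assert np.all(m.alpha <= m.C + 1e-8)


class TestPredictBinary:
    def test_decision_matches_explicit_sum_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 5))
        y = np.where(X[:, 2] - X[:, 0] > 0, 1, -1)
        m = train_binary(X, y, C=2.0, kernel=KernelSpec("rbf", gamma=1.0))
        P = rng.normal(size=(20, 5))
        vals = decision_values(m, P)
        for j in range(len(P)):  # scalar summation loop, independent path
            s = m.bias
            for i in range(len(m.support_vectors)):
                d2 = float(np.sum((m.support_vectors[i] - P[j]) ** 2))
                s += m.Q[i] * m.alpha[i] * np.exp(-m.kernel.gamma * d2)
            assert vals[j] == pytest.approx(s, abs=1e-8)

    def test_zero_decision_value_maps_to_plus_one(self):
        m = train_binary(
            np.array([[-1.0], [1.0]]), np.array([-1, 1]), 1.0, KernelSpec("linear")
        )
        label, value = predict_binary(m, np.array([0.0]))
        assert value == pytest.approx(0.0, abs=1e-10)
        assert label == 1

    def test_dimension_mismatch_rejected(self):
        m = train_binary(
            np.array([[-1.0], [1.0]]), np.array([-1, 1]), 1.0, KernelSpec("linear")
        )
        with pytest.raises(ValueError):
            predict_binary(m, np.ones(3))


class TestPhaseTree:
    def test_training_sets_shrink_down_the_tree(self, toy_clusters):
        model = train_tree(toy_clusters, (10.0, 1.0))
        sizes = [m.n_train for m in model.nodes]
        assert sizes[0] >= sizes[1] >= sizes[2]
        assert sizes == [120, 90, 60]

    def test_separable_clusters_classified_perfectly(self, toy_clusters):
        model = train_tree(toy_clusters, (10.0, 1.0))
        pred = predict_tree(model, toy_clusters.X)
        np.testing.assert_array_equal(pred, toy_clusters.y)

    def test_missing_class_rejected(self, toy_clusters):
        ds = toy_clusters.subset(toy_clusters.y != 2)
        with pytest.raises(ValueError):
            train_tree(ds, (1.0, 1.0))

    def test_prediction_total_and_deterministic(self, toy_clusters):
        model = train_tree(toy_clusters, (10.0, 1.0))
        rng = np.random.default_rng(8)
        P = rng.normal(size=(50, 5)) * 6
        p1 = predict_tree(model, P)
        p2 = predict_tree(model, P)
        np.testing.assert_array_equal(p1, p2)
        assert set(np.unique(p1)) <= {1, 2, 3, 4}

    def test_rejected_by_all_nodes_is_upper_buffer(self, toy_clusters):
        model = train_tree(toy_clusters, (10.0, 1.0))
        # a point deep inside the phase-4 cluster is rejected by nodes 1-3
        assert predict_tree(model, np.array([8.0, 8.0, 0.0, 0.0, 0.0])) == 4

    def test_increasing_c_never_hurts_training_accuracy(self, toy_clusters):
        accs = []
        for C in (0.01, 1.0, 100.0):
            model = train_tree(toy_clusters, (C, 1.0))
            accs.append(np.mean(predict_tree(model, toy_clusters.X) == toy_clusters.y))
        assert np.all(np.diff(accs) >= 0)

    def test_serialization_round_trip(self, toy_clusters):
        model = train_tree(toy_clusters, (10.0, 1.0))
        restored = tree_from_json(tree_to_json(model))
        P = np.random.default_rng(9).normal(size=(20, 5)) * 6
        np.testing.assert_array_equal(
            predict_tree(model, P), predict_tree(restored, P)
        )


class TestKernelGridReport:
    def test_shape_and_perfect_rbf_on_separable_data(self, toy_clusters):
        pairs = ((2, 1), (1, 1))
        report = kernel_grid_report(toy_clusters, toy_clusters, pairs)
        assert report.shape == (4, len(pairs))
        assert (report.loc["rbf"] == 100.0).all()

    def test_rbf_at_least_as_good_as_sigmoid(self, toy_clusters):
        report = kernel_grid_report(toy_clusters, toy_clusters, ((2, 1),))
        assert report.loc["rbf"].iloc[0] >= report.loc["sigmoid"].iloc[0]
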