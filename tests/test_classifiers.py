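import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from eogwave.classifiers import (
    KernelParams,
    dt_fit,
    dt_predict,
    dt_proba,
    euclidean_distance,
    gini,
    knn_fit,
    knn_predict,
    knn_scores,
    load_model,
    poly_kernel,
    save_model,
    svm_decision,
    svm_fit,
    svm_predict,
)

vectors = hnp.arrays(
    float, 5, elements=st.floats(-10, 10, allow_nan=False, allow_infinity=False)
)


class TestEuclidean:
    def test_three_four_five_triangle(self):
        assert euclidean_distance([0, 0], [3, 4]) == pytest.approx(5.0)

    @given(x=vectors, y=vectors)
    def test_symmetry_and_identity(self, x, y):
        assert euclidean_distance(x, y) == pytest.approx(euclidean_distance(y, x))
        assert euclidean_distance(x, x) == 0.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distance([1, 2], [1, 2, 3])


def brute_force_knn(X, y, query, k):
    """Independent oracle: sort all pairwise distances, majority vote,
    ties toward the tied class of the nearest neighbour."""
    dists = [euclidean_distance(query, row) for row in X]
    order = sorted(range(len(X)), key=lambda i: (dists[i], i))[:k]
    votes = {}
    for i in order:
        votes[y[i]] = votes.get(y[i], 0) + 1
    top = max(votes.values())
    tied = {c for c, v in votes.items() if v == top}
    for i in order:
        if y[i] in tied:
            return y[i]
    raise AssertionError("unreachable")


class TestKNN:
    def test_query_on_training_point_with_k1(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.integers(0, 3, 20)
        model = knn_fit(X, y, k=1)
        for i in (0, 7, 19):
            assert knn_predict(model, X[i]) == y[i]

    def test_agrees_with_brute_force_oracle(self, rng):
        X = rng.normal(size=(40, 4))
        y = rng.integers(0, 5, 40)
        model = knn_fit(X, y, k=3, standardize=False)
        for _ in range(200):
            q = rng.normal(size=4)
            assert knn_predict(model, q) == brute_force_knn(X, y, q, 3)

    def test_agrees_with_sklearn_on_tie_free_binary_problem(self, rng):
        sklearn_knn = pytest.importorskip("sklearn.neighbors")
        X = rng.normal(size=(60, 3))
        y = rng.integers(0, 2, 60)
        q = rng.normal(size=(30, 3))
        model = knn_fit(X, y, k=5, standardize=False)  # odd K: no vote ties
        ref = sklearn_knn.KNeighborsClassifier(5).fit(X, y).predict(q)
        assert np.array_equal(knn_predict(model, q), ref)

    def test_vote_tie_breaks_toward_nearest_neighbour(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array([1, 1, 0, 0])
        model = knn_fit(X, y, k=2, standardize=False)
        assert knn_predict(model, [0.4]) == 1
        assert knn_predict(model, [10.4]) == 0

    def test_scores_are_vote_fractions(self):
        X = np.array([[0.0], [0.1], [0.2], [5.0]])
        y = np.array([0, 0, 1, 1])
        model = knn_fit(X, y, k=4, standardize=False)
        scores = knn_scores(model, [0.0])
        assert scores == pytest.approx([0.5, 0.5])

    def test_invalid_k_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            knn_fit(X, np.zeros(5, dtype=int), k=6)
        with pytest.raises(ValueError):
            knn_fit(X, np.zeros(5, dtype=int), k=0)


class TestPolyKernel:
    def test_hand_example(self):
        assert poly_kernel([1, 0], [1, 1], KernelParams(1.0, 1.0, 2)) == pytest.approx(4.0)

    def test_linear_reduction(self):
        params = KernelParams(0.5, 0.0, 1)
        assert poly_kernel([1, 2], [3, 4], params) == pytest.approx(0.5 * 11)

    @given(a=vectors, b=vectors)
    def test_symmetry(self, a, b):
        params = KernelParams(0.3, 1.0, 3)
        assert poly_kernel(a, b, params) == pytest.approx(poly_kernel(b, a, params))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            KernelParams(0.0)
        with pytest.raises(ValueError):
            KernelParams(1.0, degree=0)


class TestSVM:
    def test_two_separated_points_linear_kernel(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([0, 1])
        model = svm_fit(X, y, C=5.0, params=KernelParams(1.0, 0.0, 1), standardize=False)
        assert np.array_equal(svm_predict(model, X), y)
        for machine in model.machines:
            assert machine.support_vectors.shape[0] == 2

    def test_xor_separable_with_degree_two_kernel(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([0, 0, 1, 1])
        model = svm_fit(X, y, C=10.0, params=KernelParams(1.0, 1.0, 2), standardize=False)
        assert np.array_equal(svm_predict(model, X), y)

    def test_conflicting_duplicates_do_not_crash(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([0, 1, 0, 1])  # two duplicated points, conflicting labels
        model = svm_fit(X, y, C=5.0, params=KernelParams(1.0, 1.0, 2), standardize=False)
        accuracy = np.mean(svm_predict(model, X) == y)
        assert accuracy <= 0.75

    def test_dual_feasibility_at_convergence(self, rng):
        X = np.vstack([rng.normal(0, 1, (20, 2)), rng.normal(4, 1, (20, 2))])
        y = np.repeat([0, 1], 20)
        C = 14.5
        model = svm_fit(X, y, C=C)
        for machine in model.machines:
            alphas = np.abs(machine.dual_coef)
            assert np.all(alphas >= -1e-6) and np.all(alphas <= C + 1e-6)
            assert abs(machine.dual_coef.sum()) < 1e-6  # sum alpha_i y_i = 0

    def test_matches_sklearn_on_separable_blobs(self, rng):
        svm_mod = pytest.importorskip("sklearn.svm")
        X = np.vstack([rng.normal(0, 0.5, (25, 2)), rng.normal(5, 0.5, (25, 2))])
        y = np.repeat([0, 1], 25)
        q = np.vstack([rng.normal(0, 0.5, (10, 2)), rng.normal(5, 0.5, (10, 2))])
        truth = np.repeat([0, 1], 10)
        mine = svm_fit(X, y, C=14.5, params=KernelParams(0.5, 1.0, 3), standardize=False)
        ref = svm_mod.SVC(C=14.5, kernel="poly", degree=3, gamma=0.5, coef0=1.0).fit(X, y)
        assert np.array_equal(svm_predict(mine, q), truth)
        assert np.array_equal(ref.predict(q), truth)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            svm_fit(np.zeros((3, 2)), np.zeros(3, dtype=int))

    def test_decision_values_have_one_column_per_class(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.integers(0, 3, 30)
        model = svm_fit(X, y)
        assert svm_decision(model, rng.normal(size=(7, 3))).shape == (7, 3)


class TestGini:
    @pytest.mark.parametrize(
        "proportions,expected",
        [([1.0], 0.0), ([0.5, 0.5], 0.5), ([0.2] * 5, 0.8)],
    )
    def test_closed_forms(self, proportions, expected):
        assert gini(proportions) == pytest.approx(expected)

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            gini([0.5, 0.6])
        with pytest.raises(ValueError):
            gini([-0.1, 1.1])


def exhaustive_best_split(X, y, n_classes):
    """Independent oracle: try every feature and every midpoint threshold."""
    n = len(y)
    best = None
    for f in range(X.shape[1]):
        values = np.unique(X[:, f])
        for lo, hi in zip(values, values[1:]):
            thr = (lo + hi) / 2
            left, right = y[X[:, f] <= thr], y[X[:, f] > thr]
            impurity = 0.0
            for side in (left, right):
                p = np.bincount(side, minlength=n_classes) / len(side)
                impurity += len(side) / n * (1 - np.sum(p**2))
            cand = (impurity, f, thr)
            if best is None or cand[0] < best[0] - 1e-15:
                best = cand
    return best


class TestDecisionTree:
    def test_single_class_training_set(self):
        model = dt_fit(np.arange(6.0).reshape(-1, 1), np.full(6, 3))
        assert model.n_nodes == 1
        assert dt_predict(model, [[0.0], [100.0]]).tolist() == [3, 3]

    def test_one_dimensional_split_interval(self):
        X = np.array([[1.0], [2.0], [8.0], [9.0]])
        y = np.array([0, 0, 1, 1])
        model = dt_fit(X, y)
        root = model.nodes[0]
        assert 2.0 < root["threshold"] < 8.0
        assert np.array_equal(dt_predict(model, X), y)

    def test_root_split_matches_exhaustive_oracle(self, rng):
        for _ in range(20):
            X = rng.normal(size=(30, 3)).round(2)
            y = rng.integers(0, 3, 30)
            model = dt_fit(X, y, max_nodes=3)
            if "feature" not in model.nodes[0]:
                continue  # no improving split existed
            _, f, thr = exhaustive_best_split(X, y, 3)
            assert model.nodes[0]["feature"] == f
            assert model.nodes[0]["threshold"] == pytest.approx(thr)

    def test_node_budget_enforced(self, rng):
        X = rng.normal(size=(200, 5))
        y = rng.integers(0, 5, 200)
        model = dt_fit(X, y, max_nodes=10)
        assert model.n_nodes <= 10

    def test_matches_sklearn_accuracy_on_toy_problem(self, rng):
        tree_mod = pytest.importorskip("sklearn.tree")
        X = np.vstack([rng.normal(c * 3, 0.4, (20, 2)) for c in range(3)])
        y = np.repeat([0, 1, 2], 20)
        mine = dt_fit(X, y, max_nodes=10)
        ref = tree_mod.DecisionTreeClassifier(max_leaf_nodes=5, random_state=0).fit(X, y)
        assert np.mean(dt_predict(mine, X) == y) == pytest.approx(
            np.mean(ref.predict(X) == y)
        )

    def test_leaf_proportions_sum_to_one(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.integers(0, 4, 50)
        model = dt_fit(X, y)
        proba = dt_proba(model, rng.normal(size=(10, 3)))
        assert proba.shape == (10, 4)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_non_finite_features_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            dt_fit(np.array([[np.nan], [1.0]]), np.array([0, 1]))


class TestSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path, rng):
        X = rng.normal(size=(40, 4))
        y = rng.integers(0, 3, 40)
        q = rng.normal(size=(15, 4))
        models = {
            "knn": knn_fit(X, y, k=3),
            "svm": svm_fit(X, y),
            "dt": dt_fit(X, y),
        }
        predictors = {
            "knn": knn_predict,
            "svm": svm_predict,
            "dt": dt_predict,
        }
        for name, model in models.items():
            path = tmp_path / f"{name}.json"
            save_model(model, path)
            loaded = load_model(path)
            assert np.array_equal(
                predictors[name](model, q), predictors[name](loaded, q)
            )
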