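import numpy as np
import pytest
from scipy.stats import multivariate_normal, ortho_group

from ifcstate import (
    ClassifierSpec,
    FeatureTable,
    gaussian_kernel,
    kmeans_landmarks,
    linear_svm_objective,
    load_model,
    nystrom_map,
    predict,
    predict_discriminant,
    predict_knn,
    predict_llsvm,
    save_model,
    train_classifier,
    train_knn,
    train_lda,
    train_linear_svm,
    train_llsvm,
    train_qda,
)
from ifcstate.classifiers import _kernel_matrix


def two_gaussians(rng, m_per_class=100, shift=(2.0, 0.0), d=2):
    X = np.vstack(
        [
            rng.standard_normal((m_per_class, d)),
            rng.standard_normal((m_per_class, d)) + np.asarray(shift),
        ]
    )
    y = np.array(["neg"] * m_per_class + ["pos"] * m_per_class, dtype=object)
    return X, y


# ---------------------------------------------------------------------------
# discriminant analysis
# ---------------------------------------------------------------------------


class TestLda:
    def test_symmetric_1d_threshold_at_zero(self, rng):
        X = np.concatenate([rng.normal(-1, 1, 200), rng.normal(1, 1, 200)])[:, None]
        y = np.array(["lo"] * 200 + ["hi"] * 200, dtype=object)
        model = train_lda(X, y)
        labels, _ = predict_discriminant(model, np.array([[0.1]]))
        assert labels[0] == "hi"

    def test_posteriors_match_density_oracle(self, rng):
        X, y = two_gaussians(rng)
        model = train_lda(X, y)
        query = rng.standard_normal((20, 2)) + 1.0
        _, post = predict_discriminant(model, query)
        # naive Bayes-ratio oracle from the fitted Gaussian densities
        dens = np.column_stack(
            [
                multivariate_normal(
                    model.params["means"][k], model.params["covariance"]
                ).pdf(query)
                for k in range(2)
            ]
        )
        oracle = dens / dens.sum(axis=1, keepdims=True)  # equal priors
        np.testing.assert_allclose(post, oracle, atol=1e-9)

    def test_duplicating_samples_leaves_predictions_unchanged(self, rng):
        X, y = two_gaussians(rng, 30)
        query = rng.standard_normal((50, 2))
        base = predict_discriminant(train_lda(X, y), query)[0]
        doubled = predict_discriminant(
            train_lda(np.vstack([X, X]), np.concatenate([y, y])), query
        )[0]
        np.testing.assert_array_equal(base, doubled)

    def test_boundary_is_perpendicular_bisector(self, rng):
        # symmetric spherical classes: sign(label) must equal the bisector side
        mu = np.array([1.5, -0.5])
        X = np.vstack(
            [rng.standard_normal((500, 2)) - mu, rng.standard_normal((500, 2)) + mu]
        )
        y = np.array(["a"] * 500 + ["b"] * 500, dtype=object)
        model = train_lda(X, y)
        grid = rng.uniform(-4, 4, (2000, 2))
        labels, _ = predict_discriminant(model, grid)
        # fitted bisector: between the *estimated* class means
        mids = model.params["means"].mean(axis=0)
        normal = model.params["means"][1] - model.params["means"][0]
        side = (grid - mids) @ np.linalg.solve(model.params["covariance"], normal)
        clear = np.abs(side) > 1e-9
        np.testing.assert_array_equal(
            labels[clear], np.where(side[clear] > 0, "b", "a")
        )

    def test_class_below_two_samples_rejected(self):
        with pytest.raises(ValueError):
            train_lda(np.zeros((3, 1)), np.array(["a", "a", "b"], dtype=object))


class TestQda:
    def test_equal_covariances_reduce_to_lda(self, rng):
        # mirrored samples give numerically identical per-class covariances
        base = rng.standard_normal((100, 2))
        X = np.vstack([base, base + [3.0, 1.0]])
        y = np.array(["a"] * 100 + ["b"] * 100, dtype=object)
        grid = rng.uniform(-3, 6, (500, 2))
        lda_labels, _ = predict_discriminant(train_lda(X, y), grid)
        qda_labels, _ = predict_discriminant(train_qda(X, y), grid)
        np.testing.assert_array_equal(lda_labels, qda_labels)

    def test_unequal_variance_thresholds_match_quadratic_root(self):
        # exact sample moments: class A ~ (0,1), class B ~ (0,9);
        # equal-prior boundary solves exp(-x^2/2) = (1/3) exp(-x^2/18)
        a = np.sqrt(0.5) * np.array([-1.0, 1.0])
        b = np.sqrt(4.5) * np.array([-1.0, 1.0])
        X = np.concatenate([a, b])[:, None]
        y = np.array(["narrow", "narrow", "wide", "wide"], dtype=object)
        model = train_qda(X, y)
        root = np.sqrt(np.log(3.0) * 18.0 / 8.0)
        eps = 1e-6
        for x, expected in [
            (root - eps, "narrow"),
            (root + eps, "wide"),
            (-root + eps, "narrow"),
            (-root - eps, "wide"),
        ]:
            labels, _ = predict_discriminant(model, np.array([[x]]))
            assert labels[0] == expected

    def test_nonseparable_pattern_better_than_lda(self, rng):
        # class A split at +-3, class B at 0: equal means, different spread
        xa = np.concatenate([rng.normal(-3, 0.5, 100), rng.normal(3, 0.5, 100)])
        xb = rng.normal(0, 0.5, 200)
        X = np.concatenate([xa, xb])[:, None]
        y = np.array(["A"] * 200 + ["B"] * 200, dtype=object)
        acc = {}
        for name, train in [("lda", train_lda), ("qda", train_qda)]:
            labels, _ = predict_discriminant(train(X, y), X)
            acc[name] = np.mean(labels == y)
        assert acc["qda"] > acc["lda"]


class TestPredictDiscriminant:
    def test_midpoint_posterior_half(self, rng):
        X, y = two_gaussians(rng, 200, shift=(2.0, 0.0))
        model = train_lda(X, y)
        mid = model.params["means"].mean(axis=0)
        _, post = predict_discriminant(model, mid[None, :])
        np.testing.assert_allclose(post[0], [0.5, 0.5], atol=1e-9)

    def test_posterior_rows_sum_to_one(self, rng):
        X, y = two_gaussians(rng)
        _, post = predict_discriminant(train_qda(X, y), rng.standard_normal((30, 2)))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_feature_count_mismatch(self, rng):
        X, y = two_gaussians(rng)
        with pytest.raises(ValueError):
            predict_discriminant(train_lda(X, y), np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# k-nearest neighbors
# ---------------------------------------------------------------------------


class TestKnn:
    def test_k1_training_row_maps_to_own_label(self, rng):
        X, y = two_gaussians(rng, 20)
        model = train_knn(X, y, k=1)
        np.testing.assert_array_equal(predict_knn(model, X), y)

    def test_k_equals_m_predicts_global_majority(self, rng):
        X = rng.standard_normal((30, 2))
        y = np.array(["maj"] * 20 + ["min"] * 10, dtype=object)
        model = train_knn(X, y, k=30)
        assert set(predict_knn(model, rng.standard_normal((40, 2)))) == {"maj"}

    @pytest.mark.parametrize("k", [1, 5, 21])
    def test_matches_reference_implementation(self, rng, k):
        # continuous data -> no distance ties; odd k, 2 classes -> no vote ties
        from sklearn.neighbors import KNeighborsClassifier

        X, y = two_gaussians(rng, 100, shift=(1.0, 1.0))
        query = rng.standard_normal((200, 2))
        ours = predict_knn(train_knn(X, y, k), query)
        ref = KNeighborsClassifier(n_neighbors=k).fit(X, y.astype(str)).predict(query)
        np.testing.assert_array_equal(ours.astype(str), ref)

    def test_rotation_invariance(self, rng):
        X, y = two_gaussians(rng, 50)
        query = rng.standard_normal((80, 2))
        R = ortho_group.rvs(2, random_state=7)
        base = predict_knn(train_knn(X, y, 5), query)
        rotated = predict_knn(train_knn(X @ R, y, 5), query @ R)
        np.testing.assert_array_equal(base, rotated)

    def test_k_out_of_range(self, rng):
        X, y = two_gaussians(rng, 5)
        with pytest.raises(ValueError):
            train_knn(X, y, k=11)


# ---------------------------------------------------------------------------
# LLSVM building blocks
# ---------------------------------------------------------------------------


class TestGaussianKernel:
    def test_identity_and_symmetry(self, rng):
        u, v = rng.standard_normal(3), rng.standard_normal(3)
        assert gaussian_kernel(u, u, 0.7) == 1.0
        assert gaussian_kernel(u, v, 0.7) == gaussian_kernel(v, u, 0.7)

    def test_known_value(self):
        # gamma=0.5, squared distance 2 -> exp(-1)
        assert gaussian_kernel([0.0, 0.0], [1.0, 1.0], 0.5) == pytest.approx(
            np.exp(-1.0)
        )


class TestKmeansLandmarks:
    def test_p_equals_m_returns_training_points(self, rng):
        X = rng.standard_normal((12, 2))
        landmarks = kmeans_landmarks(X, 12, seed=0)
        assert {tuple(r) for r in landmarks} == {tuple(r) for r in X}

    def test_two_blobs_one_landmark_each(self, rng):
        X = np.vstack(
            [rng.standard_normal((50, 2)), rng.standard_normal((50, 2)) + 20.0]
        )
        landmarks = kmeans_landmarks(X, 2, seed=1)
        dist_to_blobs = np.abs(landmarks.mean(axis=1)[:, None] - np.array([0.0, 20.0]))
        assert sorted(np.argmin(dist_to_blobs, axis=1)) == [0, 1]

    def test_deterministic(self, rng):
        X = rng.standard_normal((40, 3))
        np.testing.assert_array_equal(
            kmeans_landmarks(X, 5, seed=9), kmeans_landmarks(X, 5, seed=9)
        )


class TestNystromMap:
    def test_full_rank_reproduces_kernel_matrix(self, rng):
        X = rng.standard_normal((50, 4))
        Z = nystrom_map(X, X, gamma=0.3)
        K = _kernel_matrix(X, X, 0.3)
        np.testing.assert_allclose(Z @ Z.T, K, atol=1e-8)

    def test_three_point_hand_check(self):
        L = np.array([[0.0], [1.0], [3.0]])
        Z = nystrom_map(L, L, gamma=0.25)
        K = np.exp(-0.25 * (L - L.T) ** 2)
        np.testing.assert_allclose(Z @ Z.T, K, atol=1e-10)

    def test_mapped_dimension_bounded_by_landmark_count(self, rng):
        X = rng.standard_normal((30, 3))
        landmarks = X[:7]
        assert nystrom_map(X, landmarks, 0.5).shape[1] <= 7


class TestLinearSvm:
    def test_two_point_hard_margin(self):
        w, b = train_linear_svm(np.array([[-1.0], [1.0]]), np.array([-1.0, 1.0]), 100.0)
        assert w[0] == pytest.approx(1.0, abs=1e-8)
        assert b == pytest.approx(0.0, abs=1e-8)

    def test_label_negation_negates_solution(self, rng):
        Z = np.vstack(
            [rng.standard_normal((10, 3)), rng.standard_normal((10, 3)) + 1.0]
        )
        y = np.array([-1.0] * 10 + [1.0] * 10)
        w1, b1 = train_linear_svm(Z, y, 1.0)
        w2, b2 = train_linear_svm(Z, -y, 1.0)
        np.testing.assert_allclose(w2, -w1, atol=1e-6)
        assert b2 == pytest.approx(-b1, abs=1e-6)

    def test_objective_within_tolerance_of_reference_solver(self, rng):
        from sklearn.svm import SVC

        Z = np.vstack(
            [rng.standard_normal((10, 2)), rng.standard_normal((10, 2)) + 2.5]
        )
        y = np.array([-1.0] * 10 + [1.0] * 10)
        for C in (0.1, 1.0, 10.0):
            w, b = train_linear_svm(Z, y, C)
            ref = SVC(C=C, kernel="linear").fit(Z, y)
            obj = linear_svm_objective(Z, y, w, b, C)
            obj_ref = linear_svm_objective(
                Z, y, ref.coef_.ravel(), ref.intercept_[0], C
            )
            assert obj <= obj_ref * (1 + 1e-4)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_linear_svm(np.zeros((3, 1)), np.ones(3), 1.0)


class TestLlsvm:
    def test_concentric_pattern_beats_linear_classifier(self, rng):
        # inner cluster vs surrounding ring: not linearly separable
        inner = rng.standard_normal((100, 2)) * 0.5
        angle = rng.uniform(0, 2 * np.pi, 100)
        ring = np.column_stack([np.cos(angle), np.sin(angle)]) * 4.0
        ring += rng.standard_normal((100, 2)) * 0.3
        X = np.vstack([inner, ring])
        y = np.array(["in"] * 100 + ["out"] * 100, dtype=object)
        svm = train_llsvm(X, y, C=10.0, gamma=0.5, p=50, seed=0)
        svm_acc = np.mean(predict_llsvm(svm, X) == y)
        lda_acc = np.mean(predict_discriminant(train_lda(X, y), X)[0] == y)
        assert svm_acc > lda_acc and svm_acc > 0.95

    def test_deterministic_per_seed(self, rng):
        X, y = two_gaussians(rng, 40)
        query = rng.standard_normal((50, 2))
        m1 = train_llsvm(X, y, 1.0, 0.5, p=10, seed=3)
        m2 = train_llsvm(X, y, 1.0, 0.5, p=10, seed=3)
        np.testing.assert_array_equal(
            predict_llsvm(m1, query), predict_llsvm(m2, query)
        )

    def test_objective_non_increasing_in_landmark_count(self, rng):
        X, y = two_gaussians(rng, 25, shift=(1.5, 0.5))
        y_pm = np.where(y == "neg", -1.0, 1.0)
        objs = []
        for p in (2, 5, 50):
            model = train_llsvm(X, y, C=1.0, gamma=0.5, p=p, seed=0)
            Z = nystrom_map(X, model.params["landmarks"], 0.5)
            objs.append(
                linear_svm_objective(
                    Z, y_pm, model.params["w"], model.params["b"], 1.0
                )
            )
        assert objs[2] <= objs[1] + 1e-6 <= objs[0] + 2e-6

    def test_multiclass_rejected(self):
        X = np.zeros((6, 1))
        y = np.array(["a", "a", "b", "b", "c", "c"], dtype=object)
        with pytest.raises(ValueError, match="binary"):
            train_llsvm(X, y, 1.0, 1.0, p=3)


# ---------------------------------------------------------------------------
# dispatch, scaling integration, serialization
# ---------------------------------------------------------------------------


class TestPredictDispatch:
    @pytest.mark.parametrize("method", ["LDA", "QDA", "KNN", "LLSVM"])
    def test_row_permutation_permutes_outputs(self, separable_population, method):
        table = separable_population
        spec = ClassifierSpec(method=method, k=5, C=1.0, gamma=0.1, landmarks=20)
        model = train_classifier(table.values, table.labels, spec,
                                 list(table.class_names))
        perm = np.random.default_rng(5).permutation(table.m)
        base = predict(model, table)
        permuted = predict(model, table.take_rows(perm))
        np.testing.assert_array_equal(base[perm], permuted)

    @pytest.mark.parametrize("method", ["LDA", "QDA", "KNN", "LLSVM"])
    def test_serialization_round_trip_identical_predictions(
        self, tmp_path, separable_population, method
    ):
        table = separable_population
        spec = ClassifierSpec(method=method, k=3, C=2.0, gamma=0.2, landmarks=15)
        model = train_classifier(table.values, table.labels, spec,
                                 list(table.class_names))
        path = str(tmp_path / "model.json")
        save_model(model, path)
        reloaded = load_model(path)
        np.testing.assert_array_equal(
            predict(model, table), predict(reloaded, table)
        )

    def test_schema_mismatch_rejected(self, separable_population):
        from ifcstate import fit_scaler

        table = separable_population
        model = train_classifier(
            table.values, table.labels, ClassifierSpec("LDA"),
            list(table.class_names)
        )
        model.scaler = fit_scaler(table)
        wrong = FeatureTable(
            table.values[:, :-1], table.feature_names[:-1]
        )
        with pytest.raises(ValueError, match="schema|feature"):
            predict(model, wrong)
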