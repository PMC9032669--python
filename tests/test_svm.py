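"""Soft-margin SVM: dual feasibility, KKT conditions, margin optimality."""

import numpy as np
import pytest

from weedvision.svm import BinarySVM, MulticlassSVM


def three_clusters(n=30, seed=0, spread=0.35):
    """Well-separated 2-D Gaussian clusters, one per class."""
    rng = np.random.default_rng(seed)
    centers = {"Crop": (0.0, 0.0), "NLW": (4.0, 0.0), "BLW": (2.0, 3.5)}
    X, y = [], []
    for cls, (cx, cy) in centers.items():
        X.append(rng.normal((cx, cy), spread, size=(n, 2)))
        y += [cls] * n
    return np.vstack(X), np.asarray(y)


def grid_margin(X, t, n_angles=720):
    """Brute-force primal oracle: best margin over unit-normal directions.

    For each direction the optimal bias centres the slab between the
    extreme projections of the two classes, so the search is exact up to
    the angular resolution.
    """
    best = -np.inf
    for theta in np.linspace(0, np.pi, n_angles, endpoint=False):
        w = np.array([np.cos(theta), np.sin(theta)])
        proj = X @ w
        for sign in (1, -1):
            lo = np.min(sign * proj[t == 1])
            hi = np.max(sign * proj[t == -1])
            best = max(best, (lo - hi) / 2)
    return best


class TestBinary:
    def test_symmetric_two_point_problem(self):
        X = np.array([[-1.0], [1.0]])
        t = np.array([-1.0, 1.0])
        model = BinarySVM(C=1e6).fit(X, t)
        assert abs(model.b) < 1e-9
        assert abs(model.decision_function([[0.0]])[0]) < 1e-9
        assert (model.predict(X) == t).all()

    def test_margin_matches_primal_grid_oracle(self):
        rng = np.random.default_rng(7)
        X = np.vstack([
            rng.normal((-2.0, 0.0), 0.4, size=(10, 2)),
            rng.normal((2.0, 0.5), 0.4, size=(10, 2)),
        ])
        t = np.r_[-np.ones(10), np.ones(10)]
        model = BinarySVM(C=1e4).fit(X, t)
        assert (model.predict(X) == t).all()
        geo_margin = 1.0 / np.linalg.norm(model.w)
        oracle = grid_margin(X, t)
        assert geo_margin >= oracle * 0.999  # dual optimum beats the coarse grid
        assert geo_margin <= oracle * 1.01  # and cannot exceed the true optimum

    def test_dual_feasibility_and_kkt(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(40, 3))
        t = np.where(X[:, 0] + 0.3 * rng.normal(size=40) > 0, 1.0, -1.0)
        if len(np.unique(t)) < 2:  # pragma: no cover
            t[0] = -t[0]
        model = BinarySVM(C=5.0).fit(X, t)
        a = model.alpha_full
        assert abs(a @ model.targets_full) < 1e-6
        assert (a >= -1e-12).all() and (a <= 5.0 + 1e-9).all()
        # margin support vectors satisfy t·y(x) = 1
        margin = (a > 1e-6) & (a < 5.0 - 1e-6)
        if margin.any():
            y = model.decision_function(X[margin])
            np.testing.assert_allclose(t[margin] * y, 1.0, atol=1e-3)

    def test_explicit_weights_identity(self):
        """For the linear kernel, y(x) = w·x + b with w = Σ a_i t_i x_i."""
        rng = np.random.default_rng(13)
        X = rng.normal(size=(30, 4))
        t = np.where(X[:, 1] > 0.2, 1.0, -1.0)
        model = BinarySVM(C=5.0).fit(X, t)
        w = (model.alpha * model.support_targets) @ model.support_vectors
        np.testing.assert_allclose(model.w, w, atol=1e-12)
        probe = rng.normal(size=(5, 4))
        np.testing.assert_allclose(
            model.decision_function(probe), probe @ model.w + model.b, atol=1e-9
        )

    def test_matches_sklearn_reference(self):
        """Independent cross-check of the dual solver against scikit-learn."""
        from sklearn.svm import SVC

        rng = np.random.default_rng(17)
        X = np.vstack([
            rng.normal((-1.5, 0.0), 0.5, size=(15, 2)),
            rng.normal((1.5, 0.3), 0.5, size=(15, 2)),
        ])
        t = np.r_[-np.ones(15), np.ones(15)]
        mine = BinarySVM(C=5.0).fit(X, t)
        ref = SVC(C=5.0, kernel="linear").fit(X, t)
        np.testing.assert_allclose(mine.w, ref.coef_[0], atol=1e-2)
        np.testing.assert_allclose(mine.b, ref.intercept_[0], atol=1e-2)

    def test_larger_c_never_hurts_separable_training_accuracy(self):
        rng = np.random.default_rng(19)
        X = np.vstack([
            rng.normal((-2.0, 0.0), 0.5, size=(12, 2)),
            rng.normal((2.0, 0.0), 0.5, size=(12, 2)),
        ])
        t = np.r_[-np.ones(12), np.ones(12)]
        accs = [
            np.mean(BinarySVM(C=c).fit(X, t).predict(X) == t)
            for c in (0.1, 1.0, 5.0, 100.0)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(accs, accs[1:]))
        assert accs[-1] == 1.0

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            BinarySVM().fit(np.ones((3, 2)), np.ones(3))  # single class
        with pytest.raises(ValueError):
            BinarySVM().fit(np.array([[np.nan, 0], [1, 1]]), np.array([-1.0, 1.0]))
        with pytest.raises(ValueError):
            BinarySVM(C=-1.0).fit(np.eye(2), np.array([-1.0, 1.0]))

    def test_dimension_mismatch(self):
        model = BinarySVM().fit(np.array([[-1.0], [1.0]]), np.array([-1.0, 1.0]))
        with pytest.raises(ValueError):
            model.decision_function(np.ones((2, 3)))


class TestMulticlass:
    def test_holdout_accuracy_on_separable_clusters(self):
        X, y = three_clusters(n=30, seed=23)
        rng = np.random.default_rng(23)
        idx = rng.permutation(len(y))
        train, test = idx[:60], idx[60:]
        model = MulticlassSVM(C=5.0).fit(X[train], y[train])
        assert np.mean(model.predict(X[test]) == y[test]) >= 0.95

    def test_centroids_classified_as_their_cluster(self):
        X, y = three_clusters(n=20, seed=29)
        model = MulticlassSVM(C=5.0).fit(X, y)
        for cls in ("Crop", "NLW", "BLW"):
            centroid = X[y == cls].mean(axis=0)
            assert model.predict([centroid])[0] == cls

    def test_class_permutation_symmetry(self):
        X, y = three_clusters(n=15, seed=31)
        perm = {"Crop": "NLW", "NLW": "BLW", "BLW": "Crop"}
        base = MulticlassSVM(C=5.0).fit(X, y)
        swapped = MulticlassSVM(C=5.0).fit(X, np.array([perm[c] for c in y]))
        probe = X[::3]
        expected = np.array([perm[c] for c in base.predict(probe)])
        np.testing.assert_array_equal(swapped.predict(probe), expected)

    def test_deterministic_refits_and_batch_equals_single(self):
        X, y = three_clusters(n=12, seed=37)
        m1 = MulticlassSVM(C=5.0).fit(X, y)
        m2 = MulticlassSVM(C=5.0).fit(X, y)
        probe = X[::4]
        np.testing.assert_array_equal(m1.predict(probe), m2.predict(probe))
        singles = [m1.predict(p[None, :])[0] for p in probe]
        np.testing.assert_array_equal(m1.predict(probe), singles)

    def test_requires_two_classes(self):
        with pytest.raises(ValueError):
            MulticlassSVM().fit(np.ones((4, 2)), ["Crop"] * 4)

    def test_save_load_roundtrip(self, tmp_path):
        X, y = three_clusters(n=10, seed=41)
        model = MulticlassSVM(C=5.0)
        model.feature_fingerprint = "lbp8_1-img64-cell32-l1"
        model.fit(X, y)
        path = tmp_path / "svm.joblib"
        model.save(path)
        loaded = MulticlassSVM.load(path)
        assert loaded.feature_fingerprint == model.feature_fingerprint
        np.testing.assert_array_equal(loaded.predict(X), model.predict(X))
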