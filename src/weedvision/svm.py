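"""Soft-margin SVM trained in the dual, with a one-vs-one 3-class wrapper.

The binary classifier is the maximum-margin model y(x) = w·x + b, fitted by
maximising the dual

    L~(a) = sum_i a_i - 1/2 sum_ij a_i a_j t_i t_j K(x_i, x_j)

subject to 0 <= a_i <= C and sum_i a_i t_i = 0, with targets t_i in {-1,+1}.
The box upper bound C is the soft-margin penalty (the study's tuned value is
C = 5 with a linear kernel).  The solver is a deterministic sequential
minimal optimisation (SMO): Lagrange multipliers are updated two at a time —
each pairwise update preserves sum a_i t_i = 0 exactly — until no multiplier
violates the KKT conditions beyond ``tol``.  For the linear kernel the
explicit weight vector w = sum_i a_i t_i x_i is stored as well.

Multiclass is one-vs-one: one binary model per unordered class pair,
prediction by majority vote, ties broken by the largest sum of winning
decision magnitudes, then by class order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np

__all__ = ["BinarySVM", "MulticlassSVM", "linear_kernel", "rbf_kernel"]


def linear_kernel(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return A @ B.T


def rbf_kernel(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    sq = (
        np.sum(A**2, axis=1)[:, None]
        + np.sum(B**2, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    return np.exp(-gamma * np.maximum(sq, 0.0))


@dataclass
class BinarySVM:
    """Two-class soft-margin SVM solved by SMO.

    Parameters
    ----------
    C : box constraint on the dual multipliers (default 5, the tuned value).
    kernel : "linear" (default) or "rbf".
    gamma : RBF width; defaults to 1/n_features.
    tol : KKT violation tolerance for convergence.
    """

    C: float = 5.0
    kernel: str = "linear"
    gamma: float | None = None
    tol: float = 1e-4
    max_sweeps: int = 1000

    # fitted state
    alpha: np.ndarray = field(default=None, repr=False)
    support_vectors: np.ndarray = field(default=None, repr=False)
    support_targets: np.ndarray = field(default=None, repr=False)
    b: float = 0.0
    w: np.ndarray = field(default=None, repr=False)
    # full-training-set multipliers/targets, for feasibility checks
    alpha_full: np.ndarray = field(default=None, repr=False)
    targets_full: np.ndarray = field(default=None, repr=False)

    def _kernel(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        if self.kernel == "linear":
            return linear_kernel(A, B)
        if self.kernel == "rbf":
            gamma = self.gamma if self.gamma is not None else 1.0 / A.shape[1]
            return rbf_kernel(A, B, gamma)
        raise ValueError(f"unknown kernel {self.kernel!r}")

    def fit(self, X: np.ndarray, t: np.ndarray) -> "BinarySVM":
        X = np.asarray(X, dtype=np.float64)
        t = np.asarray(t, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] != t.shape[0]:
            raise ValueError("X must be (N, d) with one target per row")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        if not np.all(np.isin(t, (-1.0, 1.0))):
            raise ValueError("targets must be -1 or +1")
        if np.unique(t).size < 2:
            raise ValueError("both classes must be present")
        if self.C <= 0:
            raise ValueError("C must be positive")

        n = X.shape[0]
        K = self._kernel(X, X)
        alpha = np.zeros(n)
        b = 0.0
        # F_i = sum_j a_j t_j K(x_j, x_i); decision = F + b; error E = F + b - t
        F = np.zeros(n)

        def take_step(i1: int, i2: int) -> bool:
            nonlocal b, F
            if i1 == i2:
                return False
            a1, a2 = alpha[i1], alpha[i2]
            t1, t2 = t[i1], t[i2]
            E1 = F[i1] + b - t1
            E2 = F[i2] + b - t2
            s = t1 * t2
            if s > 0:
                L, H = max(0.0, a1 + a2 - self.C), min(self.C, a1 + a2)
            else:
                L, H = max(0.0, a2 - a1), min(self.C, self.C + a2 - a1)
            if L >= H:
                return False
            eta = K[i1, i1] + K[i2, i2] - 2.0 * K[i1, i2]
            if eta <= 0:
                return False  # degenerate pair (duplicate/collinear points)
            a2_new = np.clip(a2 + t2 * (E1 - E2) / eta, L, H)
            if abs(a2_new - a2) < 1e-12 * (a2_new + a2 + 1e-12):
                return False
            a1_new = a1 + s * (a2 - a2_new)
            d1, d2 = a1_new - a1, a2_new - a2
            # bias update (Platt's b1/b2 rule)
            b1 = b - E1 - t1 * d1 * K[i1, i1] - t2 * d2 * K[i1, i2]
            b2 = b - E2 - t1 * d1 * K[i1, i2] - t2 * d2 * K[i2, i2]
            if 0.0 < a1_new < self.C:
                b = b1
            elif 0.0 < a2_new < self.C:
                b = b2
            else:
                b = 0.5 * (b1 + b2)
            F += t1 * d1 * K[i1] + t2 * d2 * K[i2]
            alpha[i1], alpha[i2] = a1_new, a2_new
            return True

        def examine(i2: int) -> int:
            t2, a2 = t[i2], alpha[i2]
            E2 = F[i2] + b - t2
            r2 = E2 * t2
            if not ((r2 < -self.tol and a2 < self.C) or (r2 > self.tol and a2 > 0)):
                return 0
            non_bound = np.flatnonzero((alpha > 0) & (alpha < self.C))
            if non_bound.size > 1:
                E = F + b - t
                i1 = non_bound[int(np.argmax(np.abs(E[non_bound] - E2)))]
                if take_step(int(i1), i2):
                    return 1
            for i1 in non_bound:
                if take_step(int(i1), i2):
                    return 1
            for i1 in range(n):
                if take_step(i1, i2):
                    return 1
            return 0

        examine_all = True
        for _ in range(self.max_sweeps):
            changed = 0
            candidates = (
                range(n)
                if examine_all
                else np.flatnonzero((alpha > 0) & (alpha < self.C))
            )
            for i in candidates:
                changed += examine(int(i))
            if examine_all:
                examine_all = False
                if changed == 0:
                    break
            elif changed == 0:
                examine_all = True

        # refine b as the average over margin support vectors
        margin = (alpha > 1e-8) & (alpha < self.C - 1e-8)
        if np.any(margin):
            b = float(np.mean(t[margin] - F[margin]))

        sv = alpha > 1e-10
        self.alpha_full = alpha
        self.targets_full = t
        self.alpha = alpha[sv]
        self.support_vectors = X[sv]
        self.support_targets = t[sv]
        self.b = float(b)
        if self.kernel == "linear":
            self.w = (self.alpha * self.support_targets) @ self.support_vectors
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """y(x) = sum_i a_i t_i K(x_i, x) + b; the sign is the class."""
        if self.support_vectors is None:
            raise RuntimeError("model is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.support_vectors.shape[1]:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match model "
                f"({self.support_vectors.shape[1]})"
            )
        Kx = self._kernel(X, self.support_vectors)
        return Kx @ (self.alpha * self.support_targets) + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, 1, -1)


@dataclass
class MulticlassSVM:
    """One-vs-one multiclass SVM (3 pairwise models for 3 classes).

    Decision rule: each pairwise model votes for the class on its positive
    or negative side; the class with most votes wins.  Vote ties go to the
    tied class with the largest sum of |decision value| over the pairs it
    won, then to the earliest class in ``classes_``.
    """

    C: float = 5.0
    kernel: str = "linear"
    gamma: float | None = None
    tol: float = 1e-4
    feature_fingerprint: str | None = None

    classes_: tuple = None
    models_: dict = field(default=None, repr=False)

    def fit(self, X: np.ndarray, y) -> "MulticlassSVM":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(list(y))
        classes = tuple(np.unique(y).tolist())
        if len(classes) < 2:
            raise ValueError("need at least 2 classes")
        self.classes_ = classes
        self.models_ = {}
        for i, ci in enumerate(classes):
            for cj in classes[i + 1 :]:
                sel = (y == ci) | (y == cj)
                t = np.where(y[sel] == ci, 1.0, -1.0)
                model = BinarySVM(
                    C=self.C, kernel=self.kernel, gamma=self.gamma, tol=self.tol
                ).fit(X[sel], t)
                self.models_[(ci, cj)] = model
        return self

    def decision_matrix(self, X: np.ndarray) -> dict:
        """Pairwise decision values, keyed by (positive_class, negative_class)."""
        if self.models_ is None:
            raise RuntimeError("model is not fitted")
        return {pair: m.decision_function(X) for pair, m in self.models_.items()}

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        decisions = self.decision_matrix(X)
        n = X.shape[0]
        k = len(self.classes_)
        votes = np.zeros((n, k), dtype=np.int64)
        magnitude = np.zeros((n, k))
        cindex = {c: i for i, c in enumerate(self.classes_)}
        for (ci, cj), vals in sorted(decisions.items(), key=lambda kv: str(kv[0])):
            winner = np.where(vals >= 0, cindex[ci], cindex[cj])
            for row in range(n):
                votes[row, winner[row]] += 1
                magnitude[row, winner[row]] += abs(vals[row])
        out = []
        for row in range(n):
            best = np.flatnonzero(votes[row] == votes[row].max())
            if best.size > 1:
                best = best[magnitude[row, best] == magnitude[row, best].max()]
            out.append(self.classes_[int(best[0])])
        return np.asarray(out)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "MulticlassSVM":
        model = joblib.load(path)
        if not isinstance(model, MulticlassSVM):
            raise TypeError(f"{path} does not contain a MulticlassSVM")
        return model
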