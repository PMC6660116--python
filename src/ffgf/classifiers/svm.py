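"""Linear soft-margin SVM with two trainers.

``trainer="smo"`` solves the dual by sequential minimal optimization
(pairwise coordinate ascent with a deterministic first-violator scan and a
max-|E1 - E2| second choice).  ``trainer="ls"`` solves the least-squares SVM
linear system, i.e. the margin constraints become equalities regularized by
1/C, which reduces training to one dense solve.
"""

from __future__ import annotations

import numpy as np

from ..data import LabeledDataset
from ..exceptions import ContractError, ConvergenceError

_TRAINERS = ("smo", "ls")


class LinearSVM:
    """Maximum-margin (or least-squares) linear separator.

    Parameters
    ----------
    trainer : {"smo", "ls"}
    C : float
        Soft-margin constant (box bound for SMO, inverse ridge for LS).
    tol : float
        KKT violation tolerance for SMO.
    """

    def __init__(self, trainer: str = "smo", C: float = 1.0, tol: float = 1e-3):
        trainer = trainer.lower()
        if trainer not in _TRAINERS:
            raise ContractError(f"trainer must be one of {_TRAINERS}, got {trainer!r}")
        if C <= 0:
            raise ContractError(f"C must be positive, got {C}")
        self.trainer = trainer
        self.C = float(C)
        self.tol = float(tol)
        self.w_: np.ndarray | None = None
        self.b_: float | None = None
        self.alpha_: np.ndarray | None = None
        self.support_: np.ndarray | None = None

    def fit(self, data: LabeledDataset) -> "LinearSVM":
        data.require_both_classes()
        if self.trainer == "smo":
            self._fit_smo(data)
        else:
            self._fit_ls(data)
        return self

    # -- SMO ---------------------------------------------------------------

    def _fit_smo(self, data: LabeledDataset) -> None:
        X, t = data.X, data.t.astype(float)
        n = data.n
        C, tol = self.C, self.tol
        K = X @ X.T
        alpha = np.zeros(n)
        self._b = 0.0
        eps = 1e-12

        def f(i: int) -> float:
            return float((alpha * t) @ K[:, i] + self._b)

        def take_step(i1: int, i2: int) -> bool:
            if i1 == i2:
                return False
            a1, a2 = alpha[i1], alpha[i2]
            t1, t2 = t[i1], t[i2]
            e1 = f(i1) - t1
            e2 = f(i2) - t2
            s = t1 * t2
            if s > 0:
                lo, hi = max(0.0, a1 + a2 - C), min(C, a1 + a2)
            else:
                lo, hi = max(0.0, a2 - a1), min(C, C + a2 - a1)
            if hi - lo < eps:
                return False
            eta = K[i1, i1] + K[i2, i2] - 2.0 * K[i1, i2]
            if eta > eps:
                a2_new = a2 + t2 * (e1 - e2) / eta
                a2_new = min(max(a2_new, lo), hi)
            else:
                # flat direction: pick the better bound of the dual objective
                def obj(a2_trial: float) -> float:
                    a1_trial = a1 + s * (a2 - a2_trial)
                    d1, d2 = a1_trial - a1, a2_trial - a2
                    return (
                        d1
                        + d2
                        - 0.5 * d1 * d1 * K[i1, i1]
                        - 0.5 * d2 * d2 * K[i2, i2]
                        - s * d1 * d2 * K[i1, i2]
                        - d1 * t1 * (f(i1) - self._b)
                        - d2 * t2 * (f(i2) - self._b)
                    )

                a2_new = lo if obj(lo) > obj(hi) + eps else hi
            if abs(a2_new - a2) < eps * (a2_new + a2 + eps):
                return False
            a1_new = a1 + s * (a2 - a2_new)
            # threshold update (Platt): keep KKT at the changed points
            b1 = self._b - e1 - t1 * (a1_new - a1) * K[i1, i1] - t2 * (a2_new - a2) * K[i1, i2]
            b2 = self._b - e2 - t1 * (a1_new - a1) * K[i1, i2] - t2 * (a2_new - a2) * K[i2, i2]
            if 0 < a1_new < C:
                self._b = b1
            elif 0 < a2_new < C:
                self._b = b2
            else:
                self._b = (b1 + b2) / 2.0
            alpha[i1], alpha[i2] = a1_new, a2_new
            return True

        def examine(i2: int) -> bool:
            t2 = t[i2]
            e2 = f(i2) - t2
            r2 = e2 * t2
            if (r2 < -tol and alpha[i2] < C) or (r2 > tol and alpha[i2] > 0):
                non_bound = np.flatnonzero((alpha > 0) & (alpha < C))
                if non_bound.size > 1:
                    errors = np.array([f(i) - t[i] for i in non_bound])
                    i1 = int(non_bound[np.argmax(np.abs(errors - e2))])
                    if take_step(i1, i2):
                        return True
                for i1 in non_bound:  # deterministic scan, ascending index
                    if take_step(int(i1), i2):
                        return True
                for i1 in range(n):
                    if take_step(i1, i2):
                        return True
            return False

        max_passes = 10 * n
        passes = 0
        examine_all = True
        while passes < max_passes:
            passes += 1
            changed = 0
            if examine_all:
                for i in range(n):
                    changed += examine(i)
            else:
                for i in np.flatnonzero((alpha > 0) & (alpha < C)):
                    changed += examine(int(i))
            if examine_all:
                if changed == 0:
                    break
                examine_all = False
            elif changed == 0:
                examine_all = True
        else:
            w = (alpha * t) @ X
            margins = t * (X @ w + self._b)
            primal = 0.5 * w @ w + C * np.sum(np.maximum(0.0, 1.0 - margins))
            dual = alpha.sum() - 0.5 * (alpha * t) @ K @ (alpha * t)
            raise ConvergenceError(
                f"SMO did not converge within {max_passes} passes",
                duality_gap=float(primal - dual),
            )

        self.alpha_ = alpha
        self.support_ = np.flatnonzero(alpha > eps)
        self.w_ = (alpha * t) @ X
        self.b_ = float(self._b)

    # -- least squares -----------------------------------------------------

    def _fit_ls(self, data: LabeledDataset) -> None:
        X, t = data.X, data.t.astype(float)
        n = data.n
        omega = (t[:, None] * t[None, :]) * (X @ X.T)
        A = np.zeros((n + 1, n + 1))
        A[0, 1:] = t
        A[1:, 0] = t
        A[1:, 1:] = omega + np.eye(n) / self.C
        rhs = np.concatenate([[0.0], np.ones(n)])
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(A, rhs, rcond=None)[0]
        self.b_ = float(sol[0])
        self.alpha_ = sol[1:]
        self.support_ = np.flatnonzero(np.abs(self.alpha_) > 1e-12)
        self.w_ = (self.alpha_ * t) @ X

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        if self.w_ is None:
            raise ContractError("classifier is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.w_ + self.b_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, 1, -1)


def svm_fit(
    data: LabeledDataset, trainer: str = "smo", C: float = 1.0, tol: float = 1e-3
) -> LinearSVM:
    return LinearSVM(trainer=trainer, C=C, tol=tol).fit(data)


def svm_predict(model: LinearSVM, x: np.ndarray) -> tuple[int, float]:
    score = float(model.decision_function(np.atleast_2d(x))[0])
    return (1 if score >= 0 else -1), score
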