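"""Linear discriminant fit by least squares.

The decision score is the affine function ``y(x) = w0 + w . x``.  The
weights minimize the sum of squared deviations of y(x_n) from the +/-1
targets; the minimizer is the Moore-Penrose pseudoinverse (computed by SVD,
so rank-deficient designs are handled) of the bias-augmented design matrix
applied to the target vector.
"""

from __future__ import annotations

import numpy as np

from ..data import LabeledDataset
from ..exceptions import ContractError


class LinearDiscriminant:
    def __init__(self):
        self.w0_: float | None = None
        self.w_: np.ndarray | None = None

    def fit(self, data: LabeledDataset) -> "LinearDiscriminant":
        data.require_both_classes()
        design = np.column_stack([np.ones(data.n), data.X])
        w_aug = np.linalg.pinv(design) @ data.t.astype(float)
        self.w0_ = float(w_aug[0])
        self.w_ = w_aug[1:]
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        if self.w_ is None:
            raise ContractError("classifier is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.w0_ + X @ self.w_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, 1, -1)


def ld_fit(data: LabeledDataset) -> LinearDiscriminant:
    return LinearDiscriminant().fit(data)


def ld_predict(model: LinearDiscriminant, x: np.ndarray) -> tuple[int, float]:
    score = float(model.decision_function(np.atleast_2d(x))[0])
    return (1 if score >= 0 else -1), score
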