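"""K-nearest-neighbors under the Minkowski metric.

The whole training set is retained; prediction is a majority vote among the
K closest training points.  Exposed metrics are city-block (p=1) and
Euclidean (p=2), but any p >= 1 works.
"""

from __future__ import annotations

import numpy as np

from ..data import LabeledDataset
from ..exceptions import ContractError


def minkowski_distance(a: np.ndarray, b: np.ndarray, p: float = 2.0) -> float:
    """``(sum_i |a_i - b_i|^p)^(1/p)``; p=1 city block, p=2 Euclidean."""
    if p < 1:
        raise ContractError(f"Minkowski exponent must be >= 1, got {p}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ContractError("vectors must have equal length")
    return float(np.sum(np.abs(a - b) ** p) ** (1.0 / p))


class KNNClassifier:
    """Majority-vote KNN.

    Distance ties resolve toward the lower training index; vote ties (even K)
    resolve toward +1.  The score is (votes for +1 - votes for -1) / K, in
    [-1, +1], usable for ROC analysis.
    """

    def __init__(self, k: int = 1, p: float = 2.0):
        if p < 1:
            raise ContractError(f"Minkowski exponent must be >= 1, got {p}")
        self.k = int(k)
        self.p = float(p)
        self.train_: LabeledDataset | None = None

    def fit(self, data: LabeledDataset) -> "KNNClassifier":
        if not (1 <= self.k <= data.n):
            raise ContractError(f"K={self.k} out of range for N_train={data.n}")
        self.train_ = data
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        if self.train_ is None:
            raise ContractError("classifier is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        train = self.train_
        diffs = np.abs(X[:, None, :] - train.X[None, :, :])
        dists = np.sum(diffs**self.p, axis=2) ** (1.0 / self.p)
        scores = np.empty(X.shape[0])
        for i, row in enumerate(dists):
            # stable sort => equal distances keep ascending training index
            nearest = np.argsort(row, kind="stable")[: self.k]
            votes = train.t[nearest]
            scores[i] = votes.sum() / self.k
        return scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        return np.where(scores >= 0, 1, -1)


def knn_predict(model: KNNClassifier, x: np.ndarray) -> tuple[int, float]:
    """Label and vote score for a single input vector."""
    score = float(model.decision_function(np.atleast_2d(x))[0])
    return (1 if score >= 0 else -1), score
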