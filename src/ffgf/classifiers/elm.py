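"""Extreme learning machine and its optimally pruned variant.

An ELM is a single-hidden-layer network whose hidden parameters are drawn at
random and frozen; only the output weights are learned, by solving the
linear least-squares problem ``H B = T`` with the Moore-Penrose
pseudoinverse of the hidden-layer output matrix H.

The pruned variant ranks the hidden neurons by their least-angle-regression
order of entry against the target and keeps the prefix minimizing the
closed-form (PRESS) leave-one-out error.

Node types:

- ``linear``:  f(x) = w . x + b
- ``sigmoid``: f(x) = 1 / (1 + exp(-(w . x + b)))
- ``gaussian``: f(x) = exp(-||x - w||^2 / b^2)  (w is a center drawn from
  the training points, b a width scaled to the median pairwise distance)

Inputs are standardized (z-scored with training statistics) before reaching
the hidden layer so random weights on [-1, 1] operate on a sensible scale
regardless of the raw feature units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import lars_path

from ..data import LabeledDataset
from ..exceptions import ContractError

NODE_TYPES = ("linear", "sigmoid", "gaussian")


def _expand_node_types(node_types: tuple[str, ...], m: int) -> list[str]:
    """Split m nodes over the listed types in equal proportions.

    Remainder nodes go to the earlier-listed types.
    """
    types = tuple(node_types)
    for t in types:
        if t not in NODE_TYPES:
            raise ContractError(f"unknown node type {t!r}")
    base, extra = divmod(m, len(types))
    counts = [base + (1 if i < extra else 0) for i in range(len(types))]
    out: list[str] = []
    for t, c in zip(types, counts):
        out.extend([t] * c)
    return out


@dataclass
class HiddenLayer:
    """Frozen random hidden layer: per-node type, weight/center and bias/width."""

    types: list[str]
    W: np.ndarray  # (M, d) input weights or gaussian centers
    b: np.ndarray  # (M,) biases or gaussian widths

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        H = np.empty((X.shape[0], len(self.types)))
        for j, kind in enumerate(self.types):
            if kind == "gaussian":
                d2 = np.sum((X - self.W[j]) ** 2, axis=1)
                H[:, j] = np.exp(-d2 / self.b[j] ** 2)
            else:
                z = X @ self.W[j] + self.b[j]
                H[:, j] = z if kind == "linear" else 1.0 / (1.0 + np.exp(-z))
        return H

    def subset(self, idx: np.ndarray) -> "HiddenLayer":
        return HiddenLayer(
            types=[self.types[i] for i in idx], W=self.W[idx], b=self.b[idx]
        )


def _draw_hidden_layer(
    X: np.ndarray, m: int, node_types: tuple[str, ...], rng: np.random.Generator
) -> HiddenLayer:
    n, d = X.shape
    types = _expand_node_types(node_types, m)
    W = np.empty((m, d))
    b = np.empty(m)
    n_gauss = sum(1 for t in types if t == "gaussian")
    if n_gauss:
        # width scale from the median pairwise distance of the training points
        sub = X if n <= 300 else X[rng.choice(n, 300, replace=False)]
        diffs = sub[:, None, :] - sub[None, :, :]
        dists = np.sqrt(np.sum(diffs**2, axis=2))
        med = float(np.median(dists[np.triu_indices(len(sub), k=1)]))
        if med <= 0:
            med = 1.0
    for j, kind in enumerate(types):
        if kind == "gaussian":
            W[j] = X[rng.integers(n)]
            b[j] = rng.uniform(0.2, 0.8) * med
        else:
            W[j] = rng.uniform(-1.0, 1.0, size=d)
            b[j] = rng.uniform(-1.0, 1.0)
    return HiddenLayer(types=types, W=W, b=b)


def press_loo_error(H: np.ndarray, t: np.ndarray) -> float:
    """Mean squared PRESS residual of the least-squares fit of t on H.

    Allen's closed form: the leave-one-out residual at case i equals
    ``(t_i - yhat_i) / (1 - h_ii)`` where yhat is the in-sample projection and
    h_ii the hat-matrix leverage.  Requires N > M so leverages stay below 1.
    """
    H = np.asarray(H, dtype=float)
    t = np.asarray(t, dtype=float)
    n, m = H.shape
    if n <= m:
        raise ContractError(f"PRESS needs N > M, got N={n}, M={m}")
    U, s, _ = np.linalg.svd(H, full_matrices=False)
    rank = s > s[0] * max(n, m) * np.finfo(float).eps if s.size else s
    Ur = U[:, rank]
    yhat = Ur @ (Ur.T @ t)
    h = np.minimum(np.sum(Ur**2, axis=1), 1.0 - 1e-10)
    resid = (t - yhat) / (1.0 - h)
    return float(np.mean(resid**2))


class ELMClassifier:
    """Fixed-size ELM: M random hidden nodes, pseudoinverse output weights."""

    def __init__(
        self,
        m_hidden: int = 20,
        node_types: tuple[str, ...] = ("sigmoid",),
        seed: int | None = 0,
        standardize: bool = True,
    ):
        if m_hidden < 1:
            raise ContractError(f"hidden node count must be >= 1, got {m_hidden}")
        self.m_hidden = int(m_hidden)
        self.node_types = tuple(node_types)
        self.seed = seed
        self.standardize = standardize
        self.hidden_: HiddenLayer | None = None
        self.beta_: np.ndarray | None = None
        self.n_hidden_: int | None = None
        self._mu: np.ndarray | None = None
        self._sigma: np.ndarray | None = None

    def _scale(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not self.standardize:
            return X
        return (X - self._mu) / self._sigma

    def _fit_scaler(self, X: np.ndarray) -> np.ndarray:
        if not self.standardize:
            self._mu, self._sigma = None, None
            return np.asarray(X, dtype=float)
        self._mu = X.mean(axis=0)
        sigma = X.std(axis=0)
        self._sigma = np.where(sigma > 0, sigma, 1.0)
        return (X - self._mu) / self._sigma

    def fit(self, data: LabeledDataset) -> "ELMClassifier":
        Xs = self._fit_scaler(data.X)
        rng = np.random.default_rng(self.seed)
        self.hidden_ = _draw_hidden_layer(Xs, self.m_hidden, self.node_types, rng)
        H = self.hidden_.transform(Xs)
        self.beta_ = np.linalg.pinv(H) @ data.t.astype(float)
        self.n_hidden_ = self.m_hidden
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        if self.beta_ is None:
            raise ContractError("classifier is not fitted")
        return self.hidden_.transform(self._scale(X)) @ self.beta_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, 1, -1)


def _lars_order(H: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Column indices of H in least-angle-regression order of entry."""
    Hc = H - H.mean(axis=0)
    tc = t - t.mean()
    norms = np.linalg.norm(Hc, axis=0)
    usable = norms > 1e-12
    order: list[int] = []
    if usable.any():
        idx = np.flatnonzero(usable)
        with warnings.catch_warnings():
            # near-collinear hidden nodes get dropped from the active set;
            # they are appended at the tail below, which is all we need
            warnings.simplefilter("ignore")
            _, active, _ = lars_path(Hc[:, idx], tc, method="lar")
        order = [int(idx[a]) for a in active]
    remaining = [j for j in range(H.shape[1]) if j not in set(order)]
    return np.array(order + remaining, dtype=int)


class OPELMClassifier(ELMClassifier):
    """ELM pruned to the LARS-ranked neuron prefix with minimal PRESS error.

    ``m_hidden`` is the initial node count; it is capped at N - 2 at fit time
    so the leave-one-out formula stays defined for every candidate prefix.
    """

    def fit(self, data: LabeledDataset) -> "OPELMClassifier":
        Xs = self._fit_scaler(data.X)
        m_init = min(self.m_hidden, data.n - 2)
        if m_init < 1:
            raise ContractError("need at least 3 training cases for pruning")
        rng = np.random.default_rng(self.seed)
        layer = _draw_hidden_layer(Xs, m_init, self.node_types, rng)
        H = layer.transform(Xs)
        t = data.t.astype(float)
        order = _lars_order(H, t)
        press = np.array(
            [press_loo_error(H[:, order[:k]], t) for k in range(1, m_init + 1)]
        )
        k_best = int(np.argmin(press)) + 1  # argmin takes the first => smaller k
        keep = order[:k_best]
        self.hidden_ = layer.subset(keep)
        Hk = H[:, keep]
        self.beta_ = np.linalg.pinv(Hk) @ t
        self.n_hidden_ = k_best
        self.press_path_ = press
        self.rank_order_ = order
        return self


def elm_fit(
    data: LabeledDataset,
    m_hidden: int,
    node_types: tuple[str, ...] = ("sigmoid",),
    seed: int | None = 0,
) -> ELMClassifier:
    return ELMClassifier(m_hidden=m_hidden, node_types=node_types, seed=seed).fit(data)


def elm_predict(model: ELMClassifier, x: np.ndarray) -> tuple[int, float]:
    score = float(model.decision_function(np.atleast_2d(x))[0])
    return (1 if score >= 0 else -1), score


def op_elm_fit(
    data: LabeledDataset,
    m_init: int = 100,
    node_types: tuple[str, ...] = ("sigmoid",),
    seed: int | None = 0,
) -> OPELMClassifier:
    return OPELMClassifier(m_hidden=m_init, node_types=node_types, seed=seed).fit(data)
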