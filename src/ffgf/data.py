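"""Labeled feature tables and their CSV dialect.

The canonical on-disk form is a CSV with header
``image_id,major,minor,area,label`` (label optional at extraction time),
one row per image.  In memory a dataset is an (N, d) float matrix plus an
N-vector of targets in {+1, -1}: +1 = class C1 (benign-like), -1 = class C2
(malignant-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ContractError, FormatError

FEATURE_COLUMNS = ("major", "minor", "area")


@dataclass(frozen=True)
class LabeledDataset:
    """(N, d) feature matrix with +/-1 targets."""

    X: np.ndarray
    t: np.ndarray
    ids: tuple[str, ...] | None = field(default=None, compare=False)

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        t = np.asarray(self.t)
        if X.ndim != 2:
            raise ContractError(f"X must be 2-D, got ndim={X.ndim}")
        if t.shape != (X.shape[0],):
            raise ContractError("t must be a vector with one entry per row of X")
        if not np.all(np.isfinite(X)):
            raise ContractError("X contains missing or non-finite values")
        if not np.isin(t, (1, -1)).all():
            raise ContractError("targets must be +1 or -1")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "t", t.astype(int))

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def require_both_classes(self) -> None:
        if not (np.any(self.t == 1) and np.any(self.t == -1)):
            raise ContractError("both classes must be present")

    def subset(self, idx) -> "LabeledDataset":
        ids = tuple(np.asarray(self.ids)[idx]) if self.ids is not None else None
        return LabeledDataset(self.X[idx], self.t[idx], ids)


def write_features(
    path: str | Path,
    features: np.ndarray,
    ids: list[str],
    labels: np.ndarray | None = None,
) -> None:
    """Write a feature table in the canonical CSV dialect."""
    features = np.asarray(features, dtype=float)
    frame = pd.DataFrame(features, columns=list(FEATURE_COLUMNS))
    frame.insert(0, "image_id", ids)
    if labels is not None:
        frame["label"] = np.asarray(labels, dtype=int)
    frame.to_csv(path, index=False)


def read_features(path: str | Path) -> LabeledDataset:
    """Read a canonical feature CSV into a LabeledDataset (label required)."""
    frame = pd.read_csv(path)
    missing = set(FEATURE_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"feature CSV missing columns: {sorted(missing)}")
    if "label" not in frame.columns:
        raise FormatError("feature CSV has no 'label' column")
    ids = (
        tuple(frame["image_id"].astype(str)) if "image_id" in frame.columns else None
    )
    X = frame[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    t = frame["label"].to_numpy()
    return LabeledDataset(X, t, ids)
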