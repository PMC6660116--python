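"""End-to-end orchestration: images -> features -> LOO-CV report.

The binarization quantile is a trained preprocessing step, so inside
cross-validation it is re-selected on each fold's training portion only.
Spectra and per-quantile features are image-local (each image is thresholded
at its own quantile), so they are precomputed once and reused across folds
without leaking fold information.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classifiers import (
    ELMClassifier,
    KNNClassifier,
    LinearDiscriminant,
    LinearSVM,
    OPELMClassifier,
)
from .data import LabeledDataset
from .evaluation import EvalReport, RepetitionSummary, loocv, repeat_elm_loocv
from .exceptions import ContractError, InputError
from .fft_geometry import (
    DEFAULT_QUANTILE_GRID,
    center_spectrum,
    central_ellipse,
    binarize_spectrum,
    compute_dft,
    select_quantile,
)
from .imaging import EnhanceConfig, apply_roi, enhance, load_image, load_mask

logger = logging.getLogger(__name__)

SETTINGS = ("original", "enhanced", "roi", "roi-enhanced")

STOCHASTIC_MODELS = ("elm", "opelm")


def apply_setting(
    img: np.ndarray, mask: np.ndarray | None, setting: str
) -> np.ndarray:
    """One of the four preprocessing settings applied to a raw image."""
    if setting not in SETTINGS:
        raise ContractError(f"setting must be one of {SETTINGS}, got {setting!r}")
    if setting in ("roi", "roi-enhanced") and mask is None:
        raise ContractError(f"setting {setting!r} requires an ROI mask")
    if setting == "original":
        return img
    if setting == "enhanced":
        return enhance(img)
    if setting == "roi":
        return apply_roi(img, mask)
    # roi-enhanced: enhance the full image first, then crop to the ROI
    return apply_roi(enhance(img), mask)


def load_manifest(images_dir: str | Path) -> pd.DataFrame:
    path = Path(images_dir) / "manifest.csv"
    if not path.exists():
        raise InputError(f"manifest not found: {path}")
    manifest = pd.read_csv(path)
    if "image" not in manifest.columns or "image_id" not in manifest.columns:
        raise InputError("manifest must have 'image_id' and 'image' columns")
    return manifest


def load_images(
    images_dir: str | Path, setting: str = "original"
) -> tuple[list[np.ndarray], np.ndarray, list[str]]:
    """Load all manifest images with the given setting applied.

    Returns (images, labels, image_ids); labels are 0 where absent.
    """
    images_dir = Path(images_dir)
    manifest = load_manifest(images_dir)
    imgs, ids = [], []
    labels = []
    for _, row in manifest.iterrows():
        img = load_image(images_dir / row["image"])
        mask = None
        if "mask" in manifest.columns and isinstance(row["mask"], str):
            mask = load_mask(images_dir / row["mask"])
        imgs.append(apply_setting(img, mask, setting))
        ids.append(str(row["image_id"]))
        labels.append(int(row["label"]) if "label" in manifest.columns else 0)
    return imgs, np.asarray(labels), ids


class FeatureCache:
    """Per-image, per-quantile feature vectors, computed lazily once."""

    def __init__(self, images: Sequence[np.ndarray], grid: Sequence[float]):
        self.grid = tuple(grid)
        self._spectra = [center_spectrum(compute_dft(img)) for img in images]
        self._feats: dict[tuple[int, float], np.ndarray] = {}
        self.n = len(images)

    def features(self, i: int, q: float) -> np.ndarray:
        key = (i, q)
        if key not in self._feats:
            vec = central_ellipse(binarize_spectrum(self._spectra[i], q))
            self._feats[key] = vec.as_array()
        return self._feats[key]

    def feature_matrix(self, q: float, idx: np.ndarray | None = None) -> np.ndarray:
        rows = range(self.n) if idx is None else idx
        return np.vstack([self.features(int(i), q) for i in rows])

    def area_table(self, idx: np.ndarray) -> np.ndarray:
        return np.vstack(
            [[self.features(int(i), q)[2] for q in self.grid] for i in idx]
        )


def extract_features(
    images: Sequence[np.ndarray], q: float
) -> np.ndarray:
    """(N, 3) matrix of (major, minor, area) at a fixed quantile."""
    cache = FeatureCache(images, (q,))
    return cache.feature_matrix(q)


def make_classifier_factory(
    model: str, params: dict | None = None
) -> Callable[..., object]:
    """Classifier factory from a model name and hyperparameter dict.

    Deterministic models ignore the optional seed argument; ELM variants
    require it.
    """
    params = dict(params or {})
    model = model.lower()
    if model == "knn":
        k, p = int(params.get("k", 1)), float(params.get("p", 2))
        return lambda seed=None: KNNClassifier(k=k, p=p)
    if model == "ld":
        return lambda seed=None: LinearDiscriminant()
    if model == "svm":
        trainer = str(params.get("trainer", "smo"))
        C = float(params.get("C", 1.0))
        return lambda seed=None: LinearSVM(trainer=trainer, C=C)
    if model in ("elm", "opelm"):
        m = int(params.get("m_hidden", 100 if model == "opelm" else 20))
        node_types = tuple(params.get("node_types", ("sigmoid",)))
        cls = OPELMClassifier if model == "opelm" else ELMClassifier
        return lambda seed=0: cls(m_hidden=m, node_types=node_types, seed=seed)
    raise ContractError(f"unknown model {model!r}")


def loocv_trained_threshold(
    images: Sequence[np.ndarray],
    labels: np.ndarray,
    make_classifier: Callable[[], object],
    grid: Sequence[float] = DEFAULT_QUANTILE_GRID,
    positive: int = 1,
    fold_quantiles: list[float] | None = None,
) -> EvalReport:
    """LOO-CV over images with per-fold quantile training.

    Each fold selects the binarization quantile on its N-1 training images
    (Fisher ratio of the area feature), extracts features for training and
    held-out image at that quantile, then fits and scores the classifier.
    ``fold_quantiles``, if given, collects the quantile chosen in each fold.
    """
    cache = FeatureCache(images, grid)
    labels = np.asarray(labels)

    def hook(train_idx: np.ndarray, test_idx: int):
        areas = cache.area_table(train_idx)
        q = select_quantile(areas, labels[train_idx], cache.grid)
        if fold_quantiles is not None:
            fold_quantiles.append(q)
        X_tr = cache.feature_matrix(q, train_idx)
        x_te = cache.features(test_idx, q)
        return X_tr, labels[train_idx], x_te

    placeholder = LabeledDataset(np.zeros((len(images), 1)), labels)
    return loocv(placeholder, make_classifier, fold_hook=hook, positive=positive)


def run_experiment(cfg: dict) -> dict:
    """Execute a full experiment described by a config mapping.

    Keys: images (dir with manifest.csv), setting, model, params, grid,
    reps, seed, positive, out.  Writes and returns the JSON report.
    """
    setting = cfg.get("setting", "original")
    model = cfg["model"]
    params = cfg.get("params", {})
    grid = tuple(cfg.get("grid", DEFAULT_QUANTILE_GRID))
    seed = int(cfg.get("seed", 0))
    reps = int(cfg.get("reps", 30))
    positive = int(cfg.get("positive", 1))

    images, labels, ids = load_images(cfg["images"], setting)
    factory = make_classifier_factory(model, params)
    fold_qs: list[float] = []

    if model in STOCHASTIC_MODELS:
        cache = FeatureCache(images, grid)

        def hook(train_idx, test_idx):
            areas = cache.area_table(train_idx)
            q = select_quantile(areas, labels[train_idx], cache.grid)
            fold_qs.append(q)
            return (
                cache.feature_matrix(q, train_idx),
                labels[train_idx],
                cache.features(test_idx, q),
            )

        placeholder = LabeledDataset(np.zeros((len(images), 1)), labels)
        summary = repeat_elm_loocv(
            placeholder,
            lambda s: factory(seed=s),
            reps=reps,
            base_seed=seed,
            fold_hook=hook,
            positive=positive,
        )
        report = summary.best
        extra = {
            "reps": reps,
            "acc_mean": summary.acc_mean,
            "acc_std": summary.acc_std,
            "auc_mean": summary.auc_mean,
            "auc_std": summary.auc_std,
            "hidden_mean": summary.hidden_mean,
            "hidden_std": summary.hidden_std,
            "seeds": list(summary.seeds),
        }
    else:
        report = loocv_trained_threshold(
            images,
            labels,
            lambda: factory(),
            grid=grid,
            positive=positive,
            fold_quantiles=fold_qs,
        )
        extra = {}

    out = {
        "schema_version": 1,
        "package_version": __version__,
        "config": {
            "images": str(cfg["images"]),
            "setting": setting,
            "model": model,
            "params": params,
            "grid": list(grid),
            "seed": seed,
            "reps": reps,
            "positive": positive,
        },
        "n_cases": len(images),
        "image_ids": ids,
        "fold_quantiles": fold_qs[: len(images)],
        "metrics": report.to_dict(),
        **extra,
    }
    if cfg.get("out"):
        Path(cfg["out"]).parent.mkdir(parents=True, exist_ok=True)
        Path(cfg["out"]).write_text(json.dumps(out, indent=2))
        logger.info("report written to %s", cfg["out"])
    return out
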