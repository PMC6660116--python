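"""Synthetic two-class phantoms and Gaussian feature clusters.

The phantom generator emulates B-mode-like grayscale images of a fluid
lesion: a large smooth ellipse ("cyst") on a dark background.  The two
classes differ in the amount of internal geometric discontinuity: the
smooth class has few or no internal structures, the textured class many
bright arcs, blobs and thin septa.  More structures spread spectral energy
isotropically around the zero frequency, which fattens the central blob of
the thresholded spectrum — the property the downstream descriptor relies on.

Speckle is modeled as blended multiplicative exponential noise (the
standard coherent-imaging approximation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk, ellipse, ellipse_perimeter, line

from .data import LabeledDataset
from .exceptions import ContractError, InputError
from .imaging import write_image

DEFAULT_SIZE = (128, 128)
LAMBDA_BENIGN = 2.0
LAMBDA_MALIGNANT = 25.0
SPECKLE_DEFAULT = 0.3


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom image."""

    size: tuple[int, int] = DEFAULT_SIZE
    class_label: int = 1  # +1 smooth/benign-like, -1 textured/malignant-like
    texture_density: float = LAMBDA_BENIGN  # expected internal structure count
    speckle_level: float = SPECKLE_DEFAULT
    seed: int = 0

    def __post_init__(self):
        if self.texture_density < 0:
            raise ContractError("texture_density must be >= 0")
        if self.speckle_level < 0:
            raise ContractError("speckle_level must be >= 0")
        if self.class_label not in (1, -1):
            raise ContractError("class_label must be +1 or -1")


@dataclass(frozen=True)
class ClusterSpec:
    """Two shared-covariance Gaussian classes in feature space."""

    mu_pos: np.ndarray
    mu_neg: np.ndarray
    cov: np.ndarray
    n_per_class: int = 100
    seed: int = 0

    def __post_init__(self):
        cov = np.asarray(self.cov, dtype=float)
        if self.n_per_class < 2:
            raise ContractError("n_per_class must be >= 2")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ContractError("covariance must be positive definite") from exc


def _random_point_in_ellipse(rng, center, axes):
    """Uniform-ish point inside an axis-aligned ellipse (rejection-free)."""
    r = np.sqrt(rng.uniform())
    theta = rng.uniform(0, 2 * np.pi)
    return (
        center[0] + r * axes[0] * np.sin(theta),
        center[1] + r * axes[1] * np.cos(theta),
    )


def gen_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one phantom; returns (image uint8, cyst ROI mask).

    Fully deterministic given the spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    m, n = spec.size
    img = np.full((m, n), 30.0)
    # cyst geometry: centered with mild jitter, axis lengths ~1/3 of the frame
    cr = m / 2 + rng.uniform(-m / 16, m / 16)
    cc = n / 2 + rng.uniform(-n / 16, n / 16)
    ar = rng.uniform(0.30, 0.40) * m
    ac = rng.uniform(0.24, 0.34) * n
    wall_r, wall_c = ellipse(cr, cc, ar + 2, ac + 2, shape=(m, n))
    img[wall_r, wall_c] = 170.0
    int_r, int_c = ellipse(cr, cc, ar, ac, shape=(m, n))
    img[int_r, int_c] = 70.0
    # soften the base anatomy so its spectrum decays steeply; the internal
    # structures are drawn sharp afterwards and carry the mid-frequency
    # energy that distinguishes the textured class
    img = ndimage.gaussian_filter(img, 2.5)
    # beam-line banding: its spectral harmonics form satellites away from the
    # zero frequency that only a texture-raised broadband floor can bridge
    img = img * (1.0 + 0.5 * np.sin(2 * np.pi * np.arange(m)[:, None] / 8.0))
    mask = np.zeros((m, n), dtype=bool)
    mask[wall_r, wall_c] = True

    overlay = np.zeros((m, n))
    n_structures = rng.poisson(spec.texture_density)
    for _ in range(n_structures):
        kind = rng.integers(3)
        bright = rng.uniform(120.0, 200.0)
        if kind == 0:  # small bright blob
            pr, pc = _random_point_in_ellipse(rng, (cr, cc), (0.8 * ar, 0.8 * ac))
            rr, cc2 = disk((pr, pc), rng.uniform(1.5, 4.5), shape=(m, n))
            overlay[rr, cc2] = bright
        elif kind == 1:  # thin septum across the cyst
            th1, th2 = rng.uniform(0, 2 * np.pi, size=2)
            p1 = (int(cr + ar * np.sin(th1)), int(cc + ac * np.cos(th1)))
            p2 = (int(cr + ar * np.sin(th2)), int(cc + ac * np.cos(th2)))
            rr, cc2 = line(
                int(np.clip(p1[0], 0, m - 1)),
                int(np.clip(p1[1], 0, n - 1)),
                int(np.clip(p2[0], 0, m - 1)),
                int(np.clip(p2[1], 0, n - 1)),
            )
            overlay[rr, cc2] = bright
        else:  # bright arc (partial small ellipse outline)
            pr, pc = _random_point_in_ellipse(rng, (cr, cc), (0.6 * ar, 0.6 * ac))
            rr, cc2 = ellipse_perimeter(
                int(pr),
                int(pc),
                int(rng.uniform(3, 9)),
                int(rng.uniform(3, 9)),
                orientation=rng.uniform(0, np.pi),
                shape=(m, n),
            )
            keep = rng.uniform(size=rr.size) < 0.7
            overlay[rr[keep], cc2[keep]] = bright
    overlay = ndimage.gaussian_filter(overlay, 0.7)
    img = np.maximum(img, overlay)

    if spec.speckle_level > 0:
        noise = rng.exponential(1.0, size=(m, n))
        img = img * ((1.0 - spec.speckle_level) + spec.speckle_level * noise)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), mask


def gen_feature_clusters(spec: ClusterSpec) -> LabeledDataset:
    """Sample the two Gaussian classes; +1 rows first, then -1 rows."""
    rng = np.random.default_rng(spec.seed)
    cov = np.asarray(spec.cov, dtype=float)
    X_pos = rng.multivariate_normal(np.asarray(spec.mu_pos, float), cov, spec.n_per_class)
    X_neg = rng.multivariate_normal(np.asarray(spec.mu_neg, float), cov, spec.n_per_class)
    X = np.vstack([X_pos, X_neg])
    t = np.concatenate([np.ones(spec.n_per_class), -np.ones(spec.n_per_class)])
    return LabeledDataset(X, t)


def gen_benchmark_suite(
    out_dir: str | Path,
    n_per_class: int = 40,
    seed: int = 0,
    lambda_benign: float = LAMBDA_BENIGN,
    lambda_malignant: float = LAMBDA_MALIGNANT,
    speckle: float = SPECKLE_DEFAULT,
    size: tuple[int, int] = DEFAULT_SIZE,
) -> pd.DataFrame:
    """Write a two-class phantom dataset (PNGs + masks + manifest CSV).

    Returns the manifest; per-image seeds are derived deterministically from
    the suite seed, so a rerun yields byte-identical files.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {out_dir}") from exc
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_per_class)
    rows = []
    for idx in range(2 * n_per_class):
        benign = idx < n_per_class
        label = 1 if benign else -1
        lam = lambda_benign if benign else lambda_malignant
        image_id = f"{'benign' if benign else 'malignant'}_{idx % n_per_class:03d}"
        spec = PhantomSpec(
            size=size,
            class_label=label,
            texture_density=lam,
            speckle_level=speckle,
            seed=int(child_seeds[idx]),
        )
        img, mask = gen_phantom(spec)
        img_name = f"{image_id}.png"
        mask_name = f"{image_id}_mask.png"
        write_image(out_dir / img_name, img)
        write_image(out_dir / mask_name, mask.astype(np.uint8) * 255)
        rows.append(
            {
                "image_id": image_id,
                "image": img_name,
                "mask": mask_name,
                "label": label,
                "seed": int(child_seeds[idx]),
                "texture_density": lam,
                "speckle_level": speckle,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
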