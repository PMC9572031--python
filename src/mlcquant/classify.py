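"""Trainable pixel classification of enhanced en face images.

This is the interactive-segmentation stage of the workflow recast as a
reproducible fit: a multi-scale feature stack (raw intensity, Gaussian blurs,
gradient magnitudes, Laplacians and differences of Gaussians) feeds an
ensemble of randomized trees that maps each pixel to P(cell). Labels come
either from hand-painted label images (0 = unlabeled, 1 = cell,
2 = background) or, for synthetic data, from planted ground truth.

A deterministic 256-bin Otsu threshold is provided as a no-training fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from scipy import ndimage as ndi
from sklearn.ensemble import ExtraTreesClassifier

from .core import EnFaceImage

__all__ = [
    "FEATURE_NAMES",
    "LABEL_UNLABELED",
    "LABEL_MLC",
    "LABEL_BACKGROUND",
    "PixelModel",
    "compute_features",
    "labels_from_truth",
    "train_pixel_model",
    "predict_probability",
    "otsu_threshold",
]

LABEL_UNLABELED, LABEL_MLC, LABEL_BACKGROUND = 0, 1, 2

FEATURE_NAMES = (
    "raw",
    "gauss_1", "gauss_2", "gauss_4", "gauss_8",
    "gradmag_1", "gradmag_2",
    "laplace_1", "laplace_2",
    "dog_1_2", "dog_2_4",
)

MODEL_FORMAT_VERSION = 1


def _as_array(image) -> np.ndarray:
    arr = image.pixels if isinstance(image, EnFaceImage) else np.asarray(image)
    if arr.size == 0:
        raise ValueError("image is empty")
    return arr.astype(float)


def compute_features(image) -> np.ndarray:
    """Per-pixel feature stack, shape (H, W, len(FEATURE_NAMES)), float32.

    Deterministic; all filters use reflecting boundaries.
    """
    arr = _as_array(image)
    blurs = {s: ndi.gaussian_filter(arr, s, mode="reflect", truncate=4.0) for s in (1, 2, 4, 8)}
    planes = [arr]
    planes += [blurs[s] for s in (1, 2, 4, 8)]
    planes += [ndi.gaussian_gradient_magnitude(arr, s, mode="reflect") for s in (1, 2)]
    planes += [ndi.gaussian_laplace(arr, s, mode="reflect") for s in (1, 2)]
    planes += [blurs[1] - blurs[2], blurs[2] - blurs[4]]
    return np.stack(planes, axis=-1).astype(np.float32)


def labels_from_truth(shape: tuple[int, int], centers: np.ndarray, radius_px: float = 2.0) -> np.ndarray:
    """Label image from planted cell centers: disks = cell, elsewhere background."""
    lab = np.full(shape, LABEL_BACKGROUND, dtype=np.uint8)
    r = int(np.ceil(radius_px))
    for row, col in np.atleast_2d(centers):
        r0, r1 = max(int(row) - r - 1, 0), min(int(row) + r + 2, shape[0])
        c0, c1 = max(int(col) - r - 1, 0), min(int(col) + r + 2, shape[1])
        yy, xx = np.mgrid[r0:r1, c0:c1]
        disk = (yy - row) ** 2 + (xx - col) ** 2 <= radius_px**2
        lab[r0:r1, c0:c1][disk] = LABEL_MLC
    return lab


@dataclass
class PixelModel:
    """A fitted per-pixel classifier with its training metadata."""

    classifier: ExtraTreesClassifier
    feature_names: tuple[str, ...]
    n_pixels: int
    class_balance: dict[str, int]
    seed: int
    heldout_accuracy: float

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format_version": MODEL_FORMAT_VERSION,
                "classifier": self.classifier,
                "feature_names": self.feature_names,
                "n_pixels": self.n_pixels,
                "class_balance": self.class_balance,
                "seed": self.seed,
                "heldout_accuracy": self.heldout_accuracy,
            },
            Path(path),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PixelModel":
        d = joblib.load(Path(path))
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format: {d.get('format_version')}")
        return cls(
            classifier=d["classifier"],
            feature_names=tuple(d["feature_names"]),
            n_pixels=d["n_pixels"],
            class_balance=d["class_balance"],
            seed=d["seed"],
            heldout_accuracy=d["heldout_accuracy"],
        )


def train_pixel_model(
    images: list,
    labels: list[np.ndarray],
    seed: int = 0,
    *,
    n_estimators: int = 100,
    max_background_ratio: float = 5.0,
    holdout_fraction: float = 0.25,
) -> PixelModel:
    """Fit the pixel classifier on the labeled pixels of the given images.

    Background pixels are downsampled to at most ``max_background_ratio``
    times the cell pixels. A held-out fraction of the labeled pixels is used
    to report accuracy. Deterministic for a fixed seed.
    """
    if len(images) != len(labels):
        raise ValueError("images and labels must align")
    rng = np.random.default_rng(seed)
    X_parts, y_parts = [], []
    for img, lab in zip(images, labels):
        arr = _as_array(img)
        lab = np.asarray(lab)
        if lab.shape != arr.shape:
            raise ValueError("label image shape does not match image")
        stack = compute_features(arr)
        mlc_idx = np.argwhere(lab == LABEL_MLC)
        bg_idx = np.argwhere(lab == LABEL_BACKGROUND)
        if len(bg_idx) > max_background_ratio * max(len(mlc_idx), 1):
            keep = rng.choice(
                len(bg_idx), int(max_background_ratio * max(len(mlc_idx), 1)), replace=False
            )
            bg_idx = bg_idx[keep]
        for idx, cls_ in ((mlc_idx, 1), (bg_idx, 0)):
            if len(idx):
                X_parts.append(stack[idx[:, 0], idx[:, 1]])
                y_parts.append(np.full(len(idx), cls_, dtype=np.int8))
    if not X_parts:
        raise ValueError("no labeled pixels")
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    if not (y == 1).any():
        raise ValueError("no labeled cell (MLC) pixels")
    if not (y == 0).any():
        raise ValueError("no labeled background pixels")

    order = rng.permutation(len(y))
    n_hold = max(int(holdout_fraction * len(y)), 1)
    hold, train = order[:n_hold], order[n_hold:]
    clf = ExtraTreesClassifier(
        n_estimators=n_estimators, random_state=int(rng.integers(2**31)), n_jobs=1
    )
    clf.fit(X[train], y[train])
    acc = float((clf.predict(X[hold]) == y[hold]).mean())
    return PixelModel(
        classifier=clf,
        feature_names=FEATURE_NAMES,
        n_pixels=len(y),
        class_balance={"mlc": int((y == 1).sum()), "background": int((y == 0).sum())},
        seed=seed,
        heldout_accuracy=acc,
    )


def predict_probability(model: PixelModel, image) -> np.ndarray:
    """Per-pixel P(cell) in [0, 1], same shape as the input image."""
    if model is None or model.classifier is None:
        raise ValueError("model is not trained")
    arr = _as_array(image)
    stack = compute_features(arr)
    p = model.classifier.predict_proba(stack.reshape(-1, stack.shape[-1]))[:, 1]
    return p.reshape(arr.shape)


def otsu_threshold(image) -> int:
    """Otsu threshold over the 256-bin histogram of an intensity image.

    Returns the bin index ``t`` maximizing between-class variance of the
    split ``{<= t, > t}``; ties broken toward the lower threshold. Pixels are
    binned as ``floor(clip(value, 0, 255))``.
    """
    arr = _as_array(image)
    binned = np.clip(np.floor(arr), 0, 255).astype(np.int64)
    if binned.min() == binned.max():
        raise ValueError("constant image has no Otsu threshold")
    hist = np.bincount(binned.ravel(), minlength=256).astype(float)
    p = hist / hist.sum()
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(p)
    mu = np.cumsum(p * levels)
    mu_total = mu[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        between = (mu_total * w0 - mu) ** 2 / (w0 * (1.0 - w0))
    between = np.nan_to_num(between[:-1], nan=-np.inf)
    return int(np.argmax(between))
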