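"""Seeded synthetic phantoms with ground truth, plus scoring utilities.

The phantoms emulate the intensity structure that intensity-based brain
MRI segmentation assumes: a small number of tissue classes, each with a
characteristic mean gray level, corrupted by additive Gaussian noise and
optionally by a smooth multiplicative bias field (the slowly varying
intensity inhomogeneity typical of MR acquisitions). Geometry templates
control the spatial layout of the classes; class proportions are fixed
by the geometry so tests see deterministic class sizes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

__all__ = ["Phantom", "generate_phantom", "segmentation_accuracy"]

GEOMETRIES = ("stripes", "nested_disks", "voronoi")


@dataclass
class Phantom:
    """A synthetic image, its ground-truth label map and true parameters."""

    image: np.ndarray
    truth: np.ndarray
    class_means: np.ndarray
    class_stds: np.ndarray
    bias_amplitude: float
    seed: int


def _truth_map(
    shape: Tuple[int, int], k: int, geometry: str, rng: np.random.Generator
) -> np.ndarray:
    h, w = shape
    if geometry == "stripes":
        rows = np.arange(h)
        bands = np.minimum((rows * k) // h, k - 1)
        return np.broadcast_to(bands[:, None], shape).copy()
    if geometry == "nested_disks":
        yy, xx = np.mgrid[0:h, 0:w]
        r = np.hypot(yy - (h - 1) / 2.0, xx - (w - 1) / 2.0)
        # quantile radii give the k annuli equal pixel counts
        edges = np.quantile(r.ravel(), np.arange(1, k) / k)
        return np.searchsorted(edges, r, side="left").astype(int)
    if geometry == "voronoi":
        for _ in range(100):
            seeds = rng.random((k, 2)) * np.array([h, w])
            yy, xx = np.mgrid[0:h, 0:w]
            d = (yy[..., None] - seeds[:, 0]) ** 2 + (xx[..., None] - seeds[:, 1]) ** 2
            truth = np.argmin(d, axis=-1)
            counts = np.bincount(truth.ravel(), minlength=k)
            if counts.min() >= 0.05 * h * w:
                return truth
        raise ValueError(f"could not place {k} voronoi cells each covering >= 5% of pixels")
    raise ValueError(f"unknown geometry {geometry!r}; choose from {GEOMETRIES}")


def _bias_field(shape: Tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Zero-mean smooth surface from low-order 2-D polynomial terms, max |b| = 1."""
    h, w = shape
    y = np.linspace(-1.0, 1.0, h)[:, None]
    x = np.linspace(-1.0, 1.0, w)[None, :]
    terms = [y, x, y * x, y**2, x**2]
    coeffs = rng.normal(0.0, 1.0, len(terms))
    b = sum(c * t for c, t in zip(coeffs, terms))
    b = b - b.mean()
    peak = np.abs(b).max()
    return b / peak if peak > 0 else b


def generate_phantom(
    shape: Tuple[int, int] = (128, 128),
    class_means: Sequence[float] = (0.2, 0.5, 0.8),
    class_stds: Sequence[float] | float = 0.05,
    geometry: str = "nested_disks",
    bias_amplitude: float = 0.0,
    seed: int = 0,
) -> Phantom:
    """Generate a k-class phantom image with ground-truth labels.

    The label map is drawn by the geometry rule; the image is
    ``class_mean[truth] + N(0, class_std[truth])`` per pixel, optionally
    multiplied by ``1 + bias_amplitude * b(x, y)`` with ``b`` a smooth
    zero-mean surface, and finally clipped to [0, 1]. Every class covers
    at least 5% of the pixels. Bit-identical for equal arguments.
    """
    means = np.asarray(class_means, dtype=float)
    k = means.size
    if np.any(np.diff(means) <= 0):
        raise ValueError("class_means must be strictly increasing")
    if means.min() < 0 or means.max() > 1:
        raise ValueError("class_means must lie in [0, 1]")
    stds = np.broadcast_to(np.asarray(class_stds, dtype=float), (k,)).copy()
    if np.any(stds < 0):
        raise ValueError("class_stds must be non-negative")
    if min(shape) < 32:
        raise ValueError("shape must be at least 32x32")
    if bias_amplitude < 0:
        raise ValueError("bias_amplitude must be non-negative")

    rng = np.random.default_rng(seed)
    truth = _truth_map(tuple(shape), k, geometry, rng)
    counts = np.bincount(truth.ravel(), minlength=k)
    if counts.min() < 0.05 * truth.size:
        raise ValueError(f"geometry {geometry!r} cannot give every class >= 5% of pixels")

    image = means[truth] + rng.normal(0.0, 1.0, truth.shape) * stds[truth]
    if bias_amplitude > 0:
        image = image * (1.0 + bias_amplitude * _bias_field(tuple(shape), rng))
    image = np.clip(image, 0.0, 1.0)
    return Phantom(
        image=image,
        truth=truth,
        class_means=means,
        class_stds=stds,
        bias_amplitude=float(bias_amplitude),
        seed=seed,
    )


def segmentation_accuracy(labels: np.ndarray, truth: np.ndarray) -> float:
    """Permutation-invariant pixel agreement between a labeling and truth.

    Maximizes the agreement fraction over all assignments of predicted
    labels to truth classes (exhaustive over permutations; intended for
    c <= 6). Invariant to any relabeling of the prediction.
    """
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if labels.shape != truth.shape:
        raise ValueError(f"shape mismatch: labels {labels.shape} vs truth {truth.shape}")
    truth_classes = np.unique(truth)
    label_classes = np.unique(labels)
    if label_classes.size > truth_classes.size:
        raise ValueError("labels use more classes than the ground truth")
    c = truth_classes.size
    if c > 6:
        raise ValueError("exhaustive permutation matching supports at most 6 classes")
    # confusion[a, b] = pixels with predicted class index a and truth index b
    conf = np.zeros((label_classes.size, c), dtype=np.int64)
    for a, lv in enumerate(label_classes):
        hits = labels == lv
        for b, tv in enumerate(truth_classes):
            conf[a, b] = np.count_nonzero(hits & (truth == tv))
    n = truth.size
    best = 0
    for perm in itertools.permutations(range(c), label_classes.size):
        agree = sum(conf[a, perm[a]] for a in range(label_classes.size))
        best = max(best, agree)
    return best / n
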