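"""Rough-set construction of the harmony memory from data.

Instead of filling the harmony memory with uniform random vectors, the
improved optimizer derives its initial population from the data itself:
candidate cluster centers are iterated under a rough-set partition in
which every point certainly near one center joins that cluster's *lower
approximation*, while points whose two nearest centers are almost
equidistant fall into a *boundary region* shared between the clusters'
*upper approximations*. Centers are updated as a weighted mean of
certain (lower) and uncertain (boundary) members, and a final K-nearest
neighbor majority vote turns the boundary region into crisp labels. The
converged, refined centers seed the harmony memory, replacing blind
random initialization with a data-driven one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Mapping

import numpy as np

from .hs import HSParams, HarmonyMemory, ObjectiveFunction, _evaluate

__all__ = [
    "RoughParams",
    "RoughPartition",
    "init_centers",
    "rough_assign",
    "update_centers_rough",
    "knn_refine",
    "build_harmony_memory",
]


@dataclass(frozen=True)
class RoughParams:
    """Parameters of the rough-set memory construction.

    Parameters
    ----------
    k_clusters
        Number of clusters (the given cluster count).
    boundary_threshold
        Margin, in intensity units, below which a point's second-nearest
        center is considered indistinguishable from its nearest; such
        points become boundary points.
    w_low
        Weight of the lower-approximation mean in the center update;
        must satisfy ``0.5 < w_low < 1`` so certain members dominate.
        The boundary weight is ``w_up = 1 - w_low``.
    knn_k
        Neighborhood size of the KNN majority vote that resolves
        boundary points.
    max_rounds
        Cap on rough-update rounds.
    stop_threshold
        Convergence threshold: the rough iteration stops once the
        maximum center shift falls to or below it. The adaptive
        optimizer reuses it as its memory-collapse stopping level.
    seed
        Seed for the perturbations that diversify the emitted memory.
    """

    k_clusters: int
    boundary_threshold: float = 0.05
    w_low: float = 0.75
    knn_k: int = 5
    max_rounds: int = 100
    stop_threshold: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_clusters < 1:
            raise ValueError("k_clusters must be a positive integer")
        if self.boundary_threshold < 0:
            raise ValueError("boundary_threshold must be non-negative")
        if not 0.5 < self.w_low < 1.0:
            raise ValueError("w_low must lie strictly between 0.5 and 1")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.max_rounds < 0:
            raise ValueError("max_rounds must be non-negative")
        if self.stop_threshold < 0:
            raise ValueError("stop_threshold must be non-negative")

    @property
    def w_up(self) -> float:
        """Boundary weight, exactly ``1 - w_low``."""
        return 1.0 - self.w_low

    def to_dict(self) -> dict:
        return {
            "k_clusters": self.k_clusters,
            "boundary_threshold": self.boundary_threshold,
            "w_low": self.w_low,
            "knn_k": self.knn_k,
            "max_rounds": self.max_rounds,
            "stop_threshold": self.stop_threshold,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RoughParams":
        return cls(**dict(d))


@dataclass
class RoughPartition:
    """Lower/upper approximation assignment of points to centers.

    ``lower[i]`` holds indices of points certainly in cluster ``i``;
    ``upper[i]`` additionally contains the boundary points it shares with
    other clusters. ``boundary`` lists every point in two or more upper
    approximations (and no lower one).
    """

    centers: np.ndarray
    lower: List[np.ndarray]
    upper: List[np.ndarray]
    boundary: np.ndarray
    n_points: int = field(default=0)

    def validate(self) -> None:
        """Assert the rough-set structure invariants; raise on violation."""
        k = len(self.lower)
        seen_lower = np.concatenate([np.asarray(s) for s in self.lower]) if k else np.array([])
        if len(seen_lower) != len(set(seen_lower.tolist())):
            raise AssertionError("lower approximations are not pairwise disjoint")
        membership = np.zeros(self.n_points, dtype=int)
        for i in range(k):
            if not np.isin(self.lower[i], self.upper[i]).all():
                raise AssertionError(f"lower[{i}] is not a subset of upper[{i}]")
            membership[np.asarray(self.upper[i], dtype=int)] += 1
        if np.any(membership == 0):
            raise AssertionError("some point belongs to no upper approximation")
        in_lower = np.zeros(self.n_points, dtype=bool)
        in_lower[seen_lower.astype(int)] = True
        in_boundary = np.zeros(self.n_points, dtype=bool)
        in_boundary[np.asarray(self.boundary, dtype=int)] = True
        if np.any(in_lower & in_boundary) or np.any(~in_lower & ~in_boundary):
            raise AssertionError("each point must be in exactly one lower set XOR boundary")
        if np.any(in_boundary & (membership < 2)):
            raise AssertionError("boundary points must lie in >= 2 upper approximations")


def _as_features(data: np.ndarray) -> np.ndarray:
    """View data as an (n, d) feature matrix; grayscale vectors get d = 1."""
    data = np.asarray(data, dtype=float)
    return data[:, None] if data.ndim == 1 else data


def _distances(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix between (n, d) points and (k, d) centers."""
    diff = points[:, None, :] - centers[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def init_centers(data: np.ndarray, k: int) -> np.ndarray:
    """Deterministic initial centers at evenly spaced data quantiles.

    Center ``i`` sits at the ``(2i + 1) / (2k)`` quantile (midpoint
    interpolation), spreading the k centers across the intensity range;
    ``k = 1`` yields the median.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} data points, got {n}")
    if not np.all(np.isfinite(data)):
        raise ValueError("data must be finite")
    qs = (2 * np.arange(k) + 1) / (2 * k)
    return np.quantile(data, qs, axis=0, method="midpoint")


def rough_assign(
    data: np.ndarray, centers: np.ndarray, boundary_threshold: float
) -> RoughPartition:
    """Partition points into lower approximations and a boundary region.

    A point whose distance margin ``d_second_nearest - d_nearest`` exceeds
    the threshold is certainly in its nearest cluster (lower and upper
    approximation); otherwise it joins the upper approximations of its
    nearest center and of every center within the margin.
    """
    if boundary_threshold < 0:
        raise ValueError("boundary_threshold must be non-negative")
    X = _as_features(data)
    C = _as_features(np.asarray(centers, dtype=float).ravel() if np.ndim(centers) == 1 else centers)
    k = C.shape[0]
    if k > 1:
        gaps = _distances(C, C)
        np.fill_diagonal(gaps, np.inf)
        if gaps.min() == 0:
            raise ValueError("coincident centers: distance margins are degenerate")
    d = _distances(X, C)
    nearest = np.argmin(d, axis=1)
    d_min = d[np.arange(X.shape[0]), nearest]
    within = d - d_min[:, None] <= boundary_threshold
    within[np.arange(X.shape[0]), nearest] = False
    is_boundary = within.any(axis=1)

    lower = [np.flatnonzero((nearest == i) & ~is_boundary) for i in range(k)]
    upper = []
    for i in range(k):
        own = (nearest == i) | within[:, i]
        upper.append(np.flatnonzero(own))
    part = RoughPartition(
        centers=np.asarray(centers, dtype=float),
        lower=lower,
        upper=upper,
        boundary=np.flatnonzero(is_boundary),
        n_points=X.shape[0],
    )
    part.validate()
    return part


def update_centers_rough(
    data: np.ndarray, partition: RoughPartition, w_low: float
) -> np.ndarray:
    """Weighted rough center update.

    ``center_i = w_low * mean(lower_i) + (1 - w_low) * mean(boundary
    points of upper_i)`` when both sets are populated; a cluster with no
    boundary members takes its lower mean (the plain k-means step), one
    with an empty lower set takes its upper mean, and a fully empty
    cluster keeps its previous center.
    """
    X = _as_features(data)
    old = _as_features(
        np.asarray(partition.centers, dtype=float).ravel()
        if np.ndim(partition.centers) == 1
        else partition.centers
    )
    boundary_mask = np.zeros(X.shape[0], dtype=bool)
    boundary_mask[np.asarray(partition.boundary, dtype=int)] = True
    new = old.copy()
    for i in range(old.shape[0]):
        low_idx = np.asarray(partition.lower[i], dtype=int)
        up_idx = np.asarray(partition.upper[i], dtype=int)
        bnd_idx = up_idx[boundary_mask[up_idx]]
        if low_idx.size and bnd_idx.size:
            new[i] = w_low * X[low_idx].mean(axis=0) + (1.0 - w_low) * X[bnd_idx].mean(axis=0)
        elif low_idx.size:
            new[i] = X[low_idx].mean(axis=0)
        elif up_idx.size:
            new[i] = X[up_idx].mean(axis=0)
        # both empty: keep the previous center
    return new.ravel() if np.ndim(partition.centers) == 1 else new


def knn_refine(data: np.ndarray, partition: RoughPartition, knn_k: int) -> np.ndarray:
    """Resolve boundary points by a KNN majority vote over lower-set points.

    Lower-approximation points keep their cluster labels; each boundary
    point is assigned the majority label among its ``knn_k`` nearest
    labeled points (Euclidean distance, unweighted vote). Vote ties are
    broken toward the cluster whose voting neighbors are nearer (larger
    summed inverse distance), then toward the lowest cluster index.
    Returns a crisp label per point.
    """
    X = _as_features(data)
    n = X.shape[0]
    k = len(partition.lower)
    labels = np.full(n, -1, dtype=int)
    for i in range(k):
        idx = np.asarray(partition.lower[i], dtype=int)
        if idx.size == 0:
            raise ValueError(
                f"cluster {i} has an empty lower approximation; "
                "lower the boundary_threshold so some points are certain members"
            )
        labels[idx] = i
    labeled_idx = np.flatnonzero(labels >= 0)
    labeled_X = X[labeled_idx]
    labeled_lab = labels[labeled_idx]
    kk = min(knn_k, labeled_idx.size)
    for j in np.asarray(partition.boundary, dtype=int):
        d = np.sqrt(((labeled_X - X[j]) ** 2).sum(axis=1))
        order = np.argsort(d, kind="stable")[:kk]
        votes = np.bincount(labeled_lab[order], minlength=k)
        top = votes.max()
        tied = np.flatnonzero(votes == top)
        if tied.size == 1:
            labels[j] = int(tied[0])
            continue
        inv = np.zeros(k)
        for o in order:
            inv[labeled_lab[o]] += 1.0 / max(d[o], 1e-300)
        best = tied[np.argmax(inv[tied])]
        # argmax returns the first maximum, so residual ties fall to the
        # lowest cluster index as required
        labels[j] = int(best)
    return labels


def build_harmony_memory(
    data: np.ndarray,
    rough_params: RoughParams,
    hs_params: HSParams,
    objective: ObjectiveFunction,
) -> HarmonyMemory:
    """Construct a data-driven harmony memory of candidate center vectors.

    The rough partition/update cycle runs until the maximum center shift
    drops to ``stop_threshold`` (or ``max_rounds`` is hit); the boundary
    region of the converged partition is then resolved by the KNN vote
    and each cluster's refined center is the mean of its crisp members.
    Row 1 of the memory is the refined center vector (sorted, matching
    the pipeline's canonical encoding); the remaining rows are small
    seeded Gaussian perturbations of it (sigma = 2% of each variable's
    range), clipped to bounds, giving the search population diversity
    around a good starting point.
    """
    X = _as_features(data)
    k = rough_params.k_clusters
    if hs_params.n_dims != k * X.shape[1]:
        raise ValueError(
            f"hs_params.n_dims={hs_params.n_dims} must equal "
            f"k_clusters * feature_dim = {k * X.shape[1]}"
        )
    centers = init_centers(data, k)
    for _ in range(rough_params.max_rounds):
        part = rough_assign(data, centers, rough_params.boundary_threshold)
        new_centers = update_centers_rough(data, part, rough_params.w_low)
        shift = float(np.max(np.abs(np.asarray(new_centers) - np.asarray(centers))))
        centers = new_centers
        if shift <= rough_params.stop_threshold:
            break

    if rough_params.max_rounds > 0:
        part = rough_assign(data, centers, rough_params.boundary_threshold)
        labels = knn_refine(data, part, rough_params.knn_k)
        refined = _as_features(
            np.asarray(centers, dtype=float).ravel() if np.ndim(centers) == 1 else centers
        ).copy()
        for i in range(k):
            members = np.flatnonzero(labels == i)
            if members.size:
                refined[i] = X[members].mean(axis=0)
        centers = refined.ravel() if np.ndim(data) == 1 or X.shape[1] == 1 else refined

    # the sorted encoding collapses center-permutation symmetry; it only
    # applies to scalar (grayscale) features
    scalar = X.shape[1] == 1
    row1 = np.asarray(centers, dtype=float).ravel()
    if scalar:
        row1 = np.sort(row1)
    rng = np.random.default_rng(rough_params.seed)
    sigma = 0.02 * (hs_params.upper_bound - hs_params.lower_bound)
    extra = row1[None, :] + rng.normal(0.0, 1.0, (hs_params.hms - 1, hs_params.n_dims)) * sigma
    extra = np.clip(extra, hs_params.lower_bound, hs_params.upper_bound)
    if scalar:
        extra = np.sort(extra, axis=1)
    vectors = np.vstack([row1[None, :], extra]) if hs_params.hms > 1 else row1[None, :]
    vectors = np.clip(vectors, hs_params.lower_bound, hs_params.upper_bound)
    return HarmonyMemory(vectors=vectors, fitness=_evaluate(objective, vectors))
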