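"""Fuzzy c-means clustering with partition-coefficient/entropy validity.

Fuzzy c-means (FCM) minimizes

    J_m(U, V) = sum_i sum_j u_ij^m d(x_j, v_i)^2,   sum_i u_ij = 1,

over a membership matrix ``U`` (c x n, columns sum to one) and centers
``V``, with fuzzifier ``m > 1`` and Euclidean distances ``d``. The two
closed-form coordinate updates — memberships from inverse squared
distances, centers as ``u^m``-weighted means — are alternated until the
centers stop moving. Partition coefficient ``Vpc`` and partition entropy
``Vpe`` score the crispness of the resulting fuzzy partition: higher
``Vpc`` / lower ``Vpe`` indicate better-separated clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Mapping

import numpy as np

__all__ = [
    "FCMParams",
    "FCMResult",
    "ValidityReport",
    "fcm_memberships",
    "fcm_centers",
    "fcm_objective",
    "run_fcm",
    "vpc",
    "vpe",
]


@dataclass(frozen=True)
class FCMParams:
    """Fuzzy c-means settings: cluster count, fuzzifier m, tolerance, budget."""

    c: int
    fuzzifier: float = 2.0
    epsilon: float = 1e-5
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 1:
            raise ValueError("c must be >= 1")
        if self.fuzzifier <= 1.0:
            raise ValueError("fuzzifier must be > 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    def to_dict(self) -> dict:
        return {
            "c": self.c,
            "fuzzifier": self.fuzzifier,
            "epsilon": self.epsilon,
            "max_iter": self.max_iter,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FCMParams":
        return cls(**dict(d))


@dataclass
class FCMResult:
    """Converged fuzzy partition: memberships U (c x n), centers, J trace."""

    memberships: np.ndarray
    centers: np.ndarray
    objective_trace: np.ndarray
    iterations: int
    converged: bool


@dataclass
class ValidityReport:
    """Partition validity scores of a fuzzy clustering.

    ``vpc`` lies in [1/c, 1] and ``vpe`` in [0, ln c] for any c-cluster
    partition; a crisp partition attains the extremes vpc = 1, vpe = 0.
    """

    vpc: float
    vpe: float
    iterations: int

    def to_dict(self) -> dict:
        return {"vpc": self.vpc, "vpe": self.vpe, "iterations": self.iterations}


def _as_features(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    return data[:, None] if data.ndim == 1 else data


def _sq_distances(data: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, shape (c, n)."""
    X = _as_features(data)
    V = _as_features(np.asarray(centers, dtype=float))
    diff = V[:, None, :] - X[None, :, :]
    return (diff**2).sum(axis=-1)


def fcm_memberships(data: np.ndarray, centers: np.ndarray, fuzzifier: float) -> np.ndarray:
    """Closed-form membership update from inverse squared distances.

    ``u_ij = (1/d_ij^2)^(1/(m-1)) / sum_k (1/d_kj^2)^(1/(m-1))``. A point
    coinciding with a center gets crisp membership there (split equally
    among coincident centers). Columns sum to one.
    """
    if fuzzifier <= 1.0:
        raise ValueError("fuzzifier must be > 1")
    d2 = _sq_distances(data, centers)
    c, n = d2.shape
    U = np.empty((c, n))
    zero = d2 <= 0.0
    singular = zero.any(axis=0)
    regular = ~singular
    if regular.any():
        with np.errstate(over="ignore"):
            inv = d2[:, regular] ** (-1.0 / (fuzzifier - 1.0))
        # near-coincident points can overflow to inf; resolve them crisply
        finite = np.isfinite(inv).all(axis=0)
        cols = np.flatnonzero(regular)
        good = cols[finite]
        U[:, good] = inv[:, finite] / inv[:, finite].sum(axis=0, keepdims=True)
        for j in cols[~finite]:
            col = np.zeros(c)
            nearest = d2[:, j] == d2[:, j].min()
            col[nearest] = 1.0 / nearest.sum()
            U[:, j] = col
    for j in np.flatnonzero(singular):
        col = np.zeros(c)
        hits = zero[:, j]
        col[hits] = 1.0 / hits.sum()
        U[:, j] = col
    return U


def fcm_centers(data: np.ndarray, memberships: np.ndarray, fuzzifier: float) -> np.ndarray:
    """Centers as ``u^m``-weighted means of the data."""
    X = _as_features(data)
    U = np.asarray(memberships, dtype=float)
    W = U**fuzzifier
    weight = W.sum(axis=1)
    empty = np.flatnonzero(weight == 0)
    if empty.size:
        raise ValueError(f"cluster {int(empty[0])} has zero total membership weight")
    V = (W @ X) / weight[:, None]
    return V.ravel() if np.asarray(data).ndim == 1 else V


def fcm_objective(
    data: np.ndarray, memberships: np.ndarray, centers: np.ndarray, fuzzifier: float
) -> float:
    """The fuzzified within-cluster scatter ``J_m = sum u^m d^2``."""
    d2 = _sq_distances(data, centers)
    U = np.asarray(memberships, dtype=float)
    return float((U**fuzzifier * d2).sum())


def run_fcm(
    data: np.ndarray,
    c: int,
    initial_centers: np.ndarray,
    params: FCMParams,
) -> FCMResult:
    """Alternate membership/center updates from the given initial centers.

    Stops when the maximum absolute center shift falls below
    ``params.epsilon`` or after ``params.max_iter`` passes. The returned
    memberships are recomputed from the final centers so that the stored
    (U, V) pair is self-consistent; the objective trace (one value per
    completed pass) is non-increasing.
    """
    initial_centers = np.asarray(initial_centers, dtype=float)
    if (initial_centers.shape[0] if initial_centers.ndim else 1) != c:
        raise ValueError(f"expected {c} initial centers, got {initial_centers.shape}")
    V = initial_centers.astype(float)
    trace: List[float] = []
    converged = False
    iterations = 0
    for _ in range(params.max_iter):
        U = fcm_memberships(data, V, params.fuzzifier)
        V_new = fcm_centers(data, U, params.fuzzifier)
        trace.append(fcm_objective(data, U, V_new, params.fuzzifier))
        shift = float(np.max(np.abs(np.asarray(V_new) - np.asarray(V))))
        V = V_new
        iterations += 1
        if shift < params.epsilon:
            converged = True
            break
    U = fcm_memberships(data, V, params.fuzzifier)
    return FCMResult(
        memberships=U,
        centers=V,
        objective_trace=np.asarray(trace),
        iterations=iterations,
        converged=converged,
    )


def vpc(memberships: np.ndarray) -> float:
    """Partition coefficient ``(1/n) sum_ij u_ij^2``; 1 for crisp, 1/c for uniform."""
    U = np.asarray(memberships, dtype=float)
    return float((U**2).sum() / U.shape[1])


def vpe(memberships: np.ndarray) -> float:
    """Partition entropy ``-(1/n) sum_ij u_ij ln u_ij`` with 0·ln 0 = 0."""
    U = np.asarray(memberships, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(U > 0, U * np.log(U), 0.0)
    return float(-terms.sum() / U.shape[1])
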