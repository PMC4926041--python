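"""Canonical harmony search over box-bounded continuous vectors.

Harmony search (HS) maintains a small population of candidate solution
vectors — the *harmony memory* (HM) — and repeatedly *improvises* a new
candidate by, per component, either copying a value from a random memory
row (probability HMCR, "memory consideration"), possibly perturbing it by
a random step of scale BW (probability PAR, "pitch adjustment"), or
drawing it uniformly within the variable's bounds ("random selection").
A candidate that beats the worst stored harmony replaces it.

This module implements the classic optimizer with constant PAR/BW; the
adaptive variant that schedules both parameters lives in
:mod:`harmonyseg.improved`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "HSParams",
    "HarmonyMemory",
    "HSRunResult",
    "initialize_memory",
    "improvise",
    "update_memory",
    "run_hs",
    "save_history_csv",
]

#: Objective contract: maps an in-bounds vector of length ``n_dims`` to a
#: finite scalar; smaller is better (minimization convention throughout).
ObjectiveFunction = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class HSParams:
    """Hyperparameters and variable bounds for a harmony search run.

    Parameters
    ----------
    n_dims
        Dimension of the solution vectors.
    lower_bound, upper_bound
        Box constraints; scalars are broadcast to length ``n_dims``.
    hms
        Harmony memory size (number of stored candidate vectors).
    hmcr
        Harmony memory considering rate — probability that a component is
        copied from memory rather than drawn uniformly at random.
    par_min, par_max
        Pitch adjusting rate range. The plain optimizer uses the constant
        ``par_max``; the adaptive variant ramps between the two.
    bw_min, bw_max
        Bandwidth (pitch-adjustment step scale) range, in the same units
        as the variables. The plain optimizer uses ``bw_max``.
    max_iterations
        Number of improvisation/update cycles.
    seed
        Seed of the generator owned by the run.
    """

    n_dims: int
    lower_bound: np.ndarray
    upper_bound: np.ndarray
    hms: int = 30
    hmcr: float = 0.9
    par_min: float = 0.3
    par_max: float = 0.9
    bw_min: float = 0.01
    bw_max: float = 0.1
    max_iterations: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dims < 1:
            raise ValueError("n_dims must be a positive integer")
        if self.hms < 1:
            raise ValueError("hms must be a positive integer")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be a positive integer")
        lb = np.broadcast_to(np.asarray(self.lower_bound, dtype=float), (self.n_dims,)).copy()
        ub = np.broadcast_to(np.asarray(self.upper_bound, dtype=float), (self.n_dims,)).copy()
        lb.setflags(write=False)
        ub.setflags(write=False)
        object.__setattr__(self, "lower_bound", lb)
        object.__setattr__(self, "upper_bound", ub)
        if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
            raise ValueError("bounds must be finite")
        if np.any(lb > ub):
            raise ValueError("lower_bound must be <= upper_bound elementwise")
        for name in ("hmcr", "par_min", "par_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.par_min > self.par_max:
            raise ValueError("par_min must be <= par_max")
        if not (self.bw_min > 0 and self.bw_max > 0):
            raise ValueError("bandwidths must be positive")
        if self.bw_min > self.bw_max:
            raise ValueError("bw_min must be <= bw_max")

    def to_dict(self) -> dict:
        """Serialize to a plain mapping (bounds as lists) for YAML/JSON."""
        return {
            "n_dims": self.n_dims,
            "lower_bound": self.lower_bound.tolist(),
            "upper_bound": self.upper_bound.tolist(),
            "hms": self.hms,
            "hmcr": self.hmcr,
            "par_min": self.par_min,
            "par_max": self.par_max,
            "bw_min": self.bw_min,
            "bw_max": self.bw_max,
            "max_iterations": self.max_iterations,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "HSParams":
        return cls(**dict(d))


@dataclass
class HarmonyMemory:
    """The HM matrix of candidate vectors with cached objective values.

    ``vectors`` has shape ``(hms, n_dims)``; ``fitness[j]`` caches the
    objective evaluated on row ``j``. ``best_index`` minimizes fitness and
    ``worst_index`` maximizes it.
    """

    vectors: np.ndarray
    fitness: np.ndarray
    best_index: int = field(init=False)
    worst_index: int = field(init=False)

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        self.fitness = np.asarray(self.fitness, dtype=float)
        if self.fitness.shape != (self.vectors.shape[0],):
            raise ValueError("fitness length must equal number of memory rows")
        self._refresh_indices()

    def _refresh_indices(self) -> None:
        self.best_index = int(np.argmin(self.fitness))
        self.worst_index = int(np.argmax(self.fitness))

    @property
    def best_vector(self) -> np.ndarray:
        return self.vectors[self.best_index]

    @property
    def worst_vector(self) -> np.ndarray:
        return self.vectors[self.worst_index]

    @property
    def best_fitness(self) -> float:
        return float(self.fitness[self.best_index])

    @property
    def worst_fitness(self) -> float:
        return float(self.fitness[self.worst_index])


def _evaluate(objective: ObjectiveFunction, vectors: np.ndarray) -> np.ndarray:
    fitness = np.empty(vectors.shape[0])
    for j, row in enumerate(vectors):
        val = float(objective(row))
        if not np.isfinite(val):
            raise ValueError(
                f"objective returned non-finite value {val!r} at in-bounds point {row.tolist()}"
            )
        fitness[j] = val
    return fitness


def initialize_memory(
    params: HSParams,
    objective: ObjectiveFunction,
    rng: Optional[np.random.Generator] = None,
) -> HarmonyMemory:
    """Fill the harmony memory with ``hms`` i.i.d. uniform in-bounds rows.

    Each component is drawn as ``x_i = x^L_i + rand * (x^U_i - x^L_i)``.
    Reproducible from ``params.seed`` when ``rng`` is not supplied.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    span = params.upper_bound - params.lower_bound
    vectors = params.lower_bound + rng.random((params.hms, params.n_dims)) * span
    return HarmonyMemory(vectors=vectors, fitness=_evaluate(objective, vectors))


def improvise(
    memory: HarmonyMemory,
    params: HSParams,
    par: float,
    bw: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generate one new candidate vector from the memory.

    Per dimension: with probability ``hmcr`` copy the component from a
    uniformly chosen memory row, then with probability ``par`` perturb it
    by ``± rand * bw`` (sign uniform); otherwise draw uniformly within the
    bounds. The result is clipped to the box, so pitch adjustment can
    never step outside it.

    The random stream is consumed in a fixed order (six draws of length
    ``n_dims``: memory-consideration coin, row index, pitch coin, sign,
    step magnitude, uniform fallback) regardless of which branches fire,
    so seeded runs are bit-reproducible.
    """
    if not 0.0 <= par <= 1.0:
        raise ValueError("par must lie in [0, 1]")
    if bw <= 0:
        raise ValueError("bw must be positive")
    n = params.n_dims
    lb, ub = params.lower_bound, params.upper_bound

    u_mem = rng.random(n)
    rows = rng.integers(0, memory.vectors.shape[0], size=n)
    u_par = rng.random(n)
    signs = rng.integers(0, 2, size=n) * 2 - 1
    steps = rng.random(n)
    u_rand = rng.random(n)

    from_memory = u_mem <= params.hmcr
    candidate = np.where(
        from_memory,
        memory.vectors[rows, np.arange(n)],
        lb + u_rand * (ub - lb),
    )
    adjusted = from_memory & (u_par <= par)
    candidate = np.where(adjusted, candidate + signs * steps * bw, candidate)
    return np.clip(candidate, lb, ub)


def update_memory(
    memory: HarmonyMemory,
    candidate: np.ndarray,
    objective: ObjectiveFunction,
    params: Optional[HSParams] = None,
) -> HarmonyMemory:
    """Replace the worst row with ``candidate`` if the candidate is strictly better.

    Ties keep the incumbent. The worst fitness is therefore non-increasing
    across calls and the best row can never be evicted. Returns the
    (mutated) memory.
    """
    candidate = np.asarray(candidate, dtype=float)
    if params is not None and (
        np.any(candidate < params.lower_bound) or np.any(candidate > params.upper_bound)
    ):
        raise ValueError("candidate lies outside the variable bounds")
    value = float(objective(candidate))
    if not np.isfinite(value):
        raise ValueError(f"objective returned non-finite value at {candidate.tolist()}")
    if value < memory.worst_fitness:
        memory.vectors[memory.worst_index] = candidate
        memory.fitness[memory.worst_index] = value
        memory._refresh_indices()
    return memory


@dataclass
class HSRunResult:
    """Outcome of an optimizer run: incumbent, its fitness and the trace."""

    best_vector: np.ndarray
    best_fitness: float
    history: dict
    memory: HarmonyMemory
    iterations: int


def run_hs(
    params: HSParams,
    objective: ObjectiveFunction,
    par_schedule: Optional[Callable[[int, HarmonyMemory], float]] = None,
    bw_schedule: Optional[Callable[[int, HarmonyMemory], float]] = None,
) -> HSRunResult:
    """Run harmony search for ``params.max_iterations`` improvisations.

    ``par_schedule`` / ``bw_schedule`` map ``(iteration, memory)`` to the
    PAR / BW used for that iteration; omitted schedules default to the
    constants ``par_max`` and ``bw_max``. History arrays (``best``,
    ``worst``, ``mean`` fitness per iteration) have length
    ``max_iterations``; the best-fitness trace is non-increasing.
    """
    rng = np.random.default_rng(params.seed)
    memory = initialize_memory(params, objective, rng)
    t_max = params.max_iterations
    best = np.empty(t_max)
    worst = np.empty(t_max)
    mean = np.empty(t_max)
    for t in range(t_max):
        par = params.par_max if par_schedule is None else par_schedule(t, memory)
        bw = params.bw_max if bw_schedule is None else bw_schedule(t, memory)
        candidate = improvise(memory, params, par, bw, rng)
        try:
            update_memory(memory, candidate, objective, params)
        except ValueError as err:
            raise ValueError(f"objective failed at iteration {t}: {err}") from err
        best[t] = memory.best_fitness
        worst[t] = memory.worst_fitness
        mean[t] = float(memory.fitness.mean())
    history = {"iteration": np.arange(t_max), "best": best, "worst": worst, "mean": mean}
    return HSRunResult(
        best_vector=memory.best_vector.copy(),
        best_fitness=memory.best_fitness,
        history=history,
        memory=memory,
        iterations=t_max,
    )


def save_history_csv(history: Mapping[str, Sequence], path) -> None:
    """Write a run history to CSV with one column per history key."""
    keys = list(history)
    length = len(history[keys[0]])
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(keys)
        for i in range(length):
            writer.writerow([history[k][i] for k in keys])
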