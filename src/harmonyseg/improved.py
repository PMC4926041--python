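"""Adaptive harmony search: data-driven memory plus PAR/BW schedules.

The improved optimizer differs from the canonical one in three ways:

1. its harmony memory is built from the data by the rough-set/KNN
   construction in :mod:`harmonyseg.rough` rather than sampled uniformly;
2. the pitch adjusting rate ramps linearly from ``par_min`` to
   ``par_max`` over the run, so early iterations exploit memory while
   late iterations keep adjusting;
3. the bandwidth reacts to a feedback statistic computed from the spread
   between the best and worst stored harmonies, widening the step while
   the memory is diverse and pinning it to ``bw_max`` once the feedback
   magnitude crosses half the iteration budget.

The run terminates early once the feedback statistic collapses to the
configured stopping level (the memory has effectively converged).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .hs import HSParams, HarmonyMemory, ObjectiveFunction, improvise, update_memory
from .rough import RoughParams, build_harmony_memory

__all__ = [
    "ScheduleState",
    "adapt_par",
    "feedback_T",
    "adapt_bw",
    "run_improved_hs",
    "ImprovedHSResult",
]


@dataclass
class ScheduleState:
    """Snapshot of the adaptive schedules at one iteration."""

    t: int
    t_max: int
    feedback: float
    par: float
    bw: float

    def __post_init__(self) -> None:
        if not 0 <= self.t <= self.t_max:
            raise ValueError("t must lie in [0, t_max]")
        if self.feedback < 0:
            raise ValueError("feedback must be non-negative")


def adapt_par(t: int, t_max: int, par_min: float, par_max: float) -> float:
    """Linear pitch-adjusting-rate ramp: ``par_min`` at t=0, ``par_max`` at t=t_max."""
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    if not 0 <= t <= t_max:
        raise ValueError(f"iteration t={t} outside [0, {t_max}]")
    return par_min + (par_max - par_min) * t / t_max


def feedback_T(memory: HarmonyMemory) -> float:
    """Spread statistic between the best and worst stored harmonies.

    ``T = sum_i |x_best,i - x_worst,i| / sum_i (x_best,i - x_worst,i)^2``.
    Returns 0 for a fully collapsed memory (best equals worst), which is
    the early-termination signal. Scaling all memory vectors by ``s``
    scales the statistic by ``1/s``.
    """
    diff = memory.best_vector - memory.worst_vector
    denom = float(np.sum(diff**2))
    if denom == 0.0:
        return 0.0
    return float(np.sum(np.abs(diff)) / denom)


def adapt_bw(feedback: float, t: int, t_max: int, bw_min: float, bw_max: float) -> float:
    """Two-regime bandwidth schedule driven by the feedback statistic.

    While ``feedback < t_max / 2`` the bandwidth grows as
    ``bw_min + (bw_max - bw_min) * feedback * t / t_max`` (clamped to the
    configured range); once the feedback magnitude reaches ``t_max / 2``
    the bandwidth is held at ``bw_max``.
    """
    if feedback < 0:
        raise ValueError("feedback must be non-negative")
    if not 0 <= t <= t_max:
        raise ValueError(f"iteration t={t} outside [0, {t_max}]")
    if feedback >= t_max / 2.0:
        return bw_max
    bw = bw_min + (bw_max - bw_min) * (feedback * t) / t_max
    return float(np.clip(bw, bw_min, bw_max))


@dataclass
class ImprovedHSResult:
    """Outcome of an adaptive run with the per-iteration schedule trace."""

    best_vector: np.ndarray
    best_fitness: float
    history: dict
    memory: HarmonyMemory
    iterations: int
    terminated_early: bool


def run_improved_hs(
    data: np.ndarray,
    rough_params: RoughParams,
    hs_params: HSParams,
    objective: ObjectiveFunction,
    memory: Optional[HarmonyMemory] = None,
) -> ImprovedHSResult:
    """Run the improved optimizer on ``data``.

    Builds the rough-set harmony memory (unless one is supplied), then
    iterates improvisation/update with the adaptive PAR and BW schedules.
    Each iteration records ``(best, worst, mean, par, bw, feedback)``.
    Stops at ``hs_params.max_iterations`` or as soon as the feedback
    statistic drops to ``rough_params.stop_threshold``.
    """
    if memory is None:
        memory = build_harmony_memory(data, rough_params, hs_params, objective)
    rng = np.random.default_rng(hs_params.seed)
    t_max = hs_params.max_iterations
    cols = {k: [] for k in ("iteration", "best", "worst", "mean", "par", "bw", "feedback")}
    terminated_early = False
    iterations = 0
    for t in range(t_max):
        par = adapt_par(t, t_max, hs_params.par_min, hs_params.par_max)
        fb = feedback_T(memory)
        if fb <= rough_params.stop_threshold:
            terminated_early = True
            break
        bw = adapt_bw(fb, t, t_max, hs_params.bw_min, hs_params.bw_max)
        assert hs_params.par_min <= par <= hs_params.par_max
        assert hs_params.bw_min <= bw <= hs_params.bw_max
        candidate = improvise(memory, hs_params, par, bw, rng)
        try:
            update_memory(memory, candidate, objective, hs_params)
        except ValueError as err:
            raise ValueError(f"objective failed at iteration {t}: {err}") from err
        iterations = t + 1
        cols["iteration"].append(t)
        cols["best"].append(memory.best_fitness)
        cols["worst"].append(memory.worst_fitness)
        cols["mean"].append(float(memory.fitness.mean()))
        cols["par"].append(par)
        cols["bw"].append(bw)
        cols["feedback"].append(fb)
    history = {k: np.asarray(v) for k, v in cols.items()}
    return ImprovedHSResult(
        best_vector=memory.best_vector.copy(),
        best_fitness=memory.best_fitness,
        history=history,
        memory=memory,
        iterations=iterations,
        terminated_early=terminated_early,
    )
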