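"""Opposition-based learning (OBL) and the mSAR optimizer.

OBL evaluates, for each agent at x, the reflected point
``lb + ub - x`` and keeps whichever of the pair is fitter.  mSAR wraps
the SAR operators in a three-phase schedule: after an OBL-improved
initialization, every iteration first applies the opposite-population
greedy selection, then moves each agent with

* the social phase while ``t < T/3``,
* the individual phase (greedy memory saving) while ``T/3 <= t < 2T/3``,
* an opposition jump (greedy acceptance of the opposite point) for the
  final third,

followed by restart checks and best-so-far bookkeeping.  The schedule
concentrates directed exploration early and diversifying reflection
late; all acceptances are greedy, so the convergence curve is monotone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .sar import (
    Bounds,
    OptimizationResult,
    PopulationState,
    SarConfig,
    _Evaluator,
    epsilon_better,
    greedy_memory_update,
    init_state,
    repair_bounds,
    restart_if_stuck,
    run_sar,
    sar_iteration,
    social_phase,
    individual_phase,
    _clues_from_state,
)

__all__ = ["OblConfig", "opposite", "obl_select", "run_msar"]


@dataclass(frozen=True)
class OblConfig:
    """OBL behaviour.

    ``mode`` controls the opposite-population selection: every iteration
    (default, the most specific published schedule), only at
    initialization, or disabled.  ``schedule_enabled`` switches the
    three-phase move schedule; off, every iteration is a full SAR sweep.
    ``final_third_supplement`` additionally runs the social+individual
    sweep in the last third instead of replacing it with the opposition
    jump alone.
    """

    mode: Literal["per_iteration", "init_only", "disabled"] = "per_iteration"
    schedule_enabled: bool = True
    final_third_supplement: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("per_iteration", "init_only", "disabled"):
            raise ValueError("mode must be per_iteration, init_only or disabled")


def opposite(x: np.ndarray, bounds: Bounds) -> np.ndarray:
    """Opposite point ``lower + upper - x`` (an exact involution)."""
    x = np.asarray(x, dtype=float)
    if not bounds.contains(x):
        raise ValueError("x must lie within bounds")
    return bounds.lower + bounds.upper - x


def obl_select(
    state: PopulationState,
    bounds: Bounds,
    evaluator: Callable[[np.ndarray], tuple[float, float]],
    config: SarConfig,
) -> PopulationState:
    """Replace each agent by its opposite point iff strictly better."""
    for j in range(state.positions.shape[0]):
        # positions are in bounds by invariant; skip opposite()'s check
        opp = bounds.lower + bounds.upper - state.positions[j]
        f, g = evaluator(opp)
        if epsilon_better(f, g, state.fitness[j], state.violations[j],
                          config.eps, config.sense):
            state.positions[j] = opp
            state.fitness[j] = f
            state.violations[j] = g
            if epsilon_better(f, g, state.best_fitness, state.best_violation,
                              config.eps, config.sense):
                state.best_position = opp.copy()
                state.best_fitness = f
                state.best_violation = g
    return state


def _scheduled_move(
    t: int,
    state: PopulationState,
    evaluator: Callable[[np.ndarray], tuple[float, float]],
    bounds: Bounds,
    config: SarConfig,
    obl: OblConfig,
    rng: np.random.Generator,
) -> None:
    third = config.max_iters / 3.0
    if t < third:
        phase = "social"
    elif t < 2.0 * third:
        phase = "individual"
    else:
        phase = "opposition"

    for j in range(config.pop_size):
        if phase in ("social", "individual") or obl.final_third_supplement:
            clue = _clues_from_state(state)
            if phase == "social" or obl.final_third_supplement:
                cand = social_phase(j, state, clue, config, rng)
            else:
                cand = individual_phase(j, state, clue, rng)
            cand = repair_bounds(cand, state.positions[j], bounds)
            f, g = evaluator(cand)
            greedy_memory_update(j, cand, f, state, rng, config, g)
        if phase == "opposition":
            cand = bounds.lower + bounds.upper - state.positions[j]
            f, g = evaluator(cand)
            greedy_memory_update(j, cand, f, state, rng, config, g)
        restart_if_stuck(j, state, bounds, config, rng, evaluator)


def run_msar(
    objective: Callable,
    bounds: Bounds,
    config: SarConfig | None = None,
    obl: OblConfig | None = None,
) -> OptimizationResult:
    """Run mSAR (SAR + opposition-based learning).

    With ``obl.mode='disabled'`` and ``schedule_enabled=False`` the run
    is bitwise identical to :func:`msar.sar.run_sar` at equal seed.
    """
    config = config or SarConfig()
    obl = obl or OblConfig()

    if obl.mode == "disabled" and not obl.schedule_enabled:
        res = run_sar(objective, bounds, config)
        res.meta.update({"obl_mode": "disabled", "schedule_enabled": False})
        return res

    rng = np.random.default_rng(config.seed)
    evaluator = _Evaluator(objective)
    state = init_state(evaluator, bounds, config, rng)
    if obl.mode != "disabled":
        obl_select(state, bounds, evaluator, config)

    convergence = np.empty(config.max_iters)
    for t in range(config.max_iters):
        state.iteration = t
        if obl.mode == "per_iteration":
            obl_select(state, bounds, evaluator, config)
        if obl.schedule_enabled:
            _scheduled_move(t, state, evaluator, bounds, config, obl, rng)
        else:
            sar_iteration(state, evaluator, bounds, config, rng)
        convergence[t] = state.best_fitness

    third = config.max_iters / 3.0
    return OptimizationResult(
        best_position=state.best_position.copy(),
        best_fitness=float(state.best_fitness),
        convergence=convergence,
        evaluations=evaluator.count,
        seed=config.seed,
        meta={
            "algorithm": "msar",
            "sense": config.sense,
            "obl_mode": obl.mode,
            "schedule_enabled": obl.schedule_enabled,
            "phase_ranges": {
                "social": [0, int(np.ceil(third)) - 1],
                "individual": [int(np.ceil(third)), int(np.ceil(2 * third)) - 1],
                "opposition": [int(np.ceil(2 * third)), config.max_iters - 1],
            },
        },
    )
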