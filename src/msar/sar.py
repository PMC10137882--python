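"""Search-and-rescue optimization (SAR).

SAR is a population metaheuristic modelled on how human search teams
operate: a group of M agents explores an N-dimensional box, each agent
keeping a *position* (where it currently searches) while a *memory
matrix* of the same shape retains abandoned positions ("left clues").
The vertical stack of both — the clue matrix Z (2M x N) — is the pool
of reference points from which moves are generated:

* social phase   — move along the direction from a random clue,
  dimension-wise with probability SE (plus one forced dimension), the
  direction flipping depending on whether the clue is fitter than the
  agent;
* individual phase — step from the current position along the
  difference of two distinct random clues.

Candidates are clipped back into the box by midpoint repair, accepted
greedily (the displaced position is stored in a random memory row), and
agents that fail to improve for more than ``mu_max`` consecutive
candidates restart uniformly in the box.  An epsilon-constrained
comparison generalizes "better" to constrained problems: violations up
to ``eps`` are forgiven, otherwise the smaller violation wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "Bounds",
    "SarConfig",
    "PopulationState",
    "ClueMatrix",
    "OptimizationResult",
    "build_clue_matrix",
    "social_phase",
    "individual_phase",
    "repair_bounds",
    "epsilon_better",
    "greedy_memory_update",
    "restart_if_stuck",
    "run_sar",
]

Sense = Literal["maximize", "minimize"]


@dataclass(frozen=True)
class Bounds:
    """Box constraints: ``lower[i] < upper[i]`` for every dimension."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.atleast_1d(np.asarray(self.lower, dtype=float))
        up = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if lo.shape != up.shape or lo.ndim != 1:
            raise ValueError("lower and upper must be 1-D vectors of equal length")
        if not (np.isfinite(lo).all() and np.isfinite(up).all()):
            raise ValueError("bounds must be finite")
        if not np.all(lo < up):
            raise ValueError("require lower[i] < upper[i] for all i")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)

    @property
    def dim(self) -> int:
        return self.lower.size

    def contains(self, x: np.ndarray, atol: float = 0.0) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(np.all(x >= self.lower - atol) and np.all(x <= self.upper + atol))

    def sample(self, rng: np.random.Generator, m: int | None = None) -> np.ndarray:
        size = self.dim if m is None else (m, self.dim)
        return rng.uniform(self.lower, self.upper, size=size)

    @staticmethod
    def cube(lower: float, upper: float, dim: int) -> "Bounds":
        return Bounds(np.full(dim, float(lower)), np.full(dim, float(upper)))


@dataclass(frozen=True)
class SarConfig:
    """Run parameters.

    Defaults follow the reference experimental setup: population of 50,
    350 iterations, social-effect probability SE = 0.05.  ``mu_max`` is
    the restart patience (consecutive unsuccessful candidates tolerated
    before an agent is re-drawn uniformly). ``mutation_ratio_p`` is
    carried for configuration completeness but drives no operator.
    """

    pop_size: int = 50
    se: float = 0.05
    mu_max: int = 15
    max_iters: int = 350
    sense: Sense = "maximize"
    eps: float = 0.0
    mutation_ratio_p: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2 (social phase needs a distinct clue)")
        if not 0.0 <= self.se <= 1.0:
            raise ValueError("se must lie in [0, 1]")
        if self.mu_max < 1:
            raise ValueError("mu_max must be a positive integer")
        if self.max_iters < 1:
            raise ValueError("max_iters must be a positive integer")
        if self.sense not in ("maximize", "minimize"):
            raise ValueError("sense must be 'maximize' or 'minimize'")
        if self.eps < 0:
            raise ValueError("eps must be nonnegative")
        if not 0.0 <= self.mutation_ratio_p <= 1.0:
            raise ValueError("mutation_ratio_p must lie in [0, 1]")


@dataclass
class PopulationState:
    """Mutable bookkeeping for one SAR run.

    ``positions`` holds the current solutions X, ``memory`` the matrix of
    abandoned positions; both are M x N.  Fitness (and constraint
    violation) caches are kept for every row of each, so clue-matrix
    comparisons never re-evaluate the objective.  ``usn`` counts each
    agent's consecutive unsuccessful searches.
    """

    positions: np.ndarray
    memory: np.ndarray
    fitness: np.ndarray
    memory_fitness: np.ndarray
    violations: np.ndarray
    memory_violations: np.ndarray
    usn: np.ndarray
    best_position: np.ndarray
    best_fitness: float
    best_violation: float
    iteration: int = 0


@dataclass(frozen=True)
class ClueMatrix:
    """The 2M x N stack of positions (rows 0..M-1) then memory rows."""

    rows: np.ndarray
    fitness: np.ndarray
    violations: np.ndarray


@dataclass(frozen=True)
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    convergence: np.ndarray
    evaluations: int
    seed: int
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "best_position": [float(v) for v in self.best_position],
            "best_fitness": float(self.best_fitness),
            "convergence": [float(v) for v in self.convergence],
            "evaluations": int(self.evaluations),
            "seed": int(self.seed),
            "meta": dict(self.meta),
        }


class _Evaluator:
    """Wraps an objective callback returning ``f`` or ``(f, violation)``."""

    def __init__(self, objective: Callable):
        self.objective = objective
        self.count = 0

    def __call__(self, x: np.ndarray) -> tuple[float, float]:
        out = self.objective(np.asarray(x, dtype=float))
        if isinstance(out, tuple):
            f, g = float(out[0]), float(out[1])
        else:
            f, g = float(out), 0.0
        if not np.isfinite(f):
            raise FloatingPointError(
                f"objective returned non-finite value {f!r} at x={np.asarray(x)!r}"
            )
        if g < 0:
            raise ValueError("constraint violation must be nonnegative")
        self.count += 1
        return f, g


def build_clue_matrix(
    positions: np.ndarray,
    memory: np.ndarray,
    fitness: np.ndarray | None = None,
    memory_fitness: np.ndarray | None = None,
    violations: np.ndarray | None = None,
    memory_violations: np.ndarray | None = None,
) -> ClueMatrix:
    """Stack positions on top of memory into the 2M x N clue matrix."""
    positions = np.asarray(positions, dtype=float)
    memory = np.asarray(memory, dtype=float)
    if positions.shape != memory.shape or positions.ndim != 2:
        raise ValueError(
            f"positions {positions.shape} and memory {memory.shape} must be equal-shape 2-D"
        )
    m = positions.shape[0]
    fit = np.concatenate(
        [
            np.full(m, np.nan) if fitness is None else np.asarray(fitness, float),
            np.full(m, np.nan) if memory_fitness is None else np.asarray(memory_fitness, float),
        ]
    )
    vio = np.concatenate(
        [
            np.zeros(m) if violations is None else np.asarray(violations, float),
            np.zeros(m) if memory_violations is None else np.asarray(memory_violations, float),
        ]
    )
    return ClueMatrix(rows=np.vstack([positions, memory]), fitness=fit, violations=vio)


def _clues_from_state(state: PopulationState) -> ClueMatrix:
    return build_clue_matrix(
        state.positions,
        state.memory,
        state.fitness,
        state.memory_fitness,
        state.violations,
        state.memory_violations,
    )


def epsilon_better(
    f2: float,
    g2: float,
    f1: float,
    g1: float,
    eps: float = 0.0,
    sense: Sense = "maximize",
) -> bool:
    """Is solution 2 (f2, g2) strictly better than solution 1 (f1, g1)?

    Epsilon-constrained lexicographic comparison: if both violations are
    within ``eps`` (or exactly equal) compare fitness under ``sense``;
    otherwise the smaller violation wins.  With g1 = g2 = 0 this is a
    plain strict fitness comparison.
    """
    if g1 < 0 or g2 < 0:
        raise ValueError("constraint violations must be nonnegative")
    if (g1 <= eps and g2 <= eps) or g1 == g2:
        if sense == "maximize":
            return f2 > f1
        return f2 < f1
    return g2 < g1


def _draw_excluding(rng: np.random.Generator, n: int, excluded: Sequence[int]) -> int:
    """Uniform draw from {0..n-1} minus ``excluded`` with one rng call."""
    excluded = sorted(set(excluded))
    k = int(rng.integers(n - len(excluded)))
    for e in excluded:
        if k >= e:
            k += 1
    return k


def social_phase(
    j: int,
    state: PopulationState,
    clue: ClueMatrix,
    config: SarConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Social-phase candidate for agent ``j``.

    A clue row k != j is drawn; a single r1 ~ U[-1, 1] is shared across
    dimensions; each dimension updates when its own r2 ~ U[0, 1] falls
    below SE, and dimension ``irand`` updates unconditionally so the
    candidate differs from X_j in at least one coordinate.
    """
    n_clues = clue.rows.shape[0]
    if n_clues < 2:
        raise ValueError("social phase needs at least two clue rows")
    x = state.positions[j]
    ndim = x.size
    k = _draw_excluding(rng, n_clues, [j])
    r1 = float(rng.uniform(-1.0, 1.0))
    r2 = rng.uniform(0.0, 1.0, size=ndim)
    irand = int(rng.integers(ndim))
    zk = clue.rows[k]
    clue_is_better = epsilon_better(
        clue.fitness[k], clue.violations[k], state.fitness[j], state.violations[j],
        config.eps, config.sense,
    )
    if clue_is_better:
        moved = zk + r1 * (x - zk)
    else:
        moved = x + r1 * (x - zk)
    mask = r2 < config.se
    mask[irand] = True
    return np.where(mask, moved, x)


def individual_phase(
    j: int,
    state: PopulationState,
    clue: ClueMatrix,
    rng: np.random.Generator,
) -> np.ndarray:
    """Individual-phase candidate: X_j + r3 * (Z_k - Z_m), j, k, m distinct."""
    n_clues = clue.rows.shape[0]
    if n_clues < 3:
        raise ValueError("individual phase needs at least three clue rows")
    k = _draw_excluding(rng, n_clues, [j])
    m = _draw_excluding(rng, n_clues, [j, k])
    r3 = float(rng.uniform(0.0, 1.0))
    return state.positions[j] + r3 * (clue.rows[k] - clue.rows[m])


def repair_bounds(candidate: np.ndarray, current: np.ndarray, bounds: Bounds) -> np.ndarray:
    """Midpoint repair: an out-of-box coordinate is replaced by the mean
    of the current (in-box) coordinate and the violated bound."""
    candidate = np.asarray(candidate, dtype=float)
    current = np.asarray(current, dtype=float)
    out = candidate.copy()
    over = candidate > bounds.upper
    under = candidate < bounds.lower
    out[over] = (current[over] + bounds.upper[over]) / 2.0
    out[under] = (current[under] + bounds.lower[under]) / 2.0
    return out


def greedy_memory_update(
    j: int,
    candidate: np.ndarray,
    candidate_fitness: float,
    state: PopulationState,
    rng: np.random.Generator,
    config: SarConfig,
    candidate_violation: float = 0.0,
) -> PopulationState:
    """Greedy acceptance with memory saving.

    An improving candidate replaces X_j, whose old value is written to a
    uniformly random memory row; otherwise only the unsuccessful-search
    counter grows. The incumbent best is refreshed in place.
    """
    if epsilon_better(
        candidate_fitness, candidate_violation,
        state.fitness[j], state.violations[j],
        config.eps, config.sense,
    ):
        m = state.positions.shape[0]
        n = int(rng.integers(m))
        state.memory[n] = state.positions[j].copy()
        state.memory_fitness[n] = state.fitness[j]
        state.memory_violations[n] = state.violations[j]
        state.positions[j] = np.asarray(candidate, dtype=float)
        state.fitness[j] = candidate_fitness
        state.violations[j] = candidate_violation
        state.usn[j] = 0
        if epsilon_better(
            candidate_fitness, candidate_violation,
            state.best_fitness, state.best_violation,
            config.eps, config.sense,
        ):
            state.best_position = state.positions[j].copy()
            state.best_fitness = candidate_fitness
            state.best_violation = candidate_violation
    else:
        state.usn[j] += 1
    return state


def restart_if_stuck(
    j: int,
    state: PopulationState,
    bounds: Bounds,
    config: SarConfig,
    rng: np.random.Generator,
    evaluator: Callable[[np.ndarray], tuple[float, float]] | None = None,
) -> PopulationState:
    """Re-draw agent ``j`` uniformly when usn[j] exceeds mu_max (strict)."""
    if state.usn[j] <= config.mu_max:
        return state
    state.positions[j] = bounds.sample(rng)
    state.usn[j] = 0
    if evaluator is not None:
        f, g = evaluator(state.positions[j])
        state.fitness[j] = f
        state.violations[j] = g
        if epsilon_better(f, g, state.best_fitness, state.best_violation,
                          config.eps, config.sense):
            state.best_position = state.positions[j].copy()
            state.best_fitness = f
            state.best_violation = g
    return state


def init_state(
    evaluator: Callable[[np.ndarray], tuple[float, float]],
    bounds: Bounds,
    config: SarConfig,
    rng: np.random.Generator,
) -> PopulationState:
    """Random initial population; memory starts as a copy of it (with its
    fitness caches), so no extra evaluations are spent on initialization."""
    positions = bounds.sample(rng, config.pop_size)
    fitness = np.empty(config.pop_size)
    violations = np.empty(config.pop_size)
    for j in range(config.pop_size):
        fitness[j], violations[j] = evaluator(positions[j])
    best = 0
    for j in range(1, config.pop_size):
        if epsilon_better(fitness[j], violations[j], fitness[best], violations[best],
                          config.eps, config.sense):
            best = j
    return PopulationState(
        positions=positions,
        memory=positions.copy(),
        fitness=fitness,
        memory_fitness=fitness.copy(),
        violations=violations,
        memory_violations=violations.copy(),
        usn=np.zeros(config.pop_size, dtype=int),
        best_position=positions[best].copy(),
        best_fitness=float(fitness[best]),
        best_violation=float(violations[best]),
    )


def sar_iteration(
    state: PopulationState,
    evaluator: Callable[[np.ndarray], tuple[float, float]],
    bounds: Bounds,
    config: SarConfig,
    rng: np.random.Generator,
) -> None:
    """One full SAR sweep: per agent a social then an individual candidate,
    each repaired, evaluated and greedily accepted; restart check after both."""
    for j in range(config.pop_size):
        clue = _clues_from_state(state)
        cand = social_phase(j, state, clue, config, rng)
        cand = repair_bounds(cand, state.positions[j], bounds)
        f, g = evaluator(cand)
        greedy_memory_update(j, cand, f, state, rng, config, g)

        clue = _clues_from_state(state)
        cand = individual_phase(j, state, clue, rng)
        cand = repair_bounds(cand, state.positions[j], bounds)
        f, g = evaluator(cand)
        greedy_memory_update(j, cand, f, state, rng, config, g)

        restart_if_stuck(j, state, bounds, config, rng, evaluator)


def run_sar(
    objective: Callable,
    bounds: Bounds,
    config: SarConfig | None = None,
) -> OptimizationResult:
    """Run SAR on ``objective`` over the box ``bounds``.

    The objective maps a length-N vector to a fitness (optionally a
    ``(fitness, violation)`` pair).  Deterministic given ``config.seed``:
    a single generator drives all draws in a fixed order (per agent:
    social k, r1, r2 vector, irand, memory row; then individual k, m,
    r3, memory row; then restart draws).
    """
    config = config or SarConfig()
    rng = np.random.default_rng(config.seed)
    evaluator = _Evaluator(objective)
    state = init_state(evaluator, bounds, config, rng)
    convergence = np.empty(config.max_iters)
    for t in range(config.max_iters):
        state.iteration = t
        sar_iteration(state, evaluator, bounds, config, rng)
        convergence[t] = state.best_fitness
    return OptimizationResult(
        best_position=state.best_position.copy(),
        best_fitness=float(state.best_fitness),
        convergence=convergence,
        evaluations=evaluator.count,
        seed=config.seed,
        meta={"algorithm": "sar", "sense": config.sense},
    )
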