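"""Particle swarm minimization with centroid opposition and similarity mutation.

Three algorithm variants sit behind one configurable minimizer:

``pso``
    Canonical global-best PSO with a linearly decreasing inertia weight.
``cobl``
    PSO plus a centroid opposition-based learning step each iteration: every
    particle's mirror image through the swarm centroid is evaluated (within
    dynamic min/max boundaries, with a stochastic repair for out-of-bound
    mirrors) and greedily adopted when it is strictly better.
``smcpso``
    COBL plus a cosine-similarity mutation: particles whose cosine similarity
    to the incumbent best exceeds the swarm-average similarity are considered
    over-aggregated and are re-initialized with a probability that decays
    linearly from 50% to 5% over the run.

All evaluations — position updates, opposite solutions, and mutation
re-initializations — are charged against one shared function-evaluation
budget, so variants are compared at equal cost.  Runs are bit-reproducible
for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SwarmConfig",
    "MutationSchedule",
    "SwarmState",
    "OptimizationResult",
    "update_velocity",
    "update_position",
    "swarm_centroid",
    "opposite_position",
    "dynamic_bounds",
    "repair_opposite",
    "cosine_similarity",
    "mean_similarity",
    "mutation_factor",
    "mutation_sweep",
    "cobl_step",
    "minimize",
]

ALGORITHMS = ("pso", "cobl", "smcpso")


@dataclass(frozen=True)
class SwarmConfig:
    """Minimizer configuration.

    Defaults follow the benchmark protocol (40 particles, 10,000 function
    evaluations); CNN training uses 50 particles and a mutation sweep every
    100 iterations instead of every iteration.
    """

    n_particles: int = 40
    eval_budget: int | None = 10_000
    max_iterations: int | None = None
    inertia_start: float = 0.9
    inertia_end: float = 0.4
    c1: float = 2.0
    c2: float = 2.0
    v_max_fraction: float = 0.2
    mutation_start: float = 0.5
    mutation_end: float = 0.05
    mutation_period: int = 100
    algorithm: str = "smcpso"
    similarity_reference: str = "gbest"  # or "pbest"
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if self.eval_budget is None and self.max_iterations is None:
            raise ValueError("set eval_budget and/or max_iterations")
        if not (0.0 <= self.mutation_end <= self.mutation_start <= 1.0):
            raise ValueError("require 0 <= Mend <= Mstart <= 1")


@dataclass(frozen=True)
class MutationSchedule:
    """Linear decay of the mutation probability over the run."""

    m_start: float = 0.5
    m_end: float = 0.05
    t_max: int = 1


@dataclass
class SwarmState:
    """Mutable swarm snapshot: positions, velocities, memories, accounting."""

    positions: np.ndarray          # (N, D)
    velocities: np.ndarray         # (N, D)
    values: np.ndarray             # (N,) objective at current positions
    pbest_positions: np.ndarray    # (N, D)
    pbest_values: np.ndarray       # (N,)
    gbest_position: np.ndarray     # (D,)
    gbest_value: float
    gbest_index: int               # particle holding the incumbent best
    iteration: int = 0
    evals_used: int = 0


@dataclass(frozen=True)
class OptimizationResult:
    best_position: np.ndarray
    best_value: float
    evals_used: int
    history: list = field(repr=False)  # rows of dicts, one per iteration


# ---------------------------------------------------------------------------
# elementary swarm operations
# ---------------------------------------------------------------------------

def update_velocity(velocity, position, pbest_position, gbest_position,
                    w, c1, c2, r1, r2, v_max=None):
    """Inertia + cognitive + social velocity update, clamped to ``±v_max``."""
    v = (w * np.asarray(velocity)
         + c1 * r1 * (np.asarray(pbest_position) - position)
         + c2 * r2 * (np.asarray(gbest_position) - position))
    if v_max is not None:
        v = np.clip(v, -v_max, v_max)
    return v


def update_position(position, velocity, lower=None, upper=None):
    """Advance ``x' = x + v`` and clip into bounds.

    Returns ``(new_position, new_velocity)``; velocity components are zeroed
    where the position was clipped, so clipped particles do not keep pushing
    into the wall.
    """
    x = np.asarray(position) + velocity
    v = np.asarray(velocity)
    if lower is not None:
        clipped = np.clip(x, lower, upper)
        v = np.where(clipped != x, 0.0, v)
        x = clipped
    return x, v


def swarm_centroid(positions: np.ndarray) -> np.ndarray:
    """Componentwise mean position of the swarm."""
    positions = np.atleast_2d(positions)
    if positions.shape[0] == 0:
        raise ValueError("empty swarm has no centroid")
    return positions.mean(axis=0)


def opposite_position(x: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """Mirror a position through the swarm centroid: ``ox = 2M - x``."""
    return 2.0 * np.asarray(centroid) - np.asarray(x)


def dynamic_bounds(positions: np.ndarray):
    """Per-dimension (min, max) envelope of the current swarm."""
    positions = np.atleast_2d(positions)
    if positions.shape[0] == 0:
        raise ValueError("empty swarm has no bounds")
    return positions.min(axis=0), positions.max(axis=0)


def repair_opposite(ox, a, b, centroid, lower, upper, rng):
    """Re-draw opposite-solution components outside the dynamic envelope.

    Components below the envelope are redrawn in ``[lower, M]``, components
    above in ``[M, upper]``; in-envelope components pass through unchanged.
    Accepts scalars or same-shape arrays.
    """
    ox = np.asarray(ox, dtype=float)
    below = ox < a
    above = ox > b
    if not (np.any(below) or np.any(above)):
        return ox
    u = rng.uniform(size=ox.shape)
    repaired = np.where(below, lower + u * (centroid - lower), ox)
    repaired = np.where(above, centroid + u * (upper - centroid), repaired)
    return repaired


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Normalized dot product; defined as 0 when either vector has zero norm."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        logger.warning("cosine similarity of a zero-norm vector; returning 0")
        return 0.0
    return float(u @ v / (nu * nv))


def _row_cosine(reference: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Cosine similarity of each row of ``positions`` to ``reference``."""
    ref_norm = np.linalg.norm(reference)
    norms = np.linalg.norm(positions, axis=1)
    sims = np.zeros(positions.shape[0])
    ok = (norms > 0) & (ref_norm > 0)
    if ref_norm > 0:
        sims[ok] = positions[ok] @ reference / (norms[ok] * ref_norm)
    return sims


def mean_similarity(reference: np.ndarray, positions: np.ndarray) -> float:
    """Swarm-average cosine similarity to the reference position."""
    positions = np.atleast_2d(positions)
    return float(_row_cosine(np.asarray(reference), positions).mean())


def mutation_factor(schedule: MutationSchedule, k: int) -> float:
    """Linear mutation probability: Mstart at k=0, Mend at k=Tmax."""
    if k < 0 or k > schedule.t_max:
        logger.warning("iteration %d outside [0, %d]; clamping", k, schedule.t_max)
        k = min(max(k, 0), schedule.t_max)
    # convex-combination form: exact Mstart at k=0 and Mend at k=Tmax
    return ((schedule.t_max - k) * schedule.m_start
            + k * schedule.m_end) / schedule.t_max


# ---------------------------------------------------------------------------
# composite steps
# ---------------------------------------------------------------------------

def _update_memories(state: SwarmState) -> None:
    improved = state.values < state.pbest_values
    state.pbest_positions[improved] = state.positions[improved]
    state.pbest_values[improved] = state.values[improved]
    i = int(np.argmin(state.pbest_values))
    if state.pbest_values[i] < state.gbest_value:
        state.gbest_value = float(state.pbest_values[i])
        state.gbest_position = state.pbest_positions[i].copy()
        state.gbest_index = i


def cobl_step(state: SwarmState, objective, rng,
              eval_budget: int | None = None) -> SwarmState:
    """Centroid opposition step: greedily adopt better repaired mirrors.

    Out-of-envelope mirrors are repaired back into the dynamic (min/max)
    envelope of the current swarm, so the opposition step is contractive
    around the swarm's occupied region.  Evaluations are charged to the
    budget; with a partial budget only the leading particles are mirrored.
    """
    n = state.positions.shape[0]
    if eval_budget is not None:
        n = min(n, eval_budget - state.evals_used)
        if n <= 0:
            return state
    centroid = swarm_centroid(state.positions)
    a, b = dynamic_bounds(state.positions)
    ox = opposite_position(state.positions[:n], centroid)
    ox = repair_opposite(ox, a, b, centroid, a, b, rng)
    fox = np.asarray(objective(ox), dtype=float)
    state.evals_used += n
    better = fox < state.values[:n]
    state.positions[:n][better] = ox[better]
    state.values[:n][better] = fox[better]
    # adopting a mirror is a restart of that particle's motion: carrying the
    # old velocity keeps the swarm in a permanent high-energy churn and the
    # envelope never contracts
    state.velocities[:n][better] = 0.0
    _update_memories(state)
    return state


def mutation_sweep(state: SwarmState, schedule: MutationSchedule,
                   lower, upper, objective, rng,
                   similarity_reference: str = "gbest",
                   eval_budget: int | None = None) -> tuple[SwarmState, int]:
    """Re-initialize over-aggregated particles with probability δ(k).

    A particle is in the mutation region when its cosine similarity to the
    incumbent best exceeds the swarm-average similarity.  The particle
    holding the incumbent best is exempt, so the best-known solution
    survives every sweep.  Returns the state and the mutation count.
    """
    delta = mutation_factor(schedule, min(state.iteration, schedule.t_max))
    if similarity_reference == "pbest":
        sims = np.array([cosine_similarity(p, x) for p, x
                         in zip(state.pbest_positions, state.positions)])
    else:
        sims = _row_cosine(state.gbest_position, state.positions)
    cos_a = float(sims.mean())
    candidates = sims > cos_a
    candidates[state.gbest_index] = False
    draws = rng.uniform(size=state.positions.shape[0]) < delta
    mutate = candidates & draws
    idx = np.flatnonzero(mutate)
    if eval_budget is not None:
        room = max(0, eval_budget - state.evals_used)
        idx = idx[:room]
    if idx.size == 0:
        return state, 0
    dim = state.positions.shape[1]
    fresh = rng.uniform(lower, upper, size=(idx.size, dim))
    f_fresh = np.asarray(objective(fresh), dtype=float)
    state.evals_used += idx.size
    state.positions[idx] = fresh
    state.velocities[idx] = 0.0
    state.values[idx] = f_fresh
    # mutation is a restart: the particle's personal memory resets with it
    state.pbest_positions[idx] = fresh
    state.pbest_values[idx] = f_fresh
    _update_memories(state)
    return state, int(idx.size)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def _as_bound(bound, dim: int) -> np.ndarray:
    b = np.asarray(bound, dtype=float)
    return np.full(dim, float(b)) if b.ndim == 0 else b


def planned_iterations(config: SwarmConfig) -> int:
    """Iterations implied by the stopping rule, particles, and algorithm.

    With ``max_iterations`` set it is used directly; otherwise PSO spends N
    evaluations per iteration and COBL/SMCPSO spend 2N (positions plus
    opposites).  Used as Tmax for the inertia and mutation schedules.
    """
    if config.max_iterations is not None:
        return config.max_iterations
    per_iter = config.n_particles * (2 if config.algorithm != "pso" else 1)
    return max(1, (config.eval_budget - config.n_particles) // per_iter)


def minimize(objective, lower, upper, dim: int, config: SwarmConfig,
             init_positions: np.ndarray | None = None) -> OptimizationResult:
    """Minimize a vectorized objective ``f((n, D)) -> (n,)`` within bounds.

    Particles start uniformly in the bounds unless ``init_positions``
    (n_particles × dim, clipped into bounds) supplies domain-informed
    starting points.  Stops when the evaluation budget can no longer afford
    a full position pass, or after ``max_iterations``, whichever binds
    first.
    """
    if config.eval_budget is not None and config.eval_budget < config.n_particles:
        raise ValueError("eval_budget smaller than one evaluation pass")
    lower = _as_bound(lower, dim)
    upper = _as_bound(upper, dim)
    rng = np.random.default_rng(config.seed)
    n = config.n_particles
    v_max = config.v_max_fraction * (upper - lower)

    if init_positions is not None:
        if init_positions.shape != (n, dim):
            raise ValueError("init_positions must be (n_particles, dim)")
        x = np.clip(np.asarray(init_positions, dtype=float), lower, upper)
    else:
        x = rng.uniform(lower, upper, size=(n, dim))
    fx = np.asarray(objective(x), dtype=float)
    state = SwarmState(
        positions=x, velocities=np.zeros((n, dim)), values=fx,
        pbest_positions=x.copy(), pbest_values=fx.copy(),
        gbest_position=x[np.argmin(fx)].copy(), gbest_value=float(fx.min()),
        gbest_index=int(np.argmin(fx)), evals_used=n)

    t_max = planned_iterations(config)
    schedule = MutationSchedule(config.mutation_start, config.mutation_end, t_max)
    history: list[dict] = []

    def keep_going():
        if (config.max_iterations is not None
                and state.iteration >= config.max_iterations):
            return False
        if (config.eval_budget is not None
                and state.evals_used + n > config.eval_budget):
            return False
        return True

    while keep_going():
        frac = min(state.iteration, t_max) / t_max
        w = config.inertia_start + (config.inertia_end - config.inertia_start) * frac
        r1 = rng.uniform(size=(n, dim))
        r2 = rng.uniform(size=(n, dim))
        state.velocities = update_velocity(
            state.velocities, state.positions, state.pbest_positions,
            state.gbest_position, w, config.c1, config.c2, r1, r2, v_max)
        state.positions, state.velocities = update_position(
            state.positions, state.velocities, lower, upper)
        state.values = np.asarray(objective(state.positions), dtype=float)
        state.evals_used += n
        _update_memories(state)

        if config.algorithm in ("cobl", "smcpso"):
            cobl_step(state, objective, rng, config.eval_budget)

        cos_a = np.nan
        n_mut = 0
        delta = np.nan
        if config.algorithm == "smcpso":
            delta = mutation_factor(schedule, min(state.iteration, t_max))
            cos_a = mean_similarity(state.gbest_position, state.positions)
            if state.iteration % config.mutation_period == 0:
                state, n_mut = mutation_sweep(
                    state, schedule, lower, upper, objective, rng,
                    config.similarity_reference, config.eval_budget)

        history.append({
            "iteration": state.iteration, "evals": state.evals_used,
            "gbest_value": state.gbest_value, "cos_a": cos_a,
            "delta": delta, "mutations": n_mut})
        state.iteration += 1

    return OptimizationResult(
        best_position=state.gbest_position.copy(),
        best_value=state.gbest_value,
        evals_used=state.evals_used, history=history)


def vectorize_objective(scalar_f):
    """Lift a scalar objective ``f((D,)) -> float`` to the batch contract."""
    def batched(x):
        x = np.atleast_2d(x)
        return np.array([scalar_f(row) for row in x], dtype=float)
    return batched
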