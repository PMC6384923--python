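"""Binary dragonfly algorithm (BDA) for subset search over spectral channels.

The dragonfly algorithm steers a swarm through five position-changing
strategies — separation, alignment, cohesion, attraction to the food source
(best-so-far solution) and distraction from the enemy (worst-so-far) — with
adaptively tuned weights. The real-valued step vector is mapped to per-bit
flip probabilities by the v-shaped transfer function
``T(dx) = |dx / sqrt(dx^2 + 1)|``: a bit flips with probability ``T``,
so a large step magnitude means a likely flip regardless of direction,
which avoids forcing bits toward 0 or 1.

Factor schedules over a run of ``max_iter`` iterations:

* inertia ``w`` decreases linearly from 0.9 to 0.4;
* an auxiliary ``theta`` decreases linearly from 0.1 to 0 over the first
  half of the run and stays 0 thereafter;
* separation/alignment/cohesion factors are ``2 * gamma * theta`` with an
  independent uniform ``gamma`` per factor per iteration (so each lies in
  [0, 0.2] and vanishes in the second half);
* the food factor ``f`` is uniform on [0, 2]; the enemy factor ``e``
  equals ``theta``.

Every dragonfly treats the rest of the swarm as its neighborhood. A Lévy
random-walk step generator is provided (and unit-tested) for the
no-neighbors regime of the continuous algorithm, but the binary run loop
never reaches that regime with a whole-swarm neighborhood, so it is not
wired into :func:`run_bda`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .fitness import FitnessConfig, rmsecv
from .spectra import SpectraDataset, WavelengthMask

__all__ = [
    "SwarmFactors",
    "BDAConfig",
    "BDARunResult",
    "schedule_factors",
    "separation",
    "alignment",
    "cohesion",
    "food_attraction",
    "enemy_distraction",
    "step_update",
    "levy_flight",
    "transfer",
    "binary_update",
    "run_bda",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# factor schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SwarmFactors:
    """Per-iteration swarming weights (w, s, a, c, f, e) and auxiliary theta."""

    w: float
    s: float
    a: float
    c: float
    f: float
    e: float
    theta: float


def schedule_factors(
    iteration: int, max_iter: int, rng: np.random.Generator
) -> SwarmFactors:
    """Adaptive factor values at a given iteration.

    ``w`` anneals linearly 0.9 -> 0.4 over the whole run; ``theta`` anneals
    0.1 -> 0 over the first half then stays 0, switching off separation,
    alignment, cohesion and enemy distraction for the exploitation phase.
    """
    if not 0 <= iteration <= max_iter:
        raise ValueError(f"iteration {iteration} outside [0, {max_iter}]")
    w = 0.9 - iteration * (0.9 - 0.4) / max_iter
    half = max_iter / 2
    theta = 0.1 - iteration * 0.1 / half if iteration <= half else 0.0
    s, a, c = (2.0 * rng.uniform(0.0, 1.0) * theta for _ in range(3))
    f = rng.uniform(0.0, 2.0)
    return SwarmFactors(w=w, s=s, a=a, c=c, f=f, e=theta, theta=theta)


# ---------------------------------------------------------------------------
# the five position-changing strategies
# ---------------------------------------------------------------------------

def _check_dims(x: np.ndarray, others: np.ndarray) -> None:
    if others.size and others.shape[-1] != x.shape[-1]:
        raise ValueError("dimension mismatch between position vectors")


def separation(x: np.ndarray, neighbors: np.ndarray) -> np.ndarray:
    """``S_i = -sum_j (x - x_j)``; zero with no neighbors."""
    x = np.asarray(x, dtype=float)
    neighbors = np.atleast_2d(np.asarray(neighbors, dtype=float))
    if neighbors.size == 0:
        return np.zeros_like(x)
    _check_dims(x, neighbors)
    return -(neighbors.shape[0] * x - neighbors.sum(axis=0))


def alignment(neighbor_steps: np.ndarray) -> np.ndarray:
    """``A_i = mean_j V_j``; zero with no neighbors (caller supplies dims)."""
    steps = np.atleast_2d(np.asarray(neighbor_steps, dtype=float))
    if steps.size == 0:
        return np.zeros(steps.shape[-1] if steps.ndim == 2 else 0)
    return steps.mean(axis=0)


def cohesion(x: np.ndarray, neighbors: np.ndarray) -> np.ndarray:
    """``C_i = centroid(neighbors) - x``; zero with no neighbors."""
    x = np.asarray(x, dtype=float)
    neighbors = np.atleast_2d(np.asarray(neighbors, dtype=float))
    if neighbors.size == 0:
        return np.zeros_like(x)
    _check_dims(x, neighbors)
    return neighbors.mean(axis=0) - x


def food_attraction(x: np.ndarray, food_position: np.ndarray) -> np.ndarray:
    """``F_i = x_food - x``."""
    x = np.asarray(x, dtype=float)
    food = np.asarray(food_position, dtype=float)
    if food.shape != x.shape:
        raise ValueError("dimension mismatch between position and food")
    return food - x


def enemy_distraction(x: np.ndarray, enemy_position: np.ndarray) -> np.ndarray:
    """``E_i = x_enemy + x`` (the repulsive term enters as a sum)."""
    x = np.asarray(x, dtype=float)
    enemy = np.asarray(enemy_position, dtype=float)
    if enemy.shape != x.shape:
        raise ValueError("dimension mismatch between position and enemy")
    return enemy + x


def step_update(
    prev_step: np.ndarray,
    S: np.ndarray,
    A: np.ndarray,
    C: np.ndarray,
    F: np.ndarray,
    E: np.ndarray,
    factors: SwarmFactors,
    clamp: float,
) -> np.ndarray:
    """``dX <- (s S + a A + c C + f F + e E) + w dX``, clamped elementwise."""
    parts = [np.asarray(v, dtype=float) for v in (prev_step, S, A, C, F, E)]
    if any(not np.all(np.isfinite(v)) for v in parts):
        raise ValueError("non-finite input to step update")
    prev_step, S, A, C, F, E = parts
    new = (
        factors.s * S
        + factors.a * A
        + factors.c * C
        + factors.f * F
        + factors.e * E
        + factors.w * prev_step
    )
    return np.clip(new, -clamp, clamp)


def levy_sigma(beta: float) -> float:
    """Scale of the Lévy step distribution for stability index ``beta``."""
    if not 1.0 < beta <= 2.0:
        raise ValueError("beta must be in (1, 2]")
    num = math.gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def levy_flight(
    d: int,
    beta: float,
    rng: np.random.Generator,
    prefactor: float = 0.10,
) -> np.ndarray:
    """``prefactor * r1 * sigma / |r2|^(1/beta)`` per dimension, r1,r2 ~ U[0,1]."""
    if d < 1:
        raise ValueError("dimension must be >= 1")
    sigma = levy_sigma(beta)
    r1 = rng.uniform(0.0, 1.0, size=d)
    r2 = rng.uniform(0.0, 1.0, size=d)
    return prefactor * r1 * sigma / np.abs(r2) ** (1.0 / beta)


# ---------------------------------------------------------------------------
# binary transition
# ---------------------------------------------------------------------------

def transfer(dx):
    """V-shaped transfer function ``T(dx) = |dx / sqrt(dx^2 + 1)|`` in [0, 1)."""
    dx = np.asarray(dx, dtype=float)
    if not np.all(np.isfinite(dx)):
        raise ValueError("non-finite step input to transfer function")
    out = np.abs(dx / np.sqrt(dx * dx + 1.0))
    return out if out.ndim else float(out)


def binary_update(x_t, dx_next, r):
    """Flip each bit with probability ``T(dx)``: complement where ``r < T``."""
    x_t = np.asarray(x_t)
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > 1):
        raise ValueError("r must lie in [0, 1]")
    flip = r < transfer(dx_next)
    out = np.where(flip, 1 - x_t, x_t)
    return out if out.ndim else int(out)


# ---------------------------------------------------------------------------
# the run loop
# ---------------------------------------------------------------------------

@dataclass
class BDAConfig:
    """Optimizer settings. Defaults: 50 iterations, 10 dragonflies.

    ``stop_tol``, when set, adds an early-stop rule on the absolute change
    of the best cost between successive iterations (the alternative to the
    plain max-iterations criterion). ``step_clamp`` bounds each step
    component so the transfer function stays responsive.
    """

    max_iter: int = 50
    n_dragonflies: int = 10
    step_clamp: float = 6.0
    levy_beta: float = 1.5
    seed: int = 0
    stop_tol: float | None = None
    n_channels: int | None = None

    def __post_init__(self) -> None:
        if self.max_iter < 1 or self.n_dragonflies < 1:
            raise ValueError("max_iter and n_dragonflies must be positive")
        if self.step_clamp <= 0:
            raise ValueError("step_clamp must be positive")


@dataclass
class BDARunResult:
    """Best mask found by one BDA run and its cost trace."""

    best_mask: WavelengthMask
    best_cost: float
    trace: np.ndarray  # best-so-far cost after each evaluated iteration
    n_iterations: int


def _evaluate_population(
    X: np.ndarray,
    dataset: SpectraDataset,
    config: FitnessConfig,
    cache: dict[bytes, float],
) -> np.ndarray:
    costs = np.empty(X.shape[0])
    for i, row in enumerate(X):
        key = row.tobytes()
        cost = cache.get(key)
        if cost is None:
            cost = rmsecv(dataset, row, config).rmsecv
            cache[key] = cost
        costs[i] = cost
    return costs


def run_bda(
    dataset: SpectraDataset,
    fitness_config: FitnessConfig,
    bda_config: BDAConfig,
) -> BDARunResult:
    """One binary-dragonfly search for the lowest-RMSECV wavelength subset.

    The loop: random Bernoulli(1/2) initialization, per-individual RMSECV
    evaluation, stop test, position update through the five strategies plus
    the transfer function, repeat. Food/enemy are the best/worst masks over
    all evaluations so far, so the returned trace is non-increasing. Fully
    reproducible from ``bda_config.seed``; random draws consume a single
    generator in a fixed order (init bits, then per iteration the factor
    draws followed by the flip draws).
    """
    p = dataset.n_channels
    if bda_config.n_channels is not None and bda_config.n_channels != p:
        raise ValueError(
            f"config expects {bda_config.n_channels} channels, dataset has {p}"
        )
    rng = np.random.default_rng(bda_config.seed)
    n = bda_config.n_dragonflies
    X = (rng.random((n, p)) < 0.5).astype(np.int8)
    steps = np.zeros((n, p))

    cache: dict[bytes, float] = {}
    food_pos = np.zeros(p, dtype=np.int8)
    food_cost = np.inf
    enemy_pos = np.zeros(p, dtype=np.int8)
    enemy_cost = -np.inf
    trace: list[float] = []

    t = 0
    for t in range(bda_config.max_iter):
        costs = _evaluate_population(X, dataset, fitness_config, cache)
        i_best = int(np.argmin(costs))
        if costs[i_best] < food_cost:
            food_cost = float(costs[i_best])
            food_pos = X[i_best].copy()
        i_worst = int(np.argmax(costs))
        if costs[i_worst] > enemy_cost:
            enemy_cost = float(costs[i_worst])
            enemy_pos = X[i_worst].copy()
        trace.append(food_cost)
        logger.debug("iter %d best-so-far RMSECV %.6g", t, food_cost)

        if t == bda_config.max_iter - 1:
            break
        if (
            bda_config.stop_tol is not None
            and len(trace) >= 2
            and abs(trace[-2] - trace[-1]) < bda_config.stop_tol
        ):
            break

        factors = schedule_factors(t, bda_config.max_iter, rng)
        Xf = X.astype(float)
        total_pos = Xf.sum(axis=0)
        total_step = steps.sum(axis=0)
        m = n - 1  # whole-swarm neighborhood: everyone else
        if m > 0:
            neigh_pos_sum = total_pos[None, :] - Xf
            S = neigh_pos_sum - m * Xf
            A = (total_step[None, :] - steps) / m
            C = neigh_pos_sum / m - Xf
        else:
            S = np.zeros_like(Xf)
            A = np.zeros_like(steps)
            C = np.zeros_like(Xf)
        F = food_pos[None, :].astype(float) - Xf
        E = enemy_pos[None, :].astype(float) + Xf
        steps = np.clip(
            factors.s * S
            + factors.a * A
            + factors.c * C
            + factors.f * F
            + factors.e * E
            + factors.w * steps,
            -bda_config.step_clamp,
            bda_config.step_clamp,
        )
        r = rng.random((n, p))
        X = np.where(r < transfer(steps), 1 - X, X).astype(np.int8)

        if not X.any():
            logger.warning(
                "entire population collapsed to empty masks at iter %d; "
                "re-randomizing",
                t,
            )
            X = (rng.random((n, p)) < 0.5).astype(np.int8)

    return BDARunResult(
        best_mask=WavelengthMask(food_pos),
        best_cost=food_cost,
        trace=np.asarray(trace),
        n_iterations=t + 1,
    )
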