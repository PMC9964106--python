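"""Artificial Gorilla Troops Optimizer (GTO), continuous and binary.

A population metaheuristic modelled on gorilla troop behaviour.  Each
iteration runs an exploration phase (migration to a random point with
probability ``p_migration``, a move referenced to a random peer, or a
local differential move) and an exploitation phase (follow the
silverback — the incumbent best — when the decayed step size D is at
least W, otherwise adult-female competition around the silverback),
with greedy per-index replacement after each phase.  Minimization
convention throughout; accuracy-style objectives should be wrapped as
``error = 1 - accuracy``.

The binary mode maps each coordinate through a sigmoid and thresholds
at 0.5 to obtain a feature subset; the feature-selection objective is
``OF = alpha * error + (1 - alpha) * n_selected / n_features`` with
``alpha = 0.99``, and an empty subset is assigned the worst value 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np


class GTOError(ValueError):
    pass


@dataclass(frozen=True)
class GTOConfig:
    pop_size: int = 30
    max_iter: int = 100
    p_migration: float = 0.03
    w_threshold: float = 0.8
    lower: float | np.ndarray = -1.0
    upper: float | np.ndarray = 1.0
    a_const: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise GTOError("pop_size must be >= 2")
        if self.max_iter < 1:
            raise GTOError("max_iter must be >= 1")
        if not 0.0 <= self.p_migration <= 1.0:
            raise GTOError("p_migration must be in [0, 1]")
        if np.any(np.asarray(self.lower) > np.asarray(self.upper)):
            raise GTOError("bounds must satisfy lower <= upper per dimension")


@dataclass
class GorillaPopulation:
    positions: np.ndarray  # (pop, dim)
    fitnesses: np.ndarray  # (pop,)
    silverback_index: int
    iteration: int
    rng: np.random.Generator

    @property
    def silverback(self) -> np.ndarray:
        return self.positions[self.silverback_index]


def _bounds(config: GTOConfig, dim: int) -> tuple[np.ndarray, np.ndarray]:
    lo = np.broadcast_to(np.asarray(config.lower, dtype=float), (dim,)).copy()
    hi = np.broadcast_to(np.asarray(config.upper, dtype=float), (dim,)).copy()
    return lo, hi


def initialize(config: GTOConfig, dim: int) -> GorillaPopulation:
    """Uniform random population within the bounds; fitnesses unevaluated (NaN)."""
    lo, hi = _bounds(config, dim)
    rng = np.random.default_rng(config.seed)
    pos = rng.uniform(lo, hi, size=(config.pop_size, dim))
    fit = np.full(config.pop_size, np.nan)
    return GorillaPopulation(pos, fit, 0, 0, rng)


def _decay(rng: np.random.Generator, t: int, max_iter: int) -> float:
    # D = F * (1 - t/MaxIt) with F = cos(2 r4) + 1; the leading factor is
    # pluggable in spirit but this is the canonical choice.
    f = np.cos(2.0 * rng.random()) + 1.0
    return f * (1.0 - t / max_iter)


def exploration_step(pop: GorillaPopulation, config: GTOConfig) -> np.ndarray:
    """Candidate positions from the three exploration mechanisms, clipped."""
    n, dim = pop.positions.shape
    lo, hi = _bounds(config, dim)
    rng = pop.rng
    D = _decay(rng, pop.iteration, config.max_iter)
    cand = np.empty_like(pop.positions)
    for i in range(n):
        x = pop.positions[i]
        r = rng.random()
        R = rng.uniform(-1.0, 1.0)
        S = D * R
        if r < config.p_migration:
            # migration to an unknown site
            cand[i] = rng.uniform(lo, hi)
        elif rng.random() >= 0.5:
            # move referenced to a random peer
            xr = pop.positions[int(rng.integers(n))]
            r2 = rng.random()
            Z = rng.uniform(-D, D, size=dim)
            cand[i] = (r2 - D) * xr + S * (Z * x)
        else:
            # local differential move against a random candidate position
            gxr = pop.positions[int(rng.integers(n))]
            r3 = rng.random()
            cand[i] = x - S * (S * (x - gxr) + r3 * (x - gxr))
    return np.clip(cand, lo, hi)


def exploitation_step(pop: GorillaPopulation, config: GTOConfig) -> np.ndarray:
    """Follow-silverback when D >= W, else competition around the silverback."""
    n, dim = pop.positions.shape
    lo, hi = _bounds(config, dim)
    rng = pop.rng
    D = _decay(rng, pop.iteration, config.max_iter)
    sb = pop.silverback
    cand = np.empty_like(pop.positions)
    if D >= config.w_threshold:
        mean_vec = np.abs(pop.positions.mean(axis=0))
        for i in range(n):
            R = rng.uniform(-1.0, 1.0)
            S = D * R
            g = 2.0 ** S
            M = np.power(np.power(mean_vec + 1e-30, g), 1.0 / g)
            cand[i] = S * M * (pop.positions[i] - sb) + pop.positions[i]
    else:
        for i in range(n):
            mult = (2.0 * rng.random() - 1.0) * config.a_const
            cand[i] = sb - (sb - pop.positions[i]) * mult
    return np.clip(cand, lo, hi)


def greedy_replace(
    pop: GorillaPopulation,
    candidates: np.ndarray,
    objective: Callable[[np.ndarray], float],
) -> GorillaPopulation:
    """Keep the better of incumbent and candidate per index; re-select silverback."""
    if candidates.shape != pop.positions.shape:
        raise GTOError("candidate array shape mismatch")
    for i, cand in enumerate(candidates):
        try:
            f = float(objective(cand))
        except Exception as exc:  # noqa: BLE001 - candidate failure is data, not fatal
            raise GTOError(f"objective failed for candidate {i}") from exc
        if np.isnan(pop.fitnesses[i]) or f < pop.fitnesses[i]:
            pop.positions[i] = cand
            pop.fitnesses[i] = f
    pop.silverback_index = int(np.argmin(pop.fitnesses))
    return pop


def binarize(position: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
    """Sigmoid transfer to bits: 1 where sigmoid(x) strictly exceeds the
    threshold (0.5 deterministic, or a uniform draw if ``rng`` is given)."""
    p = 1.0 / (1.0 + np.exp(-np.asarray(position, dtype=float)))
    thr = 0.5 if rng is None else rng.random(size=p.shape)
    return (p > thr).astype(np.int64)


def fitness_feature_selection(bits: np.ndarray, error_rate: float, alpha: float = 0.99) -> float:
    """OF = alpha*error + (1-alpha)*|selected|/|features|; empty subset -> 1.0."""
    bits = np.asarray(bits)
    if bits.size == 0:
        raise GTOError("empty bit vector")
    if not 0.0 <= error_rate <= 1.0:
        raise GTOError("error_rate must be in [0, 1]")
    ls = int(bits.sum())
    if ls == 0:
        return 1.0
    return alpha * error_rate + (1.0 - alpha) * ls / bits.size


def optimize(
    objective: Callable[[np.ndarray], float],
    dim: int,
    config: GTOConfig,
    initial_positions: np.ndarray | None = None,
) -> tuple[np.ndarray, float, list[float]]:
    """Run the full GTO loop; returns (best position, best value, history).

    ``history[t]`` is the best-so-far objective after iteration t+1 and is
    non-increasing.  Evaluation budget: pop_size * (2 * max_iter + 1).
    ``initial_positions`` (shape (k, dim), k <= pop_size) seeds the first k
    gorillas with known-good starting points (warm start); the rest stay
    uniform random.
    """
    pop = initialize(config, dim)
    if initial_positions is not None:
        init = np.atleast_2d(np.asarray(initial_positions, dtype=float))
        if init.shape[1] != dim or init.shape[0] > config.pop_size:
            raise GTOError("initial_positions must be (k <= pop_size, dim)")
        lo, hi = _bounds(config, dim)
        pop.positions[: init.shape[0]] = np.clip(init, lo, hi)
    for i in range(config.pop_size):
        pop.fitnesses[i] = float(objective(pop.positions[i]))
    pop.silverback_index = int(np.argmin(pop.fitnesses))
    history: list[float] = []
    for t in range(config.max_iter):
        pop.iteration = t
        pop = greedy_replace(pop, exploration_step(pop, config), objective)
        pop = greedy_replace(pop, exploitation_step(pop, config), objective)
        history.append(float(pop.fitnesses[pop.silverback_index]))
    best = pop.silverback.copy()
    return best, float(pop.fitnesses[pop.silverback_index]), history


def select_features(
    error_fn: Callable[[np.ndarray], float],
    n_features: int,
    config: GTOConfig,
    alpha: float = 0.99,
    warm_start_full: bool = True,
) -> tuple[np.ndarray, float, list[float]]:
    """Binary GTO feature selection minimizing the OF objective.

    ``error_fn`` maps a bit mask to a classification error rate in [0, 1].
    With ``warm_start_full`` the all-features subset joins the initial
    population, so the search refines the complete set rather than having
    to rediscover it.  Returns (bit mask, OF value, history).
    """

    cache: dict[bytes, float] = {}

    def objective(x: np.ndarray) -> float:
        bits = binarize(x)
        key = bits.tobytes()
        if key not in cache:
            if bits.sum() == 0:
                cache[key] = 1.0
            else:
                cache[key] = fitness_feature_selection(bits, float(error_fn(bits)), alpha)
        return cache[key]

    init = None
    if warm_start_full:
        lo, hi = _bounds(config, n_features)
        init = hi[None, :]  # sigmoid(upper) > 0.5 per coordinate -> all selected
    best, val, history = optimize(objective, n_features, config, initial_positions=init)
    return binarize(best), val, history


def tune_hyperparameters(
    train_fn: Callable[[dict], float],
    search_space: dict[str, Callable[[float], object]],
    config: GTOConfig,
) -> tuple[dict, float, list[float]]:
    """Hyperparameter search on the unit cube.

    ``search_space`` maps parameter names to decoders taking a coordinate in
    [0, 1] (use log-uniform or binning decoders for scale/categorical
    parameters); ``train_fn`` receives the decoded dict and returns a
    validation error.  A failing ``train_fn`` gets the worst fitness.
    """
    names = list(search_space)
    cfg_unit = GTOConfig(**{**config.__dict__, "lower": 0.0, "upper": 1.0})

    def decode(x: np.ndarray) -> dict:
        return {name: search_space[name](float(v)) for name, v in zip(names, x)}

    def objective(x: np.ndarray) -> float:
        try:
            return float(train_fn(decode(x)))
        except Exception:  # noqa: BLE001 - failed trials score worst
            return float("inf")

    best, val, history = optimize(objective, len(names), cfg_unit)
    return decode(best), val, history
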