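"""Stochastic search strategies: genetic algorithm, particle swarm, and
simulated annealing, batched for a plate-based campaign (population = swarm
= walker count = batch size, default 8).

Default hyperparameters are the best-ranked variants from the in-silico grid
search: GA (elitism 2, mutation probability 0.4, extent 0.3, random
crossover, rank selection), PSO (w0 0.9, decay 0.95, c1 2.5, c2 1.0), and
SA (T0 380, cooling 0.7, step 0.8).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from ..design_space import DesignSpace, snap_to_grid
from .base import BatchOptimizer

__all__ = [
    "GAConfig",
    "PSOConfig",
    "SAConfig",
    "GAOptimizer",
    "PSOOptimizer",
    "SAOptimizer",
    "rank_selection_probabilities",
]


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GAConfig:
    elitism: int = 2
    mutation_probability: float = 0.4
    mutation_extent: float = 0.3  # fraction of each parameter range
    crossover: Literal["random", "single_point"] = "random"
    selection: Literal["rank"] = "rank"

    def __post_init__(self) -> None:
        if self.elitism < 0:
            raise ValueError("elitism must be >= 0")
        if not 0.0 <= self.mutation_probability <= 1.0:
            raise ValueError("mutation_probability must be in [0, 1]")
        if not 0.0 < self.mutation_extent <= 1.0:
            raise ValueError("mutation_extent must be in (0, 1]")


def rank_selection_probabilities(n: int) -> np.ndarray:
    """Linear rank-selection probabilities for individuals sorted worst to
    best: rank i (1-based) gets i / sum(1..n); the best gets n/sum."""
    ranks = np.arange(1, n + 1, dtype=float)
    return ranks / ranks.sum()


class GAOptimizer(BatchOptimizer):
    """Generational GA with elitism.

    The top ``elitism`` individuals are carried into the next generation
    with their recorded scores (their experiments are not re-spent), so each
    proposal contains ``batch_size − elitism`` new conditions to evaluate.
    """

    def __init__(
        self,
        space: DesignSpace,
        batch_size: int = 8,
        config: GAConfig = GAConfig(),
    ):
        super().__init__(space, batch_size)
        if config.elitism >= batch_size:
            raise ValueError("elitism must be smaller than the batch size")
        self.config = config
        self.population: list[np.ndarray] = []
        self.pop_values: list[float] = []
        self._pending_elites: list[tuple[np.ndarray, float]] = []

    def _initialize(self, points, values) -> None:
        self.population = list(points)
        self.pop_values = list(values)

    def _mutate(self, point: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        cfg = self.config
        out = np.asarray(point, dtype=float).copy()
        for i in range(self.space.ndim):
            if rng.random() < cfg.mutation_probability:
                out[i] += rng.uniform(-cfg.mutation_extent, cfg.mutation_extent) * (
                    self.space.widths[i]
                )
        out = np.clip(out, self.space.lower, self.space.upper)
        return snap_to_grid(out, self.space)

    def _crossover(
        self, a: np.ndarray, b: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        if self.config.crossover == "random":
            mask = rng.integers(0, 2, size=self.space.ndim).astype(bool)
            return np.where(mask, a, b)
        cut = int(rng.integers(1, self.space.ndim))  # single_point
        return np.concatenate([a[:cut], b[cut:]])

    def propose(self, rng: np.random.Generator) -> list[np.ndarray]:
        order = np.argsort(self.pop_values)  # ascending: worst ... best
        probs = rank_selection_probabilities(len(order))
        sorted_pop = [self.population[i] for i in order]
        elites_idx = order[::-1][: self.config.elitism]
        self._pending_elites = [
            (self.population[i], self.pop_values[i]) for i in elites_idx
        ]
        n_offspring = self.batch_size - self.config.elitism
        offspring = []
        for _ in range(n_offspring):
            pa, pb = rng.choice(len(sorted_pop), size=2, p=probs)
            child = self._crossover(sorted_pop[pa], sorted_pop[pb], rng)
            offspring.append(self._mutate(child, rng))
        return self._dedupe(offspring, rng, mutate=self._mutate)

    def _update(self, points, values) -> None:
        self.population = [p for p, _ in self._pending_elites] + list(points)
        self.pop_values = [v for _, v in self._pending_elites] + list(values)


# ---------------------------------------------------------------------------
# Particle swarm optimization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSOConfig:
    w0: float = 0.9  # initial inertia weight
    cd: float = 0.95  # inertia decay per iteration
    c1: float = 2.5  # cognitive factor
    c2: float = 1.0  # social factor

    def __post_init__(self) -> None:
        if min(self.w0, self.cd, self.c1, self.c2) <= 0:
            raise ValueError("all PSO factors must be positive")
        if self.cd > 1.0:
            raise ValueError("cd must be in (0, 1]")


class PSOOptimizer(BatchOptimizer):
    """Canonical global-best PSO with decaying inertia.

    Velocity update per particle:
    ``v <- w·v + c1·r1∘(pbest − x) + c2·r2∘(gbest − x)`` with per-dimension
    U(0,1) draws r1, r2; velocities are clipped to ± the parameter range,
    positions clipped to bounds and snapped to the grid.  A particle landing
    on an already-tested condition is jittered by one grid step along a
    seeded random dimension.
    """

    def __init__(
        self,
        space: DesignSpace,
        batch_size: int = 8,
        config: PSOConfig = PSOConfig(),
    ):
        super().__init__(space, batch_size)
        self.config = config
        self.x: np.ndarray = np.empty((0, space.ndim))
        self.v: np.ndarray = np.empty((0, space.ndim))
        self.pbest_x: np.ndarray = np.empty((0, space.ndim))
        self.pbest_y: np.ndarray = np.empty(0)
        self.gbest_x: np.ndarray = np.empty(space.ndim)
        self.gbest_y: float = -math.inf
        self.w: float = config.w0

    def _initialize(self, points, values) -> None:
        self.x = np.array(points, dtype=float)
        self.v = np.zeros_like(self.x)
        self.pbest_x = self.x.copy()
        self.pbest_y = np.array(values, dtype=float)
        g = int(np.argmax(values))
        self.gbest_x = self.x[g].copy()
        self.gbest_y = float(values[g])

    def _jitter(self, point: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(point, dtype=float).copy()
        dim = int(rng.integers(self.space.ndim))
        spec = self.space.specs[dim]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out[dim] += sign * spec.step
        out = np.clip(out, self.space.lower, self.space.upper)
        return snap_to_grid(out, self.space)

    def propose(self, rng: np.random.Generator) -> list[np.ndarray]:
        cfg = self.config
        n, d = self.x.shape
        r1 = rng.uniform(size=(n, d))
        r2 = rng.uniform(size=(n, d))
        v = (
            self.w * self.v
            + cfg.c1 * r1 * (self.pbest_x - self.x)
            + cfg.c2 * r2 * (self.gbest_x - self.x)
        )
        vmax = self.space.widths
        v = np.clip(v, -vmax, vmax)
        x = np.clip(self.x + v, self.space.lower, self.space.upper)
        proposals = [snap_to_grid(p, self.space) for p in x]
        self.v = v
        self.w *= cfg.cd
        batch = self._dedupe(proposals, rng, mutate=self._jitter)
        self.x = np.array(batch, dtype=float) if batch else self.x
        return batch

    def _update(self, points, values) -> None:
        vals = np.asarray(values, dtype=float)
        for i, (p, y) in enumerate(zip(points, vals)):
            if i < len(self.pbest_y) and y > self.pbest_y[i]:
                self.pbest_y[i] = y
                self.pbest_x[i] = np.asarray(p, dtype=float)
            if y > self.gbest_y:
                self.gbest_y = float(y)
                self.gbest_x = np.asarray(p, dtype=float)


# ---------------------------------------------------------------------------
# Simulated annealing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SAConfig:
    T0: float = 380.0  # initial temperature, activity units (U mg^-1)
    cT: float = 0.7  # geometric cooling factor
    S0: float = 0.8  # step size, fraction of each parameter range

    def __post_init__(self) -> None:
        if self.T0 <= 0:
            raise ValueError("T0 must be positive")
        if not 0.0 < self.cT < 1.0:
            raise ValueError("cT must be in (0, 1)")
        if not 0.0 < self.S0 <= 1.0:
            raise ValueError("S0 must be in (0, 1]")


class SAOptimizer(BatchOptimizer):
    """Batch SA: independent walkers (one per batch slot), geometric cooling.

    Each walker proposes ``current + U(−S0, S0)·range`` per dimension
    (clipped, snapped); after evaluation, an improving move is always
    accepted, a worsening one with probability exp(Δ/T) at
    ``T = T0·cT^k`` (Δ in raw activity units, maximization).
    """

    def __init__(
        self,
        space: DesignSpace,
        batch_size: int = 8,
        config: SAConfig = SAConfig(),
    ):
        super().__init__(space, batch_size)
        self.config = config
        self.current_x: list[np.ndarray] = []
        self.current_y: list[float] = []
        self.k = 0  # completed annealing iterations
        self._accept_rng: np.random.Generator | None = None

    def _initialize(self, points, values) -> None:
        self.current_x = [np.asarray(p, dtype=float) for p in points]
        self.current_y = list(values)

    def _step(self, point: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        delta = rng.uniform(-self.config.S0, self.config.S0, size=self.space.ndim)
        out = np.asarray(point, dtype=float) + delta * self.space.widths
        out = np.clip(out, self.space.lower, self.space.upper)
        return snap_to_grid(out, self.space)

    def propose(self, rng: np.random.Generator) -> list[np.ndarray]:
        proposals = [self._step(x, rng) for x in self.current_x]
        self._accept_rng = rng
        return self._dedupe(proposals, rng, mutate=lambda p, r: self._step(p, r))

    @property
    def temperature(self) -> float:
        return self.config.T0 * self.config.cT**self.k

    def _update(self, points, values) -> None:
        rng = self._accept_rng or np.random.default_rng(0)
        T = self.temperature
        for i, (p, y) in enumerate(zip(points, values)):
            if i >= len(self.current_y):
                break
            delta = y - self.current_y[i]
            if delta >= 0 or rng.random() < math.exp(delta / T):
                self.current_x[i] = np.asarray(p, dtype=float)
                self.current_y[i] = float(y)
        self.k += 1
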