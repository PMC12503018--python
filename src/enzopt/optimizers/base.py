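"""Shared machinery for batch experiment-planning strategies.

All strategies propose batches of reaction conditions, receive the (noisy)
measured activities back, and keep a full history.  On a gridded space they
obey a no-repeat rule: no condition is proposed twice across the whole
campaign.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from typing import Optional, Sequence

import numpy as np

from ..design_space import DesignSpace, snap_to_grid

__all__ = ["BatchOptimizer", "RSOptimizer", "point_key", "grid_index"]


def point_key(point: np.ndarray) -> tuple:
    """Hashable identity for a point (robust to float noise)."""
    return tuple(np.round(np.asarray(point, dtype=float), 9))


def grid_index(space: DesignSpace, point: np.ndarray) -> int:
    """Flat C-order grid index of an on-grid point."""
    idx = []
    for x, spec in zip(point, space.specs):
        idx.append(int(round((x - spec.lower) / spec.step)))
    shape = tuple(s.n_levels for s in space.specs)
    return int(np.ravel_multi_index(tuple(idx), shape))


class BatchOptimizer(ABC):
    """Base class: history bookkeeping and the no-repeat rule."""

    #: the strategy supplies its own iteration-0 design (RSM does)
    provides_initial = False
    #: enforce global uniqueness of proposed points (RSM replicates instead)
    enforce_no_repeat = True

    def __init__(self, space: DesignSpace, batch_size: int = 8):
        if batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        self.space = space
        self.batch_size = batch_size
        self.history: list[tuple[np.ndarray, float]] = []
        self.tested: set[tuple] = set()
        self.exhausted = False
        self.n_updates = 0

    # -- campaign interface -------------------------------------------------

    def tell(self, points: Sequence[np.ndarray], values: Sequence[float]) -> None:
        """Record an evaluated batch and update internal state."""
        pts = [np.asarray(p, dtype=float) for p in points]
        for p, v in zip(pts, values):
            self.history.append((p, float(v)))
            self.tested.add(point_key(p))
        if self.n_updates == 0:
            self._initialize(pts, list(map(float, values)))
        else:
            self._update(pts, list(map(float, values)))
        self.n_updates += 1

    @abstractmethod
    def propose(self, rng: np.random.Generator) -> list[np.ndarray]:
        """Next batch of unevaluated conditions."""

    def initial_design(self, rng: np.random.Generator) -> Optional[list[np.ndarray]]:
        """Iteration-0 design, for strategies that fix their own (else None)."""
        return None

    # -- subclass hooks -----------------------------------------------------

    def _initialize(self, points: list[np.ndarray], values: list[float]) -> None:
        pass

    def _update(self, points: list[np.ndarray], values: list[float]) -> None:
        pass

    # -- helpers ------------------------------------------------------------

    @property
    def best(self) -> tuple[np.ndarray, float]:
        i = int(np.argmax([v for _, v in self.history]))
        return self.history[i]

    def is_tested(self, point: np.ndarray) -> bool:
        return point_key(point) in self.tested

    def _grid_cardinality(self) -> int:
        return self.space.grid_cardinality()

    def random_untested(
        self,
        rng: np.random.Generator,
        n: int,
        also_exclude: Optional[set] = None,
    ) -> list[np.ndarray]:
        """Seeded uniform draw of ``n`` untested grid points (without
        replacement); returns fewer and sets ``exhausted`` if the grid runs
        out."""
        exclude = set(self.tested)
        if also_exclude:
            exclude |= also_exclude
        card = self._grid_cardinality()
        n_free = card - len(exclude)
        if n_free <= 0:
            self.exhausted = True
            return []
        out: list[np.ndarray] = []
        chosen: set[tuple] = set()
        # rejection sampling; switch to full enumeration on small remainders
        attempts = 0
        while len(out) < n and attempts < 50 * n + 100:
            flat = int(rng.integers(card))
            p = self.space.point_from_index(flat)
            k = point_key(p)
            if k in exclude or k in chosen:
                attempts += 1
                continue
            out.append(p)
            chosen.add(k)
        if len(out) < n:
            # dense fallback: enumerate all free points, seeded choice
            from ..design_space import enumerate_grid

            free = [
                p
                for p in enumerate_grid(self.space)
                if point_key(p) not in exclude and point_key(p) not in chosen
            ]
            need = n - len(out)
            if len(free) <= need:
                out.extend(free)
                self.exhausted = True
            else:
                idx = rng.choice(len(free), size=need, replace=False)
                out.extend(free[i] for i in idx)
        return out

    def _dedupe(
        self,
        proposals: list[np.ndarray],
        rng: np.random.Generator,
        mutate=None,
        max_attempts: int = 100,
    ) -> list[np.ndarray]:
        """Enforce uniqueness within the batch and against history.

        Colliding proposals are re-drawn via ``mutate(point, rng)`` (up to
        ``max_attempts`` each) and finally replaced by seeded random untested
        grid points.
        """
        if not self.enforce_no_repeat:
            return proposals
        out: list[np.ndarray] = []
        batch_keys: set[tuple] = set()
        for p in proposals:
            cand = p
            ok = False
            for _ in range(max_attempts):
                k = point_key(cand)
                if k not in self.tested and k not in batch_keys:
                    ok = True
                    break
                if mutate is None:
                    break
                cand = mutate(cand, rng)
            if not ok:
                repl = self.random_untested(rng, 1, also_exclude=batch_keys)
                if not repl:
                    continue  # grid exhausted
                cand = repl[0]
            out.append(cand)
            batch_keys.add(point_key(cand))
        return out


class RSOptimizer(BatchOptimizer):
    """Random search: seeded uniform untested grid points, the unguided
    baseline every guided strategy is benchmarked against."""

    def propose(self, rng: np.random.Generator) -> list[np.ndarray]:
        batch = self.random_untested(rng, self.batch_size)
        if len(batch) < self.batch_size:
            self.exhausted = True
        return batch
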