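"""Batch Bayesian optimization on a discrete candidate grid.

Each iteration refits the GP surrogate to the full history (length-scale by
log marginal likelihood), then builds a batch of q conditions with the
Kriging-believer construction: the acquisition function is evaluated on all
untested grid candidates (or a seeded subsample on very large grids), the
argmax is taken (ties to the first candidate in deterministic grid order),
and its posterior mean is appended as a pseudo-observation before the next
batch member is selected.  Pseudo-observations are discarded afterwards;
kernel hyperparameters are not re-optimized within a batch.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from ..design_space import DesignSpace
from .base import BatchOptimizer, point_key
from .gp import BOConfig, GPModel, acquisition, fit_gp

__all__ = ["BOOptimizer", "propose_batch_bo"]

# grids larger than this are never materialized in full; a seeded subsample
# of _DEFAULT_SUBSAMPLE candidates is drawn per believer step instead
_EXHAUSTIVE_LIMIT = 200_000
_DEFAULT_SUBSAMPLE = 100_000


class _CandidateGrid:
    """Untested-candidate bookkeeping over the flat grid index."""

    def __init__(self, space: DesignSpace, config: BOConfig):
        if not space.is_gridded:
            raise ValueError("batch BO requires a gridded space")
        self.space = space
        self.card = space.grid_cardinality()
        sub = config.candidate_subsample
        if sub is None and self.card > _EXHAUSTIVE_LIMIT:
            sub = _DEFAULT_SUBSAMPLE
        self.subsample = sub
        self.tested = np.zeros(self.card, dtype=bool)
        if self.subsample is None:
            self._points = space.points_from_indices(np.arange(self.card))
        else:
            self._points = None

    def mark(self, point: np.ndarray) -> None:
        self.tested[self.space.index_of(point)] = True

    @property
    def n_untested(self) -> int:
        return self.card - int(self.tested.sum())

    def pool(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """(points, flat indices) of candidates, in ascending grid order."""
        if self.subsample is None:
            idx = np.flatnonzero(~self.tested)
            return self._points[idx], idx
        n = min(self.subsample, self.card)
        flat = np.sort(rng.choice(self.card, size=n, replace=False))
        flat = flat[~self.tested[flat]]
        return self.space.points_from_indices(flat), flat


def _believer_loop(
    model: GPModel,
    grid: _CandidateGrid,
    config: BOConfig,
    q: int,
    rng: np.random.Generator,
) -> tuple[list[np.ndarray], bool]:
    batch: list[np.ndarray] = []
    believer = model
    for _ in range(q):
        pts, flat = grid.pool(rng)
        if flat.size == 0:
            return batch, True
        mean, var = believer.predict(pts)
        acq = acquisition(mean, np.sqrt(var), believer.best_scaled, config)
        pick = int(np.argmax(acq))  # first max in deterministic grid order
        chosen = pts[pick]
        batch.append(chosen)
        grid.tested[flat[pick]] = True
        believer = believer.with_pseudo_observations(
            chosen[None, :], np.array([mean[pick]])
        )
    return batch, len(batch) < q


def propose_batch_bo(
    history: Sequence[tuple[np.ndarray, float]],
    space: DesignSpace,
    config: BOConfig,
    q: int,
    seed: int,
    model: Optional[GPModel] = None,
) -> tuple[list[np.ndarray], bool]:
    """Kriging-believer batch of ``q`` untested grid points.

    Returns ``(points, exhausted)``; ``exhausted`` is set when fewer than
    ``q`` untested candidates remain.  Passing a pre-fitted ``model`` skips
    the hyperparameter fit (the campaign fits once per iteration).
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    rng = np.random.default_rng(seed)
    if model is None:
        model = fit_gp(history, space, config, seed=seed)
    grid = _CandidateGrid(space, config)
    for p, _ in history:
        grid.mark(np.asarray(p, dtype=float))
    return _believer_loop(model, grid, config, q, rng)


class BOOptimizer(BatchOptimizer):
    """Campaign-facing batch BO with persistent candidate bookkeeping."""

    def __init__(
        self,
        space: DesignSpace,
        batch_size: int = 8,
        config: BOConfig = BOConfig(),
    ):
        super().__init__(space, batch_size)
        self.config = config
        self.model: Optional[GPModel] = None
        self._grid = _CandidateGrid(space, config)

    def tell(self, points, values) -> None:
        super().tell(points, values)
        for p in points:
            self._grid.mark(np.asarray(p, dtype=float))

    def propose(self, rng: np.random.Generator) -> list[np.ndarray]:
        seed = int(rng.integers(2**31 - 1))
        self.model = fit_gp(self.history, self.space, self.config, seed=seed)
        # work on a copy of the tested mask: believer picks become tested
        # only once the campaign reports their measured values back
        grid = _CandidateGrid.__new__(_CandidateGrid)
        grid.space = self._grid.space
        grid.card = self._grid.card
        grid.subsample = self._grid.subsample
        grid.tested = self._grid.tested.copy()
        grid._points = self._grid._points
        batch, exhausted = _believer_loop(
            self.model, grid, self.config, self.batch_size, rng
        )
        self.exhausted = self.exhausted or exhausted
        return batch
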