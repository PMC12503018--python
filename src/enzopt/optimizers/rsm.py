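"""Response-surface-methodology baseline.

Three rounds of a face-centred central composite design (CCD), each followed
by a full quadratic (interaction + squares) least-squares fit; the model
argmax over the current region recentres and halves the region for the next
round.  For the five-parameter problem each round spends 50 experiments
(32 factorial corners + 10 axial face points + 8 centre replicates), so the
complete procedure costs 150 experiments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ..design_space import Bounds, DesignSpace, shrink_recenter
from .base import BatchOptimizer

__all__ = [
    "QuadraticModel",
    "rsm_design_round",
    "fit_quadratic_model",
    "rsm_next_region",
    "RSMOptimizer",
    "run_rsm_procedure",
]

_CENTER_REPLICATES_D5 = 8


def rsm_design_round(bounds: Bounds, center_replicates: Optional[int] = None) -> list[np.ndarray]:
    """Face-centred CCD (alpha = 1) for one RSM round, all points in bounds.

    d=5 gives exactly 50 points: 2^5 corners, 2·5 axial face points, and 8
    centre replicates.  Other dimensionalities generalize with the same
    corner/axial structure; ``center_replicates`` defaults to 8.
    """
    d = bounds.ndim
    lo, hi, c = bounds.lower, bounds.upper, bounds.center
    pts: list[np.ndarray] = []
    for corner in itertools.product(*[(l, h) for l, h in zip(lo, hi)]):
        pts.append(np.array(corner, dtype=float))
    for i in range(d):
        for val in (lo[i], hi[i]):
            p = c.copy()
            p[i] = val
            pts.append(p)
    n_center = _CENTER_REPLICATES_D5 if center_replicates is None else center_replicates
    for _ in range(n_center):
        pts.append(c.copy())
    return pts


def _quadratic_features(x: np.ndarray) -> np.ndarray:
    """Design matrix columns: 1, d linear, d(d-1)/2 pairwise, d squared."""
    x = np.atleast_2d(x)
    n, d = x.shape
    cols = [np.ones(n)]
    cols.extend(x[:, i] for i in range(d))
    for i in range(d):
        for j in range(i + 1, d):
            cols.append(x[:, i] * x[:, j])
    cols.extend(x[:, i] ** 2 for i in range(d))
    return np.column_stack(cols)


@dataclass
class QuadraticModel:
    """Full quadratic interaction model on inputs scaled to [−1, 1] within
    the round's bounds; 21 coefficients for d=5."""

    coefficients: np.ndarray
    bounds: Bounds
    r_squared: float
    rank_deficient: bool = False
    degenerate_variance: bool = False

    def _scale(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        c, w = self.bounds.center, self.bounds.widths
        return 2.0 * (pts - c) / w

    def predict(self, points: np.ndarray) -> np.ndarray:
        return _quadratic_features(self._scale(points)) @ self.coefficients


def fit_quadratic_model(
    observations: Sequence[tuple[np.ndarray, float]],
    bounds: Bounds,
) -> QuadraticModel:
    """Least-squares quadratic fit; R² on the training observations.

    With fewer observations than coefficients the minimum-norm solution is
    returned and flagged.  A constant response (zero total variance, zero
    residual) reports R² = 1 with ``degenerate_variance`` set.
    """
    pts = np.array([np.asarray(p, dtype=float) for p, _ in observations])
    y = np.array([float(v) for _, v in observations])
    if not (np.all(np.isfinite(pts)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite observations")
    c, w = bounds.center, bounds.widths
    xs = 2.0 * (pts - c) / w
    X = _quadratic_features(xs)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    degenerate = ss_tot == 0.0
    r2 = 1.0 if degenerate else 1.0 - ss_res / ss_tot
    return QuadraticModel(
        coefficients=beta,
        bounds=bounds,
        r_squared=r2,
        rank_deficient=rank < X.shape[1],
        degenerate_variance=degenerate,
    )


def rsm_next_region(
    model: QuadraticModel,
    bounds: Bounds,
    global_bounds: Bounds,
    scan_levels: int = 21,
    shrink_factor: float = 0.5,
) -> tuple[np.ndarray, Bounds]:
    """Model argmax over a dense grid scan of the region, and the halved,
    recentred bounds for the next round (chunked evaluation keeps memory flat
    on the default 21-level scan)."""
    axes = [
        np.linspace(lo, hi, scan_levels)
        for lo, hi in zip(bounds.lower, bounds.upper)
    ]
    best_val = -np.inf
    best_pt: Optional[np.ndarray] = None
    chunk: list[np.ndarray] = []
    chunk_size = 200_000

    def flush(chunk_pts: list[np.ndarray]):
        nonlocal best_val, best_pt
        arr = np.array(chunk_pts)
        vals = model.predict(arr)
        i = int(np.argmax(vals))
        if vals[i] > best_val:
            best_val = float(vals[i])
            best_pt = arr[i]

    for combo in itertools.product(*axes):
        chunk.append(np.array(combo))
        if len(chunk) >= chunk_size:
            flush(chunk)
            chunk = []
    if chunk:
        flush(chunk)
    assert best_pt is not None
    new_bounds = shrink_recenter(bounds, best_pt, shrink_factor, global_bounds)
    return best_pt, new_bounds


class RSMOptimizer(BatchOptimizer):
    """Three fixed CCD rounds; supplies its own iteration-0 design.

    Centre replicates are part of the design, so the global no-repeat rule
    is waived.  After the third round the strategy is exhausted.
    """

    provides_initial = True
    enforce_no_repeat = False

    def __init__(
        self,
        space: DesignSpace,
        batch_size: int = 8,  # unused; rounds are 50-point designs
        n_rounds: int = 3,
        scan_levels: int = 21,
    ):
        super().__init__(space, batch_size)
        self.n_rounds = n_rounds
        self.scan_levels = scan_levels
        self.global_bounds = space.bounds()
        self.current_bounds = space.bounds()
        self.round_models: list[QuadraticModel] = []
        self.round_optima: list[np.ndarray] = []
        self._round_obs: list[tuple[np.ndarray, float]] = []
        self.rounds_done = 0

    def initial_design(self, rng: np.random.Generator) -> list[np.ndarray]:
        return rsm_design_round(self.current_bounds)

    def _finish_round(self, points, values) -> None:
        self._round_obs = list(zip(points, values))
        model = fit_quadratic_model(self._round_obs, self.current_bounds)
        self.round_models.append(model)
        opt, new_bounds = rsm_next_region(
            model,
            self.current_bounds,
            self.global_bounds,
            scan_levels=self.scan_levels,
        )
        self.round_optima.append(opt)
        self.current_bounds = new_bounds
        self.rounds_done += 1

    def _initialize(self, points, values) -> None:
        self._finish_round(points, values)

    def _update(self, points, values) -> None:
        self._finish_round(points, values)

    def propose(self, rng: np.random.Generator) -> list[np.ndarray]:
        if self.rounds_done >= self.n_rounds:
            self.exhausted = True
            return []
        return rsm_design_round(self.current_bounds)


def run_rsm_procedure(
    landscape,
    noise,
    seed: int,
    n_rounds: int = 3,
    scan_levels: int = 21,
):
    """Drive the full RSM procedure on a landscape with simulated noise.

    Returns a dict with the best observed activity, the per-round model R²
    values, the per-round model optima, and the experiment count.
    """
    from ..landscapes import apply_noise

    rng = np.random.default_rng(seed)
    space = landscape.domain
    opt = RSMOptimizer(space, n_rounds=n_rounds, scan_levels=scan_levels)
    batch = opt.initial_design(rng)
    best = -np.inf
    n_exp = 0
    while batch:
        values = [apply_noise(landscape.evaluate(p), noise, rng) for p in batch]
        opt.tell(batch, values)
        best = max(best, max(values))
        n_exp += len(values)
        batch = opt.propose(rng)
    return {
        "best_value": float(best),
        "r_squared": [m.r_squared for m in opt.round_models],
        "round_optima": opt.round_optima,
        "n_experiments": n_exp,
    }
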