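"""Parameter domain, grids, and experimental-design generators.

The search domain is a box of named reaction parameters (by default the five
used for peroxidase condition optimization: pH, temperature, salt, organic
solvent and cosubstrate concentration).  Each dimension may carry a step size,
in which case admissible values form a regular grid; intervals are closed at
both ends.  Design generators cover Latin hypercube initialization, 3-level
full-factorial screening designs with iterative range halving/recentring, and
the chunked execution order used to spread a screening design over plates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
from scipy.stats import qmc

__all__ = [
    "ParameterSpec",
    "DesignSpace",
    "Bounds",
    "htps_space",
    "grid_space",
    "snap_to_grid",
    "lhs_sample",
    "full_factorial_3",
    "shrink_recenter",
    "chunk_design",
    "enumerate_grid",
]

_REL_TOL = 1e-9


@dataclass(frozen=True)
class ParameterSpec:
    """One bounded reaction parameter, optionally gridded.

    Parameters
    ----------
    name : str
        Identifier, unique within a :class:`DesignSpace`.
    lower, upper : float
        Closed interval bounds in domain units.
    step : float, optional
        Grid spacing.  If given, ``(upper - lower) / step`` must be an
        integer (to 1e-9 relative tolerance) and admissible values are
        ``lower + k * step``.
    unit : str
        Unit label for reports.
    """

    name: str
    lower: float
    upper: float
    step: Optional[float] = None
    unit: str = ""

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(
                f"{self.name}: lower ({self.lower}) must be < upper ({self.upper})"
            )
        if self.step is not None:
            if self.step <= 0:
                raise ValueError(f"{self.name}: step must be positive")
            span = (self.upper - self.lower) / self.step
            if abs(span - round(span)) > _REL_TOL * max(1.0, abs(span)):
                raise ValueError(
                    f"{self.name}: range {self.upper - self.lower} is not an "
                    f"integer multiple of step {self.step}"
                )

    @property
    def n_levels(self) -> Optional[int]:
        """Number of grid levels, or None for a continuous dimension."""
        if self.step is None:
            return None
        return int(round((self.upper - self.lower) / self.step)) + 1

    def levels(self) -> np.ndarray:
        if self.step is None:
            raise ValueError(f"{self.name} is continuous (no step)")
        return self.lower + self.step * np.arange(self.n_levels)


# Table of the five default reaction parameters: (name, unit).
_DEFAULT_NAMES = (
    ("pH", "-"),
    ("temperature", "degC"),
    ("salt", "mM"),
    ("solvent", "%(v/v)"),
    ("cosubstrate", "mM"),
)


@dataclass(frozen=True)
class DesignSpace:
    """Ordered collection of :class:`ParameterSpec` defining the search box."""

    specs: tuple[ParameterSpec, ...]

    def __init__(self, specs: Sequence[ParameterSpec]):
        specs = tuple(specs)
        if len(specs) < 1:
            raise ValueError("a design space needs at least one dimension")
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate parameter names: {names}")
        object.__setattr__(self, "specs", specs)

    @property
    def ndim(self) -> int:
        return len(self.specs)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    @property
    def lower(self) -> np.ndarray:
        return np.array([s.lower for s in self.specs], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.array([s.upper for s in self.specs], dtype=float)

    @property
    def widths(self) -> np.ndarray:
        return self.upper - self.lower

    @property
    def is_gridded(self) -> bool:
        return all(s.step is not None for s in self.specs)

    def grid_cardinality(self) -> int:
        """Total number of grid points (without materializing the grid)."""
        if not self.is_gridded:
            raise ValueError("space is not fully gridded")
        return math.prod(s.n_levels for s in self.specs)

    def bounds(self) -> "Bounds":
        return Bounds(tuple((s.lower, s.upper) for s in self.specs))

    def contains(self, point: np.ndarray, atol: float = 1e-9) -> bool:
        p = np.asarray(point, dtype=float)
        return bool(
            np.all(p >= self.lower - atol) and np.all(p <= self.upper + atol)
        )

    def point_from_index(self, flat_index: int) -> np.ndarray:
        """Map a flat grid index (C order, first dimension slowest) to a point."""
        return self.points_from_indices(np.array([flat_index]))[0]

    def points_from_indices(self, flat_indices: np.ndarray) -> np.ndarray:
        """Vectorized flat-index -> point mapping; returns an (n, d) array."""
        shape = tuple(s.n_levels for s in self.specs)
        idx = np.unravel_index(np.asarray(flat_indices, dtype=np.int64), shape)
        cols = [
            s.lower + s.step * k.astype(float) for s, k in zip(self.specs, idx)
        ]
        return np.column_stack(cols)

    def index_of(self, point: np.ndarray) -> int:
        """Flat C-order grid index of an on-grid point."""
        shape = tuple(s.n_levels for s in self.specs)
        idx = tuple(
            int(round((x - s.lower) / s.step)) for x, s in zip(point, self.specs)
        )
        return int(np.ravel_multi_index(idx, shape))


@dataclass(frozen=True)
class Bounds:
    """Per-dimension (lower, upper) pairs; a sub-box of a global space."""

    pairs: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        for lo, hi in self.pairs:
            if not lo < hi:
                raise ValueError(f"invalid bounds ({lo}, {hi})")

    @property
    def ndim(self) -> int:
        return len(self.pairs)

    @property
    def lower(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=float)

    @property
    def widths(self) -> np.ndarray:
        return self.upper - self.lower

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)

    def contains(self, point: np.ndarray, atol: float = 1e-9) -> bool:
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= self.lower - atol) and np.all(p <= self.upper + atol))

    @staticmethod
    def from_arrays(lower: np.ndarray, upper: np.ndarray) -> "Bounds":
        return Bounds(tuple((float(l), float(u)) for l, u in zip(lower, upper)))


def htps_space() -> DesignSpace:
    """Continuous screening space (pH 2.5–8, 20–60 degC, 0–500 mM salt,
    0–30 %(v/v) solvent, 0–10 mM cosubstrate)."""
    ranges = [(2.5, 8.0), (20.0, 60.0), (0.0, 500.0), (0.0, 30.0), (0.0, 10.0)]
    return DesignSpace(
        [
            ParameterSpec(name, lo, hi, None, unit)
            for (name, unit), (lo, hi) in zip(_DEFAULT_NAMES, ranges)
        ]
    )


def grid_space() -> DesignSpace:
    """Discretized deployment space (pH 2.4–8 step 0.2; temperature 20–60 step 2;
    salt 0–500 step 25; solvent 0–30 step 2.5; cosubstrate 0–10 step 0.2)."""
    ranges = [
        (2.4, 8.0, 0.2),
        (20.0, 60.0, 2.0),
        (0.0, 500.0, 25.0),
        (0.0, 30.0, 2.5),
        (0.0, 10.0, 0.2),
    ]
    return DesignSpace(
        [
            ParameterSpec(name, lo, hi, step, unit)
            for (name, unit), (lo, hi, step) in zip(_DEFAULT_NAMES, ranges)
        ]
    )


def snap_to_grid(point: np.ndarray, space: DesignSpace) -> np.ndarray:
    """Move each coordinate to the nearest grid level; exact ties go to the
    lower level.  Idempotent; continuous dimensions pass through unchanged.
    """
    p = np.asarray(point, dtype=float)
    if not space.contains(p):
        raise ValueError(f"point {p} outside space bounds")
    out = p.copy()
    for i, spec in enumerate(space.specs):
        if spec.step is None:
            continue
        t = (p[i] - spec.lower) / spec.step
        k_low = math.floor(t + _REL_TOL)
        frac = t - k_low
        # tie (frac == 0.5) breaks toward the lower level
        k = k_low if frac <= 0.5 + _REL_TOL else k_low + 1
        k = min(max(k, 0), spec.n_levels - 1)
        out[i] = spec.lower + k * spec.step
    return out


def lhs_sample(space: DesignSpace, n: int, seed: int) -> list[np.ndarray]:
    """Latin hypercube sample of ``n`` points.

    Before any grid snapping, each dimension has exactly one sample in each of
    ``n`` equal-width strata of its range (random position within the stratum,
    no centring).  Gridded dimensions are then snapped, which may create
    coincident coordinates when ``n`` exceeds the number of levels.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=space.ndim, seed=seed)
    unit = sampler.random(n)
    pts = qmc.scale(unit, space.lower, space.upper)
    if space.is_gridded:
        return [snap_to_grid(p, space) for p in pts]
    return [np.asarray(p, dtype=float) for p in pts]


def full_factorial_3(bounds: Bounds) -> list[np.ndarray]:
    """3-level full factorial: Cartesian product of {lower, mid, upper} per
    dimension; 3^d points, centre included exactly once."""
    levels = [
        (lo, 0.5 * (lo + hi), hi) for lo, hi in zip(bounds.lower, bounds.upper)
    ]
    return [np.array(combo, dtype=float) for combo in itertools.product(*levels)]


def shrink_recenter(
    bounds: Bounds,
    best: np.ndarray,
    factor: float,
    global_bounds: Bounds,
) -> Bounds:
    """Shrink each dimension's width by ``factor``, centred on ``best``, then
    shift (never shrink further) so the interval stays inside
    ``global_bounds``.  This is the range-halving step of the iterative
    factorial screening when ``factor=0.5``."""
    if not 0.0 < factor < 1.0:
        raise ValueError("factor must be in (0, 1)")
    best = np.asarray(best, dtype=float)
    if not bounds.contains(best):
        raise ValueError("best point must lie within the current bounds")
    new_w = factor * bounds.widths
    lo = best - 0.5 * new_w
    hi = best + 0.5 * new_w
    # shift into global box
    shift = np.maximum(global_bounds.lower - lo, 0.0)
    lo += shift
    hi += shift
    shift = np.maximum(hi - global_bounds.upper, 0.0)
    lo -= shift
    hi -= shift
    return Bounds.from_arrays(lo, hi)


def chunk_design(
    points: Sequence[np.ndarray],
    n_chunks: int,
    center: np.ndarray,
    seed: int,
) -> list[list[np.ndarray]]:
    """Split a design into execution chunks.

    Points are sorted lexicographically by coordinates (pH and temperature
    leading, given the default dimension order), split into ``n_chunks``
    near-equal contiguous chunks, the centre point is appended to every chunk
    that lacks it (as a repeated control), and each chunk is shuffled with a
    seeded permutation.
    """
    if n_chunks < 1:
        raise ValueError("n_chunks must be >= 1")
    pts = [np.asarray(p, dtype=float) for p in points]
    if not pts:
        raise ValueError("points must be non-empty")
    arr = np.array(pts)
    order = np.lexsort(tuple(arr[:, i] for i in range(arr.shape[1] - 1, -1, -1)))
    sorted_pts = [pts[i] for i in order]
    raw_chunks = np.array_split(np.arange(len(sorted_pts)), n_chunks)
    center = np.asarray(center, dtype=float)
    rng = np.random.default_rng(seed)
    chunks: list[list[np.ndarray]] = []
    for idxs in raw_chunks:
        chunk = [sorted_pts[i] for i in idxs]
        if not any(np.allclose(p, center) for p in chunk):
            chunk.append(center.copy())
        perm = rng.permutation(len(chunk))
        chunks.append([chunk[i] for i in perm])
    return chunks


def enumerate_grid(
    space: DesignSpace,
    subsample: Optional[int] = None,
    seed: int = 0,
) -> Iterator[np.ndarray]:
    """Yield grid points in deterministic C order (first dimension slowest).

    With ``subsample``, yields a seeded uniform sample of that size without
    replacement instead (still deterministic for a fixed seed).
    """
    if not space.is_gridded:
        raise ValueError("space is not fully gridded")
    card = space.grid_cardinality()
    if subsample is None:
        for combo in itertools.product(*(s.levels() for s in space.specs)):
            yield np.array(combo, dtype=float)
    else:
        if subsample > card:
            raise ValueError(
                f"subsample {subsample} exceeds grid cardinality {card}"
            )
        rng = np.random.default_rng(seed)
        flat = rng.choice(card, size=subsample, replace=False)
        for f in flat:
            yield space.point_from_index(int(f))
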