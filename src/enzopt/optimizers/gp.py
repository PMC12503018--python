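"""Gaussian-process surrogate and acquisition functions for batch BO.

The GP works on a normalized problem: inputs scaled to the unit cube by the
global design-space bounds, outputs min–max scaled to [0, 1] over the current
history.  On that scale a fixed homoscedastic noise variance of 0.02 reflects
the 13.2 % assay coefficient of variation, the kernel amplitude is pinned at
1 (zero-mean prior, unit prior variance), and only the Matérn length scale is
fitted — by log-marginal-likelihood maximization from seeded random restarts.

Regression itself is delegated to scikit-learn's GaussianProcessRegressor;
the Matérn closed forms and the acquisition functions (EI, UCB, PI) are
implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, Matern

from ..design_space import DesignSpace

__all__ = [
    "BOConfig",
    "GPModel",
    "matern_covariance",
    "fit_gp",
    "acquisition",
]

KernelName = Literal["matern12", "matern32", "matern52", "rbf"]
AcquisitionName = Literal["EI", "UCB", "PI"]

_KERNEL_NU = {"matern12": 0.5, "matern32": 1.5, "matern52": 2.5, "rbf": math.inf}


@dataclass(frozen=True)
class BOConfig:
    """Bayesian-optimization hyperparameters (defaults = best screened
    variant: Matérn 3/2 kernel with expected improvement)."""

    kernel: KernelName = "matern32"
    acquisition: AcquisitionName = "EI"
    noise_variance: float = 0.02  # on the [0, 1] output scale
    n_restarts: int = 10
    xi: float = 0.01  # EI / PI improvement offset
    kappa: float = 2.0  # UCB exploration weight
    candidate_subsample: Optional[int] = None

    def __post_init__(self) -> None:
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.kernel not in _KERNEL_NU:
            raise ValueError(f"unknown kernel {self.kernel!r}")


def matern_covariance(r: float, length_scale: float, nu: float) -> float:
    """Matérn correlation at distance ``r`` (k(0) = 1, unit amplitude).

    Supports nu in {0.5, 1.5, 2.5, inf}; nu=inf is the squared exponential.
    """
    if length_scale <= 0:
        raise ValueError("length_scale must be positive")
    if r < 0:
        raise ValueError("distance must be nonnegative")
    s = r / length_scale
    if nu == 0.5:
        return math.exp(-s)
    if nu == 1.5:
        a = math.sqrt(3.0) * s
        return (1.0 + a) * math.exp(-a)
    if nu == 2.5:
        a = math.sqrt(5.0) * s
        return (1.0 + a + a * a / 3.0) * math.exp(-a)
    if nu == math.inf:
        return math.exp(-0.5 * s * s)
    raise ValueError(f"unsupported nu {nu}")


@dataclass
class GPModel:
    """Fitted GP with the scaling needed to move between raw and model space.

    ``predict`` returns the latent posterior mean and variance on the scaled
    output space; ``y_lo``/``y_hi`` undo the min–max output scaling.
    """

    gpr: GaussianProcessRegressor
    space: DesignSpace
    y_lo: float
    y_hi: float
    config: BOConfig
    x_train: np.ndarray  # scaled inputs
    y_train: np.ndarray  # scaled outputs

    def scale_x(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.space.lower) / self.space.widths

    def scale_y(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.y_hi == self.y_lo:
            return np.full_like(values, 0.5)
        return (values - self.y_lo) / (self.y_hi - self.y_lo)

    def unscale_y(self, scaled: np.ndarray) -> np.ndarray:
        return self.y_lo + np.asarray(scaled) * (self.y_hi - self.y_lo)

    def predict(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and variance (scaled space) at raw-space points."""
        mean, std = self.gpr.predict(self.scale_x(points), return_std=True)
        return mean, std**2

    @property
    def best_scaled(self) -> float:
        return float(self.y_train.max())

    def with_pseudo_observations(
        self, points: np.ndarray, values_scaled: np.ndarray
    ) -> "GPModel":
        """Refit with extra (point, scaled value) pairs at *fixed* kernel
        hyperparameters — the believer update used inside batch proposal."""
        x_new = np.vstack([self.x_train, self.scale_x(points)])
        y_new = np.concatenate([self.y_train, np.atleast_1d(values_scaled)])
        gpr = GaussianProcessRegressor(
            kernel=self.gpr.kernel_,  # fitted kernel, frozen
            alpha=self.config.noise_variance,
            optimizer=None,
        )
        gpr.fit(x_new, y_new)
        return GPModel(
            gpr=gpr,
            space=self.space,
            y_lo=self.y_lo,
            y_hi=self.y_hi,
            config=self.config,
            x_train=x_new,
            y_train=y_new,
        )


def _make_kernel(config: BOConfig, length_scale: float = 1.0, fixed: bool = False):
    bounds = "fixed" if fixed else (1e-3, 1e3)
    nu = _KERNEL_NU[config.kernel]
    if math.isinf(nu):
        return RBF(length_scale=length_scale, length_scale_bounds=bounds)
    return Matern(length_scale=length_scale, length_scale_bounds=bounds, nu=nu)


def fit_gp(
    history: Sequence[tuple[np.ndarray, float]],
    space: DesignSpace,
    config: BOConfig,
    seed: int = 0,
    length_scale: Optional[float] = None,
) -> GPModel:
    """Fit the GP surrogate to evaluated (point, activity) pairs.

    Inputs are scaled to the unit cube by the *global* space bounds and
    outputs min–max scaled to [0, 1] over the history (an all-equal history
    maps to 0.5 everywhere).  The isotropic length scale is optimized by log
    marginal likelihood from ``config.n_restarts`` seeded random starts;
    passing ``length_scale`` skips optimization and freezes it (used by
    closed-form oracles and believer updates).
    """
    if not history:
        raise ValueError("history must contain at least one observation")
    pts = np.array([np.asarray(p, dtype=float) for p, _ in history])
    vals = np.array([float(v) for _, v in history])
    if not (np.all(np.isfinite(pts)) and np.all(np.isfinite(vals))):
        raise ValueError("non-finite values in history")
    y_lo, y_hi = float(vals.min()), float(vals.max())
    x = (pts - space.lower) / space.widths
    y = np.full_like(vals, 0.5) if y_hi == y_lo else (vals - y_lo) / (y_hi - y_lo)

    fixed = length_scale is not None
    kernel = _make_kernel(config, length_scale or 1.0, fixed=fixed)
    gpr = GaussianProcessRegressor(
        kernel=kernel,
        alpha=config.noise_variance,
        optimizer=None if fixed else "fmin_l_bfgs_b",
        n_restarts_optimizer=0 if fixed else config.n_restarts,
        normalize_y=False,  # zero-mean prior on the scaled outputs
        random_state=seed,
    )
    gpr.fit(x, y)
    return GPModel(
        gpr=gpr,
        space=space,
        y_lo=y_lo,
        y_hi=y_hi,
        config=config,
        x_train=x,
        y_train=y,
    )


def acquisition(
    mean: np.ndarray,
    sd: np.ndarray,
    best: float,
    config: BOConfig,
) -> np.ndarray:
    """Acquisition value(s) on the scaled-output space.

    EI  = (mean − best − xi)·Φ(z) + sd·φ(z),  z = (mean − best − xi)/sd,
          reducing to max(mean − best − xi, 0) at sd = 0;
    PI  = Φ(z), reducing to 1{mean > best + xi} at sd = 0;
    UCB = mean + kappa·sd.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd < 0):
        raise ValueError("sd must be nonnegative")
    imp = mean - best - config.xi
    if config.acquisition == "UCB":
        return mean + config.kappa * sd
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, imp / np.where(sd > 0, sd, 1.0), 0.0)
    z = np.clip(z, -40.0, 40.0)  # Φ/φ saturate; avoids overflow in φ
    if config.acquisition == "EI":
        ei = imp * norm.cdf(z) + sd * norm.pdf(z)
        return np.where(sd > 0, ei, np.maximum(imp, 0.0))
    if config.acquisition == "PI":
        return np.where(sd > 0, norm.cdf(z), (imp > 0).astype(float))
    raise ValueError(f"unknown acquisition {config.acquisition!r}")
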