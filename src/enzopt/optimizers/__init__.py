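"""Experiment-planning strategies for batch reaction-condition optimization.

Six strategies are available: batch Bayesian optimization on a discrete grid
(GP + Matérn kernel + EI/UCB/PI with Kriging-believer batching), a genetic
algorithm, particle swarm optimization, simulated annealing, random search,
and a three-round response-surface-methodology baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Union

from ..design_space import DesignSpace
from .base import BatchOptimizer, RSOptimizer, grid_index, point_key
from .bo import BOOptimizer, propose_batch_bo
from .evolutionary import (
    GAConfig,
    GAOptimizer,
    PSOConfig,
    PSOOptimizer,
    SAConfig,
    SAOptimizer,
    rank_selection_probabilities,
)
from .gp import BOConfig, GPModel, acquisition, fit_gp, matern_covariance
from .rsm import (
    QuadraticModel,
    RSMOptimizer,
    fit_quadratic_model,
    rsm_design_round,
    rsm_next_region,
)

__all__ = [
    "AlgorithmVariant",
    "make_optimizer",
    "BatchOptimizer",
    "RSOptimizer",
    "BOOptimizer",
    "GAOptimizer",
    "PSOOptimizer",
    "SAOptimizer",
    "RSMOptimizer",
    "BOConfig",
    "GAConfig",
    "PSOConfig",
    "SAConfig",
    "GPModel",
    "QuadraticModel",
    "matern_covariance",
    "fit_gp",
    "acquisition",
    "propose_batch_bo",
    "fit_quadratic_model",
    "rsm_design_round",
    "rsm_next_region",
    "rank_selection_probabilities",
    "grid_index",
    "point_key",
]

OptimizerConfig = Union[BOConfig, GAConfig, PSOConfig, SAConfig, None]

_ALGORITHMS = {
    "bo": (BOOptimizer, BOConfig),
    "ga": (GAOptimizer, GAConfig),
    "pso": (PSOOptimizer, PSOConfig),
    "sa": (SAOptimizer, SAConfig),
    "rs": (RSOptimizer, type(None)),
    "rsm": (RSMOptimizer, type(None)),
}


@dataclass(frozen=True)
class AlgorithmVariant:
    """An algorithm id plus its hyperparameter configuration."""

    algorithm: str
    config: OptimizerConfig = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.algorithm not in _ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; "
                f"choose from {sorted(_ALGORITHMS)}"
            )
        _, cfg_type = _ALGORITHMS[self.algorithm]
        cfg = self.config
        if cfg_type is type(None):
            if cfg is not None:
                raise ValueError(f"{self.algorithm} takes no config")
        elif cfg is None:
            object.__setattr__(self, "config", cfg_type())
        elif not isinstance(cfg, cfg_type):
            raise ValueError(
                f"{self.algorithm} expects {cfg_type.__name__}, "
                f"got {type(cfg).__name__}"
            )
        if not self.label:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        if self.config is None:
            return self.algorithm
        parts = [
            f"{k}={v}" for k, v in sorted(vars(self.config).items())
            if v is not None
        ]
        return f"{self.algorithm}({','.join(parts)})"


def make_optimizer(
    variant: AlgorithmVariant, space: DesignSpace, batch_size: int = 8
) -> BatchOptimizer:
    """Instantiate the strategy behind a variant on a given space."""
    cls, _ = _ALGORITHMS[variant.algorithm]
    if variant.config is None:
        return cls(space, batch_size)
    return cls(space, batch_size, config=variant.config)
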