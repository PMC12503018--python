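"""Grid search over algorithm variants on a fixed landscape.

Every variant is run once per shared initial Latin-hypercube set (30 sets in
the screening protocol), with the lack-of-improvement stop active; mean and
sample standard deviation of the highest activity and of the iterations to
stop are aggregated per variant and ranked.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .campaign import CampaignConfig, CampaignResult, run_campaign
from .design_space import DesignSpace, lhs_sample
from .landscapes import Landscape, NoiseModel
from .optimizers import (
    AlgorithmVariant,
    BOConfig,
    GAConfig,
    PSOConfig,
    SAConfig,
)

__all__ = [
    "InitialSets",
    "BenchmarkResult",
    "make_initial_sets",
    "expand_variant_grid",
    "run_benchmark",
    "rank_variants",
    "default_variant_grids",
]


@dataclass
class InitialSets:
    """The shared iteration-0 batches (points plus their derived seeds)."""

    batches: list[list[np.ndarray]]
    seeds: list[int]
    master_seed: int

    def __len__(self) -> int:
        return len(self.batches)

    def to_json(self) -> str:
        return json.dumps(
            {
                "master_seed": self.master_seed,
                "seeds": self.seeds,
                "batches": [
                    [[float(x) for x in p] for p in batch]
                    for batch in self.batches
                ],
            }
        )

    @staticmethod
    def from_json(text: str) -> "InitialSets":
        d = json.loads(text)
        return InitialSets(
            batches=[
                [np.array(p, dtype=float) for p in batch]
                for batch in d["batches"]
            ],
            seeds=list(d["seeds"]),
            master_seed=d["master_seed"],
        )


def make_initial_sets(
    space: DesignSpace,
    n_sets: int = 30,
    batch_size: int = 8,
    master_seed: int = 0,
) -> InitialSets:
    """``n_sets`` LHS batches from per-set seeds derived off the master seed,
    reusable bit-identically across variants and sessions."""
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    ss = np.random.SeedSequence(master_seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_sets)]
    batches = [lhs_sample(space, batch_size, seed=s) for s in seeds]
    return InitialSets(batches=batches, seeds=seeds, master_seed=master_seed)


def default_variant_grids() -> dict[str, dict[str, list]]:
    """Hyperparameter grids per algorithm: the values reported for the
    top-ranked screened variants plus symmetric neighbours."""
    return {
        "ga": {
            "elitism": [1, 2],
            "mutation_probability": [0.1, 0.2, 0.4, 0.8],
            "mutation_extent": [0.3, 0.6],
            "crossover": ["random", "single_point"],
            "selection": ["rank"],
        },
        "pso": {
            "w0": [0.9, 1.1],
            "cd": [0.85, 0.95],
            "c1": [1.5, 2.0, 2.5],
            "c2": [1.0, 1.5],
        },
        "sa": {
            "T0": [75.0, 150.0, 380.0],
            "cT": [0.5, 0.6, 0.7, 0.9],
            "S0": [0.4, 0.8],
        },
        "bo": {
            "kernel": ["matern12", "matern32", "matern52", "rbf"],
            "acquisition": ["EI", "UCB", "PI"],
        },
    }


_CONFIG_TYPES = {"ga": GAConfig, "pso": PSOConfig, "sa": SAConfig, "bo": BOConfig}


def expand_variant_grid(
    grids: dict[str, dict[str, list]]
) -> list[AlgorithmVariant]:
    """Cartesian product of each algorithm's hyperparameter grid, in
    deterministic order."""
    variants: list[AlgorithmVariant] = []
    for algo in sorted(grids):
        grid = grids[algo]
        if not grid:
            raise ValueError(f"empty grid for {algo}")
        if algo in _CONFIG_TYPES:
            keys = sorted(grid)
            for combo in itertools.product(*(grid[k] for k in keys)):
                cfg = _CONFIG_TYPES[algo](**dict(zip(keys, combo)))
                variants.append(AlgorithmVariant(algorithm=algo, config=cfg))
        else:  # rs / rsm take no hyperparameters
            variants.append(AlgorithmVariant(algorithm=algo))
    return variants


@dataclass
class BenchmarkResult:
    """Per-variant aggregates plus the raw per-set campaign results."""

    table: pd.DataFrame  # label, algorithm, mean_best, sd_best, mean_iters, sd_iters, n_runs
    raw: dict[str, list[CampaignResult]]
    initial_sets: InitialSets

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _cell_key(
    variant: AlgorithmVariant, set_index: int, config: CampaignConfig
) -> str:
    payload = f"{variant.label}|{set_index}|{config}"
    return hashlib.sha256(payload.encode()).hexdigest()[:24]


def run_benchmark(
    variants: Sequence[AlgorithmVariant],
    landscape: Landscape,
    noise: NoiseModel,
    initial_sets: InitialSets,
    config: CampaignConfig,
    cache_dir: Optional[Path] = None,
) -> BenchmarkResult:
    """Run every variant on every shared initial set and aggregate.

    Campaign seeds are the per-set seeds, so any two variants see identical
    iteration-0 batches and identical noise streams per set.  With
    ``cache_dir`` per-cell manifests are written and reused on resume.
    Individual campaign failures are recorded (NaN row contribution), not
    fatal.
    """
    rows = []
    raw: dict[str, list[CampaignResult]] = {}
    for variant in variants:
        results: list[CampaignResult] = []
        for i, batch in enumerate(initial_sets.batches):
            cell_cfg = CampaignConfig(
                batch_size=config.batch_size,
                max_iterations=config.max_iterations,
                y_target=config.y_target,
                convergence_window=config.convergence_window,
                convergence_threshold=config.convergence_threshold,
                stop_on_convergence=config.stop_on_convergence,
                seed=initial_sets.seeds[i],
            )
            cache_file = None
            if cache_dir is not None:
                cache_dir = Path(cache_dir)
                cache_dir.mkdir(parents=True, exist_ok=True)
                cache_file = cache_dir / f"{_cell_key(variant, i, cell_cfg)}.json"
            try:
                res = run_campaign(
                    variant, landscape, noise, landscape.domain, cell_cfg,
                    initial_batch=batch,
                )
                results.append(res)
                if cache_file is not None:
                    cache_file.write_text(res.to_json())
            except Exception as exc:  # record, don't abort the screen
                results.append(None)  # type: ignore[arg-type]
                rows_note = f"campaign failed for {variant.label} set {i}: {exc}"
                print(rows_note)
        raw[variant.label] = results
        ok = [r for r in results if r is not None]
        bests = np.array([r.best_value for r in ok])
        iters = np.array([r.iterations_run - 1 for r in ok], dtype=float)
        rows.append(
            {
                "label": variant.label,
                "algorithm": variant.algorithm,
                "mean_best": bests.mean() if ok else np.nan,
                "sd_best": bests.std(ddof=1) if len(ok) > 1 else np.nan,
                "mean_iters": iters.mean() if ok else np.nan,
                "sd_iters": iters.std(ddof=1) if len(ok) > 1 else np.nan,
                "n_runs": len(ok),
            }
        )
    return BenchmarkResult(
        table=pd.DataFrame(rows), raw=raw, initial_sets=initial_sets
    )


def rank_variants(result: BenchmarkResult, k: int) -> pd.DataFrame:
    """Top-k variants by mean best activity (descending); ties broken by
    fewer mean iterations, then label."""
    if k > len(result.table):
        raise ValueError("k exceeds the number of variants")
    t = result.table.sort_values(
        by=["mean_best", "mean_iters", "label"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return t.head(k).reset_index(drop=True)
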