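"""Dataset CSV round-trip, run configuration, and result serialization.

Canonical dataset schema (header required, UTF-8, decimal point):
``pH, temperature_C, na2so4_mM, acn_pct_vv, h2o2_mM, activity_U_per_mg,
replicate``.  Note the file column order carries salt/solvent/cosubstrate,
while the in-memory point order is (pH, temperature, salt, solvent,
cosubstrate) — the mapping below is fixed.  Other column names (e.g. from a
third-party deposition) are adapted via a column-mapping dict in the config.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .design_space import DesignSpace, ParameterSpec, grid_space, htps_space
from .landscapes import Dataset, Observation
from .optimizers import (
    AlgorithmVariant,
    BOConfig,
    GAConfig,
    PSOConfig,
    SAConfig,
)
from .campaign import CampaignConfig, CampaignResult

__all__ = [
    "CANONICAL_COLUMNS",
    "read_dataset",
    "write_dataset",
    "load_config",
    "parse_design_space",
    "parse_variant",
    "parse_campaign_config",
    "write_campaign_outputs",
]

# canonical column -> point dimension index (activity/replicate excluded)
CANONICAL_COLUMNS = {
    "pH": 0,
    "temperature_C": 1,
    "na2so4_mM": 2,
    "acn_pct_vv": 3,
    "h2o2_mM": 4,
}
ACTIVITY_COLUMN = "activity_U_per_mg"
REPLICATE_COLUMN = "replicate"


def read_dataset(
    path,
    space: Optional[DesignSpace] = None,
    column_mapping: Optional[dict[str, str]] = None,
) -> Dataset:
    """Read a dataset CSV (canonical schema, or mapped via
    ``column_mapping``: canonical name -> file column name).

    Rows with non-finite activity are dropped with a printed count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path} contains no rows")
    mapping = {c: c for c in list(CANONICAL_COLUMNS) + [ACTIVITY_COLUMN, REPLICATE_COLUMN]}
    if column_mapping:
        mapping.update(column_mapping)
    for canonical, actual in mapping.items():
        if canonical == REPLICATE_COLUMN:
            continue  # optional
        if actual not in df.columns:
            raise ValueError(
                f"missing column {actual!r} (for canonical field {canonical!r})"
            )
    space = space if space is not None else htps_space()
    n_bad = int((~np.isfinite(df[mapping[ACTIVITY_COLUMN]])).sum())
    if n_bad:
        print(f"read_dataset: dropping {n_bad} rows with non-finite activity")
        df = df[np.isfinite(df[mapping[ACTIVITY_COLUMN]])]
    has_rep = mapping[REPLICATE_COLUMN] in df.columns
    obs = []
    for _, row in df.iterrows():
        point = np.empty(5)
        for canonical, dim in CANONICAL_COLUMNS.items():
            point[dim] = float(row[mapping[canonical]])
        obs.append(
            Observation(
                point=point,
                activity=float(row[mapping[ACTIVITY_COLUMN]]),
                replicate_id=int(row[mapping[REPLICATE_COLUMN]]) if has_rep else 0,
            )
        )
    return Dataset(observations=obs, space=space)


def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset in the canonical CSV schema (full double precision)."""
    rows = []
    for obs in dataset.observations:
        row = {c: repr(float(obs.point[d])) for c, d in CANONICAL_COLUMNS.items()}
        row[ACTIVITY_COLUMN] = repr(float(obs.activity))
        row[REPLICATE_COLUMN] = obs.replicate_id
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Config parsing
# ---------------------------------------------------------------------------

_VARIANT_CONFIGS = {"bo": BOConfig, "ga": GAConfig, "pso": PSOConfig, "sa": SAConfig}


class ConfigError(ValueError):
    """Raised on schema violations in a run config."""


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    return cfg


def parse_design_space(block) -> DesignSpace:
    """Design-space block: "htps" / "grid" or a list of
    {name, lower, upper, step?, unit?} dicts."""
    if block in (None, "grid"):
        return grid_space()
    if block == "htps":
        return htps_space()
    if not isinstance(block, list):
        raise ConfigError("design_space must be 'htps', 'grid', or a list")
    specs = []
    for item in block:
        unknown = set(item) - {"name", "lower", "upper", "step", "unit"}
        if unknown:
            raise ConfigError(f"unknown design-space keys: {sorted(unknown)}")
        try:
            specs.append(
                ParameterSpec(
                    name=item["name"],
                    lower=float(item["lower"]),
                    upper=float(item["upper"]),
                    step=float(item["step"]) if item.get("step") is not None else None,
                    unit=item.get("unit", ""),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"bad design-space entry {item}: {exc}") from exc
    return DesignSpace(specs)


def parse_variant(block) -> AlgorithmVariant:
    """Algorithm block: {algorithm: ga|pso|sa|bo|rs|rsm, params: {...}}."""
    if not isinstance(block, dict) or "algorithm" not in block:
        raise ConfigError("algorithm block must contain an 'algorithm' key")
    unknown = set(block) - {"algorithm", "params", "label"}
    if unknown:
        raise ConfigError(f"unknown algorithm keys: {sorted(unknown)}")
    algo = block["algorithm"]
    params = block.get("params") or {}
    try:
        if algo in _VARIANT_CONFIGS:
            cfg = _VARIANT_CONFIGS[algo](**params)
            return AlgorithmVariant(algo, cfg, label=block.get("label", ""))
        if params:
            raise ConfigError(f"{algo} takes no params")
        return AlgorithmVariant(algo, label=block.get("label", ""))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad algorithm block: {exc}") from exc


def parse_campaign_config(block, seed: int) -> CampaignConfig:
    block = block or {}
    unknown = set(block) - {
        "batch_size",
        "max_iterations",
        "y_target",
        "convergence_window",
        "convergence_threshold",
        "stop_on_convergence",
    }
    if unknown:
        raise ConfigError(f"unknown campaign keys: {sorted(unknown)}")
    try:
        return CampaignConfig(seed=seed, **block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad campaign block: {exc}") from exc


def write_campaign_outputs(
    result: CampaignResult, space: DesignSpace, out_dir
) -> None:
    """JSON manifest plus a per-experiment CSV
    (iteration, coordinates, noisy value, best-so-far)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(result.to_json())
    rows = []
    for it, (pts, vals) in enumerate(result.iterations):
        for p, v in zip(pts, vals):
            row = {"iteration": it}
            row.update(
                {name: repr(float(x)) for name, x in zip(space.names, p)}
            )
            row["activity_U_per_mg"] = repr(float(v))
            row["best_so_far"] = repr(float(result.best_trace[it]))
            rows.append(row)
    pd.DataFrame(rows).to_csv(out / "experiments.csv", index=False)
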