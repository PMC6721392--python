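"""Patient-table and configuration I/O.

The patient table is plain comma-separated text with a header row, UTF-8,
"." decimal separator, empty fields for missing values. Configuration
files (generator settings, thresholds) are YAML key/value documents.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .classify import Thresholds
from .cohort import BINARY_FLAGS, CohortConfig, GroupParams
from .exceptions import ConfigError
from .labels import DiagnosisLabel

__all__ = ["read_table", "write_table", "load_config", "save_config", "thresholds_from_dict"]

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False}


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a patient table as CSV (full float precision, empty = missing)."""
    table.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a patient table written by :func:`write_table`."""
    table = pd.read_csv(path)
    for flag in BINARY_FLAGS:
        if flag in table.columns and table[flag].dtype == object:
            table[flag] = table[flag].map(lambda v: _BOOL_MAP.get(str(v).strip().lower(), v))
    return table


def thresholds_from_dict(data: dict[str, Any]) -> Thresholds:
    valid = {f for f in Thresholds.__dataclass_fields__}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown threshold keys: {sorted(unknown)}")
    return Thresholds(**data)


def cohort_config_from_dict(data: dict[str, Any]) -> CohortConfig:
    kwargs: dict[str, Any] = {}
    if "group_sizes" in data:
        kwargs["group_sizes"] = {DiagnosisLabel(k): int(v) for k, v in data["group_sizes"].items()}
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "confusion" in data:
        kwargs["confusion"] = {
            DiagnosisLabel(b): {DiagnosisLabel(c): float(p) for c, p in row.items()}
            for b, row in data["confusion"].items()
        }
    return CohortConfig(**kwargs)


def group_params_from_dict(data: dict[str, Any]) -> dict[DiagnosisLabel, GroupParams]:
    """Parse per-group generator settings nested by group label.

    Expected shape per group: ``{"continuous": {var: [mean, sd], ...},
    "binary": {flag: p, ...}}``.
    """
    params = {}
    for key, entry in data.items():
        label = DiagnosisLabel(key)
        continuous = {v: (float(m), float(s)) for v, (m, s) in entry["continuous"].items()}
        binary = {f: float(p) for f, p in entry["binary"].items()}
        params[label] = GroupParams(label=label, continuous=continuous, binary=binary)
    return params


def group_params_to_dict(params: dict[DiagnosisLabel, GroupParams]) -> dict[str, Any]:
    return {
        label.value: {
            "continuous": {v: [m, s] for v, (m, s) in p.continuous.items()},
            "binary": dict(p.binary),
        }
        for label, p in params.items()
    }


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return data


def save_config(data: dict[str, Any], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
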