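"""CSV/YAML input-output with schema validation.

All tables are UTF-8, comma-delimited CSVs with a mandatory header row;
dates are ISO-8601.  Loaders name the offending file and row on parse
errors and warn (but proceed) on unknown extra columns.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
import os
from pathlib import Path
from typing import Any, Type, TypeVar

import pandas as pd
import yaml

from .cohort import (
    ANTI_VEGF_DRUGS,
    DX_CATEGORIES,
    PROC_CATEGORIES,
    Registry,
    RegistrySchemaError,
    _SCHEMAS,
)

logger = logging.getLogger(__name__)

__all__ = [
    "load_registry",
    "load_yaml_config",
    "dataclass_from_mapping",
    "RunManifest",
    "write_manifest",
]

T = TypeVar("T")

_ENUM_COLUMNS = {
    ("injections", "drug"): ANTI_VEGF_DRUGS,
    ("diagnoses", "code_category"): DX_CATEGORIES,
    ("procedures", "category"): PROC_CATEGORIES,
}


def _parse_dates(df: pd.DataFrame, table: str, path: Path) -> pd.DataFrame:
    if "date" not in df.columns:
        return df
    parsed = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & df["date"].notna()
    if bad.any():
        row = int(bad.idxmax())
        raise RegistrySchemaError(
            f"{path.name}: unparseable date {df.loc[row, 'date']!r} at row {row + 2}"
        )
    out = df.copy()
    out["date"] = parsed.dt.date
    return out


def load_registry(directory: str | Path) -> Registry:
    """Load and validate the seven-table registry bundle from a directory."""
    directory = Path(directory)
    frames = {}
    for name, cols in _SCHEMAS.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing registry table: {path}")
        df = pd.read_csv(path)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise RegistrySchemaError(f"{path.name}: missing columns {missing}")
        extra = [c for c in df.columns if c not in cols]
        if extra:
            logger.warning("%s: ignoring unknown columns %s", path.name, extra)
            df = df[cols]
        df = _parse_dates(df, name, path)
        for (table, col), allowed in _ENUM_COLUMNS.items():
            if table == name:
                bad = df[col].dropna().loc[lambda s: ~s.isin(allowed)]
                if len(bad):
                    row = int(bad.index[0])
                    raise RegistrySchemaError(
                        f"{path.name}: unknown {col} {bad.iloc[0]!r} at row {row + 2}"
                    )
        frames[name] = df
    if "laterality" in frames["diagnoses"]:
        frames["diagnoses"]["laterality"] = frames["diagnoses"]["laterality"].astype(
            object
        )
    return Registry(**frames).validate()


def _coerce(value: Any, typ: Any) -> Any:
    if typ is _dt.date or typ == "datetime.date":
        return value if isinstance(value, _dt.date) else _dt.date.fromisoformat(value)
    return value


def dataclass_from_mapping(cls: Type[T], mapping: dict | None) -> T:
    """Build a config dataclass from a YAML mapping, coercing ISO dates."""
    mapping = dict(mapping or {})
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(mapping) - set(fields)
    if unknown:
        raise ValueError(f"{cls.__name__}: unknown config keys {sorted(unknown)}")
    kwargs = {}
    for name, value in mapping.items():
        f = fields[name]
        if f.type in ("_dt.date", "datetime.date") or f.type is _dt.date:
            value = _coerce(value, _dt.date)
        kwargs[name] = value
    return cls(**kwargs)


def load_yaml_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return data or {}


@dataclasses.dataclass
class RunManifest:
    """Provenance record written atomically at the end of a pipeline run."""

    config_hash: str
    package_version: str
    seed: int
    stage_counts: dict
    warnings: list

    @staticmethod
    def hash_config(config: Any) -> str:
        if dataclasses.is_dataclass(config) and not isinstance(config, type):
            config = dataclasses.asdict(config)
        payload = json.dumps(config, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(manifest: RunManifest, path: str | Path) -> None:
    path = Path(path)
    tmp = path.with_suffix(".tmp")
    with open(tmp, "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2, default=str)
    os.replace(tmp, path)
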