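"""CSV readers/writers with schema validation.

Every tabular interface of the pipeline is plain CSV with a documented
header. ``read_table`` validates the header against a named schema, coerces
column types, reports offending row numbers, and rejects duplicate keys
(silent duplicate sensor records would otherwise double-count in every
mean). Each writer's output round-trips through its own reader.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import SchemaError

__all__ = ["Schema", "SCHEMAS", "read_table", "write_table"]


@dataclass(frozen=True)
class Schema:
    """Declared columns (name -> kind) and uniqueness keys of a table."""

    name: str
    columns: Mapping[str, str]  # kind: str | float | int | datetime | date
    keys: Sequence[str] = ()
    optional: Mapping[str, str] = field(default_factory=dict)


SCHEMAS = {
    s.name: s
    for s in [
        Schema(
            "observations",
            {
                "plot_id": "str", "cultivar": "str", "regime": "str",
                "timestamp": "datetime",
                "tc_n": "float", "tc_s": "float", "tc_e": "float", "tc_w": "float",
                "air_temp_c": "float", "rh_pct": "float",
                "days_since_irrigation": "int",
            },
            keys=("plot_id", "timestamp"),
            optional={"year": "str"},
        ),
        Schema(
            "baselines",
            {
                "cultivar": "str", "year": "str",
                "slope_a": "float", "intercept_b": "float", "upper_limit": "float",
                "n_lower_obs": "int", "n_upper_obs": "int", "fit_r2": "float",
            },
            keys=("cultivar", "year"),
        ),
        Schema(
            "weather",
            {"date": "date", "year": "str", "air_temp_c": "float", "rh_pct": "float"},
            keys=("year", "date"),
        ),
        Schema(
            "events",
            {"plot_id": "str", "date": "date", "kind": "str", "mm": "float"},
            optional={"cultivar": "str", "regime": "str", "year": "str"},
        ),
        Schema(
            "soil_profile",
            {
                "plot_id": "str", "layer_top_cm": "float", "layer_bottom_cm": "float",
                "theta_fc": "float", "theta": "float",
            },
            keys=("plot_id", "layer_top_cm"),
        ),
        Schema(
            "leaf_weights",
            {"plot_id": "str", "fw_g": "float", "tw_g": "float", "dw_g": "float"},
            optional={"cultivar": "str", "regime": "str", "year": "str"},
        ),
        Schema(
            "traits",
            {
                "plot_id": "str", "cultivar": "str", "regime": "str", "year": "str",
                "seed_yield_gm2": "float", "water_total_mm": "float",
            },
            keys=("plot_id", "year"),
            optional={
                "seasonal_cwsi": "float", "rwc_pct": "float",
                "color_score": "int", "wue": "float",
            },
        ),
        Schema(
            "cwsi_records",
            {
                "plot_id": "str", "cultivar": "str", "regime": "str", "year": "str",
                "timestamp": "datetime", "vpd_kpa": "float", "tc_minus_ta": "float",
                "lower_limit_at_vpd": "float", "upper_limit": "float",
                "cwsi_raw": "float", "cwsi": "float", "clamped": "str",
            },
            keys=("plot_id", "timestamp"),
        ),
        Schema(
            "summary",
            {"cultivar": "str", "regime": "str", "year": "str", "seasonal_cwsi": "float"},
            optional={"seasonal_cwsi_rounded": "float"},
        ),
        Schema(
            "relations",
            {
                "predictor": "str", "response": "str", "slope": "float",
                "intercept": "float", "r2": "float", "n": "int", "p_value": "float",
            },
            keys=("response",),
        ),
    ]
}

_COERCE = {
    "str": lambda s: s.astype(str),
    "float": lambda s: pd.to_numeric(s, errors="coerce").astype(float),
    "int": lambda s: pd.to_numeric(s, errors="coerce"),
    "datetime": lambda s: pd.to_datetime(s, errors="coerce"),
    "date": lambda s: pd.to_datetime(s, errors="coerce").dt.date,
}


def read_table(path, schema: str | Schema) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Raises SchemaError naming missing columns, unparseable cells (with row
    numbers) and duplicated key rows.
    """
    sch = SCHEMAS[schema] if isinstance(schema, str) else schema
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")  # lossless reread
    missing = [c for c in sch.columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name} ({sch.name}): missing columns {missing}")
    for col, kind in {**sch.columns, **sch.optional}.items():
        if col not in df.columns:
            continue
        raw_na = df[col].isna()
        df[col] = _COERCE[kind](df[col])
        bad = df[col].isna() & ~raw_na
        if kind != "str" and bad.any():
            rows = (df.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
            raise SchemaError(
                f"{path.name} ({sch.name}): unparseable {kind} in column "
                f"{col!r} at file lines {rows}"
            )
        if kind == "int":
            if df[col].isna().any():
                rows = (df.index[df[col].isna()] + 2).tolist()[:5]
                raise SchemaError(
                    f"{path.name} ({sch.name}): missing {col!r} at lines {rows}"
                )
            df[col] = df[col].astype(int)
    if sch.keys:
        dup = df.duplicated(subset=list(sch.keys))
        if dup.any():
            rows = (df.index[dup] + 2).tolist()[:5]
            raise SchemaError(
                f"{path.name} ({sch.name}): duplicate {tuple(sch.keys)} at lines {rows}"
            )
    return df


def write_table(df: pd.DataFrame, path, schema: str | Schema | None = None) -> Path:
    """Write a CSV; if a schema is given, check its columns are present."""
    if schema is not None:
        sch = SCHEMAS[schema] if isinstance(schema, str) else schema
        missing = [c for c in sch.columns if c not in df.columns]
        if missing:
            raise SchemaError(f"cannot write {sch.name}: missing columns {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
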