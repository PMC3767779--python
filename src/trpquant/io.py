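"""Tab-separated table input/output with explicit schemas.

All interchange tables are TSV with a header row and the literal token
``NA`` for missing values.  Schemas map column names to target dtypes;
reading validates the header and reports malformed numeric cells with
their (1-based, header-exclusive) row number.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

NA_TOKEN = "NA"

#: metadata columns of a feature table; every other column is a run.
FEATURE_META_COLUMNS = [
    "feature_id",
    "peptide_sequence",
    "site_id",
    "n_phospho",
    "site_localized",
    "charge",
    "mz",
    "rt",
]

DESIGN_SCHEMA = {
    "run_id": str,
    "genotype": str,
    "condition": str,
    "bio_replicate": int,
    "tech_replicate": int,
    "enzyme": str,
    "scale_factor": float,
}

BLOT_SCHEMA = {
    "lane_id": str,
    "membrane_id": str,
    "genotype": str,
    "condition": str,
    "timepoint": float,
    "heads_loaded": float,
    "phospho_signal": float,
    "total_signal": float,
}

IP_SCHEMA = {
    "site_id": str,
    "replicate": int,
    "p_input": float,
    "t_input": float,
    "p_ip": float,
    "t_ip": float,
}

SCREEN_RECORD_SCHEMA = {
    "mutant_id": str,
    "site_id": str,
    "condition": str,
    "stage": str,
    "replicate": int,
    "relative_phospho_pct": float,
}


class TableSchemaError(ValueError):
    """Raised when a table does not match its declared schema."""


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write ``table`` as TSV with ``NA`` for missing values.

    Floats are rendered with %.12g so that write→read round trips are
    exact for values produced by the pipeline.
    """
    table.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN, float_format="%.12g")


def read_table(path: str | Path, schema: dict[str, type] | None = None) -> pd.DataFrame:
    """Read a TSV table, optionally validating and typing it against ``schema``.

    Columns present in the file but absent from the schema are kept as-is
    (feature tables carry one column per run, which cannot be enumerated
    statically); columns required by the schema but missing raise
    :class:`TableSchemaError` listing them.
    """
    path = Path(path)
    raw = pd.read_csv(
        path, sep="\t", dtype=str, na_values=[NA_TOKEN], keep_default_na=False
    )
    if schema is None:
        return _coerce_all_numeric(raw)
    missing = [c for c in schema if c not in raw.columns]
    if missing:
        raise TableSchemaError(
            f"{path.name}: missing required columns {missing}; "
            f"found {list(raw.columns)}"
        )
    out = {}
    for col in raw.columns:
        if col not in schema:  # extra columns: best-effort typing
            numeric = pd.to_numeric(raw[col], errors="coerce")
            out[col] = raw[col] if (raw[col].notna() & numeric.isna()).any() else numeric
            continue
        target = schema[col]
        if target is str:
            out[col] = raw[col]
        elif target in (int, float, bool):
            out[col] = _coerce_column(raw[col], col, target, path.name)
        else:  # pragma: no cover - defensive
            raise TableSchemaError(f"unsupported schema dtype {target!r} for {col}")
    return pd.DataFrame(out)


def _coerce_column(series: pd.Series, name: str, target: type, fname: str) -> pd.Series:
    if target is bool:
        mapped = series.str.lower().map({"true": True, "false": False, "1": True, "0": False})
        bad = series.notna() & mapped.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise TableSchemaError(
                f"{fname}: column {name!r} row {row}: cannot parse "
                f"{series[bad].iloc[0]!r} as boolean"
            )
        return mapped.astype("boolean").astype(bool) if not mapped.isna().any() else mapped
    numeric = pd.to_numeric(series, errors="coerce")
    bad = series.notna() & numeric.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise TableSchemaError(
            f"{fname}: column {name!r} row {row}: cannot parse "
            f"{series[bad].iloc[0]!r} as a number"
        )
    if target is int and not numeric.isna().any():
        return numeric.astype(int)
    return numeric.astype(float)


def _coerce_all_numeric(raw: pd.DataFrame) -> pd.DataFrame:
    """Best-effort typing when no schema is given: numeric where possible."""
    out = {}
    for col in raw.columns:
        numeric = pd.to_numeric(raw[col], errors="coerce")
        mixed = raw[col].notna() & numeric.isna()
        out[col] = raw[col] if mixed.any() else numeric
        if col == "site_localized":
            out[col] = raw[col].str.lower().isin(["true", "1"])
    return pd.DataFrame(out)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table: fixed metadata columns plus one column per run."""
    table = read_table(path)
    missing = [c for c in FEATURE_META_COLUMNS if c not in table.columns]
    if missing:
        raise TableSchemaError(f"feature table missing columns {missing}")
    for col in ("n_phospho", "charge"):
        table[col] = table[col].astype(int)
    table["site_localized"] = table["site_localized"].astype(bool)
    return table


def run_columns(table: pd.DataFrame) -> list[str]:
    """Names of the per-run abundance columns of a feature table."""
    return [c for c in table.columns if c not in FEATURE_META_COLUMNS]


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
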