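"""Tabular and config I/O: province CSVs, constants overrides, manifests.

Province tables are plain UTF-8 CSV with '.' decimal separators, one row
per province, columns named exactly as the :class:`ProvinceInputs`
fields.  Output CSVs are written with 12 significant digits so a
write/read round trip preserves every number at that precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .core_model import ModelConstants, ProvinceInputs, ValidationError

__all__ = [
    "PROVINCE_COLUMNS",
    "read_provinces",
    "write_table",
    "load_constants",
    "write_manifest",
]

PROVINCE_COLUMNS = (
    "province_id", "region", "area_urban", "green_frac", "d_green",
    "d_sgreen", "d_simp", "sd_simp", "pop_urban", "floor_resid",
    "floor_total", "n_set", "n_household",
)

_NUMERIC_COLUMNS = PROVINCE_COLUMNS[2:]

FLOAT_FORMAT = "%.12g"


def read_provinces(path) -> pd.DataFrame:
    """Read and validate a province-inputs CSV.

    Raises :class:`ValidationError` listing the expected schema when
    columns are missing, naming the row and column for non-numeric cells,
    and propagating per-row invariant violations.
    """
    df = pd.read_csv(path, encoding="utf-8")
    missing = [col for col in PROVINCE_COLUMNS if col not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing column(s) {missing}; expected schema: {list(PROVINCE_COLUMNS)}"
        )
    if len(df) == 0:
        raise ValidationError(f"{path}: province table is empty")
    for col in _NUMERIC_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad) or coerced.isna().any():
            row = int((df.index[coerced.isna()])[0])
            raise ValidationError(
                f"{path}: non-numeric or missing value in column {col!r}, row {row} "
                f"(value {df.loc[row, col]!r})"
            )
        df[col] = coerced
    for i, row in df.iterrows():
        try:
            ProvinceInputs.from_row(row)
        except ValidationError as e:
            raise ValidationError(f"{path}, row {i}: {e}") from e
    return df[list(PROVINCE_COLUMNS)]


def write_table(df: pd.DataFrame, path) -> None:
    """Write a results table as UTF-8 CSV at 12 significant digits."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, encoding="utf-8")


def load_constants(path=None) -> ModelConstants:
    """Model constants with optional YAML/JSON overrides.

    Unspecified fields keep their defaults; unknown fields raise.
    """
    if path is None:
        return ModelConstants()
    text = Path(path).read_text(encoding="utf-8")
    overrides = yaml.safe_load(text) or {}   # YAML is a JSON superset
    if not isinstance(overrides, dict):
        raise ValidationError(f"{path}: constants file must map field -> value")
    return ModelConstants().with_overrides(
        {k: float(v) for k, v in overrides.items()}
    )


def write_manifest(path, *, seed=None, n_sims=None, constants: ModelConstants | None = None,
                   extra: dict | None = None) -> None:
    """Record the effective run configuration for provenance."""
    from dataclasses import asdict

    from . import __version__

    manifest = {"urbancarbon_version": __version__}
    if seed is not None:
        manifest["seed"] = seed
    if n_sims is not None:
        manifest["n_sims"] = n_sims
    if constants is not None:
        manifest["constants"] = asdict(constants)
    if extra:
        manifest.update(extra)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")
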