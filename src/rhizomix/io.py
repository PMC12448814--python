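"""Reading and writing the pipeline's tabular interchange files.

Everything is headered, comma-delimited, UTF-8 text with "." decimals and
empty cells as NA.  External data (e.g. a published deposit with its own
column names) is adapted through a column-mapping config: a YAML/JSON
document with one block per table mapping internal names to the file's
names, e.g. ``plants: {genotype_id: variety_name, total_biomass: TDW_mg}``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = {
    "design": ["tube_id", "treatment", "block", "harvest_date", "is_control",
               "is_mixture", "pos1", "pos2", "pos3", "pos4", "pos5", "pos6"],
    "plants": ["tube_id", "position", "genotype_id", "shoot_biomass",
               "root_biomass", "total_biomass", "n_leaves", "n_tillers", "leaf_n"],
    "tubes": ["tube_id", "root_length", "root_area"],
}
NUMERIC_COLUMNS = {
    "plants": ["shoot_biomass", "root_biomass", "total_biomass", "leaf_n"],
    "tubes": ["root_length", "root_area"],
    "design": [],
}


def load_column_map(path) -> dict:
    """Column-mapping config: {table: {internal_name: external_name}}."""
    path = Path(path)
    text = path.read_text()
    mapping = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(mapping, dict):
        raise ValueError(f"column map in {path} is not a mapping")
    return mapping


def read_table(path, kind: str, column_map: dict | None = None) -> pd.DataFrame:
    """Read and validate one of the interchange tables.

    ``column_map`` maps internal column names to the file's names for this
    table kind.  Unknown extra columns are kept but logged; missing required
    columns raise with the offending names; non-numeric values in numeric
    columns raise with the row numbers.
    """
    if kind not in REQUIRED_COLUMNS:
        raise ValueError(f"unknown table kind '{kind}'")
    df = pd.read_csv(path)
    if column_map:
        rename = {ext: internal for internal, ext in column_map.items()
                  if ext in df.columns}
        df = df.rename(columns=rename)
    required = REQUIRED_COLUMNS[kind]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing} for table '{kind}'"
        )
    extra = [c for c in df.columns if c not in required]
    if extra:
        log.warning("%s: ignoring unrecognized column(s) %s", path, extra)
    for c in NUMERIC_COLUMNS[kind]:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[coerced.isna() & df[c].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric values in column '{c}' at rows "
                f"{list(bad[:10])}"
            )
        df[c] = coerced
    if kind == "design":
        for c in ("is_control", "is_mixture"):
            df[c] = df[c].astype(bool)
    return df[required + extra]


def read_tables(paths: dict, column_map: dict | None = None) -> dict:
    """Read design/plants/tubes tables, applying a per-table column map."""
    column_map = column_map or {}
    return {
        kind: read_table(p, kind, column_map.get(kind))
        for kind, p in paths.items()
    }


def write_csv(df: pd.DataFrame, path, float_format: str = "%.10g") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=float_format)
    return path
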