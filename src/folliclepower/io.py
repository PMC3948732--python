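"""Observation-table and configuration I/O.

The interchange format is a plain CSV with one row per analyzed section.
Geometric-mode tables carry the columns

    ewe_id, ovary_id, fragment_id, section_index, group, area_mm2,
    n_primordial, n_primary, n_secondary

and direct-mode tables replace the area/count columns with a single ``y``
(log10-transformed density).  Unknown extra columns are preserved on a
round trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .errors import FormatError

__all__ = [
    "KEY_COLUMNS",
    "COUNT_COLUMNS",
    "read_observation_table",
    "write_observation_table",
    "load_config",
    "dump_config",
]

KEY_COLUMNS = ["ewe_id", "ovary_id", "fragment_id", "section_index", "group"]
COUNT_COLUMNS = ["n_primordial", "n_primary", "n_secondary"]


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in KEY_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"observation table missing required column(s): {missing}")
    has_counts = all(c in table.columns for c in COUNT_COLUMNS)
    if not has_counts and "y" not in table.columns:
        raise FormatError(
            "observation table needs either count columns "
            f"{COUNT_COLUMNS} with area_mm2, or a 'y' column"
        )
    if has_counts:
        if "area_mm2" not in table.columns:
            raise FormatError("observation table missing required column(s): ['area_mm2']")
        for col in COUNT_COLUMNS:
            bad = table.index[table[col] < 0]
            if len(bad):
                raise FormatError(f"negative count in column {col} at row {bad[0]}")
        bad = table.index[table["area_mm2"] <= 0]
        if len(bad):
            raise FormatError(f"non-positive area_mm2 at row {bad[0]}")
        table = table.astype({c: int for c in COUNT_COLUMNS})
    table = table.astype({"section_index": int})
    bad = table.index[table["section_index"] < 0]
    if len(bad):
        raise FormatError(f"negative section_index at row {bad[0]}")
    return table


def read_observation_table(path: str | Path) -> pd.DataFrame:
    """Read and validate an observation CSV.

    An empty (header-only) file returns an empty table.  Missing required
    columns, negative counts or non-positive areas raise
    :class:`~folliclepower.errors.FormatError` naming the offender.
    """
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file without header") from exc
    if table.empty and len(table.columns):
        missing = [c for c in KEY_COLUMNS if c not in table.columns]
        if missing:
            raise FormatError(f"observation table missing required column(s): {missing}")
        return table
    return _validate(table)


def write_observation_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Validate and write an observation table as CSV (lossless round trip)."""
    path = Path(path)
    _validate(table.copy())
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: configuration must be a mapping")
    return data


def dump_config(config: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=True))
    return path
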