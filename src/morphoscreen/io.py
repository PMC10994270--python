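"""Feature-table CSV round-trip with schema checking.

Schema: metadata columns first, in fixed order (plate_id, well,
subclone_id, genotype, treatment, concentration_nM, field), then named
numeric feature columns.  Unknown extra columns are preserved and passed
through.  Well-level tables omit the ``field`` column.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .design import METADATA_COLUMNS


class SchemaError(ValueError):
    """A feature table is missing required metadata columns."""


def metadata_columns(table: pd.DataFrame) -> list[str]:
    """The schema metadata columns present in this table, in schema order."""
    return [c for c in METADATA_COLUMNS if c in table.columns]


def feature_columns(table: pd.DataFrame) -> list[str]:
    """All non-metadata columns, in table order."""
    meta = set(METADATA_COLUMNS)
    return [c for c in table.columns if c not in meta]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table to CSV at full float precision."""
    table.to_csv(path, index=False, float_format=None)


def read_feature_table(path: str | Path, well_level: bool | None = None) -> pd.DataFrame:
    """Read a feature-table CSV, enforcing the metadata schema.

    Parameters
    ----------
    well_level
        If True, the ``field`` column is not required; if False it is;
        if None (default), its presence decides the table's level.

    Raises
    ------
    SchemaError
        Naming the metadata columns that are absent.
    """
    table = pd.read_csv(path)
    required = [c for c in METADATA_COLUMNS if c != "field"]
    if well_level is False:
        required = list(METADATA_COLUMNS)
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table {path} missing metadata columns: {missing}")
    return table
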