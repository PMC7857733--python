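"""CSV readers/writers for data matrices, loading tables, and result tables.

The loading-table layout is fixed package-wide: first column literally
``Variables``, followed by contiguous ``PC1``..``PCk`` columns.  Data
matrices are plain CSVs with a header of variable names and an optional
leading subject-id column.  All writers can prepend a comment header
carrying the tool version and a hash of the resolved parameters, and all
readers skip ``#`` comment lines, so result files are self-describing
and round-trip clean.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .pca import DataMatrix, LoadingsTable

__all__ = [
    "read_data_matrix",
    "write_data_matrix",
    "read_loadings_table",
    "write_loadings_table",
    "write_table",
    "params_hash",
]


def params_hash(params: dict) -> str:
    """Short stable hash of a parameter dict (order-insensitive)."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def _header_line(params: dict | None) -> str:
    tag = f"# syndromics v{__version__}"
    if params is not None:
        tag += f" params={params_hash(params)}"
    return tag + "\n"


def write_table(
    frame: pd.DataFrame,
    path: str | Path,
    params: dict | None = None,
    digits: int | None = None,
) -> None:
    """Write a result table with the version/parameter comment header.

    ``digits`` limits floats to that many significant digits (the CLI
    default is 6); ``None`` writes full precision (17 significant digits,
    round-trip exact for doubles).
    """
    float_format = f"%.{digits}g" if digits is not None else "%.17g"
    with open(path, "w") as fh:
        fh.write(_header_line(params))
        frame.to_csv(fh, index=False, float_format=float_format)


def read_data_matrix(path: str | Path, id_column: str | None = "auto") -> DataMatrix:
    """Read a subjects x variables CSV (header row = variable names).

    ``id_column='auto'`` treats a non-numeric first column as subject
    ids; pass a column name to force it, or ``None`` for no id column.
    """
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    if frame.shape[1] == 0:
        raise ValueError(f"{path}: empty table")
    if id_column == "auto":
        first = frame.columns[0]
        named_like_id = first.lower() in ("subject", "subjects", "id", "subject_id")
        if named_like_id or not pd.api.types.is_numeric_dtype(frame[first]):
            id_column = first
        else:
            id_column = None
    return DataMatrix.from_frame(frame, id_column=id_column)


def write_data_matrix(
    data: DataMatrix,
    path: str | Path,
    id_column: str | None = "subject",
    params: dict | None = None,
    digits: int | None = None,
) -> None:
    write_table(data.to_frame(id_column=id_column), path, params=params, digits=digits)


def read_loadings_table(path: str | Path) -> LoadingsTable:
    """Read a loadings CSV in the package layout.

    Raises a specific error for a wrong first-column name, non-contiguous
    PC labels, duplicate variable names, or absent component columns.
    """
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    try:
        return LoadingsTable.from_frame(frame)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_loadings_table(
    table: LoadingsTable,
    path: str | Path,
    params: dict | None = None,
    digits: int | None = None,
) -> None:
    write_table(table.to_frame(), path, params=params, digits=digits)
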