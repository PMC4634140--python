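"""Reading, validating and writing plate-level colony-count tables.

The canonical on-disk format is a tab-separated table with a header row and
one row per cell-culture plate.  Default column names follow common usage in
clonogenic-assay data sets::

    exp        replicate experiment identifier (categorical)
    dose       radiation dose in Gy (optional; curve data only)
    ncells     number of cells seeded on the plate (positive integer)
    ncolonies  number of colonies scored (non-negative integer)

plus optional grouping columns (e.g. a cell-line column) and optional binary
treatment factors for two-way designs.  Any file column can be remapped to a
canonical field through ``column_map``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AssayTable",
    "AssayValidationError",
    "read_assay_table",
    "write_assay_table",
    "survival_fractions",
]

#: canonical field -> default file column header
DEFAULT_COLUMNS = {
    "experiment_id": "exp",
    "dose": "dose",
    "cells_seeded": "ncells",
    "colonies": "ncolonies",
    # optional fields are read only when their column exists in the file
    "group": "group",
    "factor_a": "factor_a",
    "factor_b": "factor_b",
}

REQUIRED_FIELDS = ("experiment_id", "cells_seeded", "colonies")
OPTIONAL_FIELDS = ("dose", "group", "factor_a", "factor_b")


class AssayValidationError(ValueError):
    """Raised when a table violates the plate-record invariants."""


def _check_injective(column_map: dict[str, str]) -> None:
    seen: dict[str, str] = {}
    for canon, col in column_map.items():
        if col in seen:
            raise AssayValidationError(
                f"column map is not injective: fields {seen[col]!r} and "
                f"{canon!r} both resolve to file column {col!r}"
            )
        seen[col] = canon


@dataclass
class AssayTable:
    """Plate-level colony-count records in canonical long format.

    ``data`` holds one row per plate with canonical column names
    (``experiment_id``, ``cells_seeded``, ``colonies`` and any of ``dose``,
    ``group``, ``factor_a``, ``factor_b``).  ``column_map`` remembers the
    mapping to the file headers so the table round-trips.
    """

    data: pd.DataFrame
    column_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COLUMNS))

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        if len(df) == 0:
            raise AssayValidationError("no records")
        for f in REQUIRED_FIELDS:
            if f not in df.columns:
                raise AssayValidationError(f"missing required column for field {f!r}")
        _check_injective(self.column_map)

        def _bad_rows(mask: pd.Series, what: str) -> None:
            if mask.any():
                rows = list(np.flatnonzero(mask.to_numpy())[:5] + 1)
                raise AssayValidationError(f"{what} (data row(s) {rows})")

        cells = df["cells_seeded"]
        cols = df["colonies"]
        _bad_rows(cells != np.floor(cells), "non-integer cells_seeded")
        _bad_rows(cols != np.floor(cols), "non-integer colonies")
        _bad_rows(cells < 1, "cells_seeded must be >= 1")
        _bad_rows(cols < 0, "colonies must be >= 0")
        if "dose" in df.columns:
            d = df["dose"].astype(float)
            _bad_rows(~np.isfinite(d), "dose must be finite")
            _bad_rows(d < 0, "negative dose")
        for f in ("factor_a", "factor_b"):
            if f in df.columns:
                _bad_rows(~df[f].isin([0, 1]), f"{f} must be 0 or 1")
        if df["experiment_id"].nunique() < 2:
            warnings.warn(
                "fewer than 2 experiments: between-replicate dispersion is "
                "not meaningful",
                stacklevel=3,
            )

    # -- conveniences -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def experiments(self) -> list:
        return list(pd.unique(self.data["experiment_id"]))

    def subset(self, mask) -> "AssayTable":
        return AssayTable(self.data.loc[mask].reset_index(drop=True), dict(self.column_map))


def read_assay_table(path, column_map: dict[str, str] | None = None) -> AssayTable:
    """Read a tab-separated plate table into an :class:`AssayTable`.

    Parameters
    ----------
    path
        TSV file with a header row.
    column_map
        Mapping from canonical field names (``experiment_id``, ``dose``,
        ``cells_seeded``, ``colonies``, ``group``, ``factor_a``,
        ``factor_b``) to the file's column headers.  Unmapped canonical
        fields fall back to the defaults; optional fields are picked up
        only when their column exists.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(REQUIRED_FIELDS) - set(OPTIONAL_FIELDS)
        if unknown:
            raise AssayValidationError(f"unknown canonical fields in column map: {sorted(unknown)}")
        cmap.update(column_map)
    _check_injective(cmap)

    raw = pd.read_csv(path, sep="\t", header=0)
    if len(raw) == 0:
        raise AssayValidationError("no records")

    for f in REQUIRED_FIELDS:
        if cmap[f] not in raw.columns:
            raise AssayValidationError(
                f"missing required column {cmap[f]!r} (field {f!r}); "
                f"available columns: {list(raw.columns)}"
            )

    out = pd.DataFrame()
    used_map: dict[str, str] = {}
    for f in REQUIRED_FIELDS + OPTIONAL_FIELDS:
        col = cmap.get(f)
        if col is not None and col in raw.columns:
            out[f] = raw[col]
            used_map[f] = col
    out["experiment_id"] = out["experiment_id"].astype(str)
    if "group" in out.columns:
        out["group"] = out["group"].astype(str)
    for f in ("factor_a", "factor_b"):
        if f in out.columns:
            out[f] = _coerce_binary(out[f], f)
    for f in ("cells_seeded", "colonies"):
        vals = pd.to_numeric(out[f], errors="coerce")
        if vals.isna().any() or (vals != np.floor(vals)).any():
            row = int(np.flatnonzero((vals.isna() | (vals != np.floor(vals))).to_numpy())[0]) + 1
            raise AssayValidationError(f"non-integer {f} at data row {row}")
        out[f] = vals.astype(int)
    if "dose" in out.columns:
        out["dose"] = pd.to_numeric(out["dose"], errors="raise").astype(float)
    return AssayTable(out, used_map or dict(DEFAULT_COLUMNS))


def _coerce_binary(series: pd.Series, name: str) -> pd.Series:
    """Coerce a two-level factor to {0, 1}; first level sorted = 0."""
    vals = series.astype(str).str.strip()
    levels = sorted(vals.unique())
    if set(levels) <= {"0", "1"}:
        return vals.astype(int)
    if len(levels) != 2:
        raise AssayValidationError(
            f"factor {name!r} must be binary; found levels {levels}"
        )
    return vals.map({levels[0]: 0, levels[1]: 1}).astype(int)


def write_assay_table(table: AssayTable, path) -> None:
    """Write the table back to TSV using its original column headers."""
    df = table.data.rename(columns=table.column_map)
    df.to_csv(path, sep="\t", index=False)


def survival_fractions(table: AssayTable) -> pd.DataFrame:
    """Attach the observed per-plate survival fraction S = colonies / cells.

    Zero colonies are allowed (S = 0).  Returns a copy of the table's data
    with an ``S`` column appended.
    """
    df = table.data.copy()
    df["S"] = df["colonies"] / df["cells_seeded"]
    return df
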