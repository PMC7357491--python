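"""Data model and primitive transforms for phenotype assay measurements.

The canonical in-memory container is :class:`AssayTable`, a thin validated
wrapper around a long-format :class:`pandas.DataFrame`.  One row is one
measurement of one experimental unit (plate, tube, or well) at one time.
Clearance/spreading halos are stored as two perpendicular half-diameters
``r1_cm``/``r2_cm`` and quantified as a rectangle area ``A = r1 * r2``;
all other assays store a single ``value`` with a ``value_kind`` tag.

Two interchange layouts are supported:

``long_csv``
    one row per measurement, columns
    ``strain,assay,condition,unit,replicate,time_h,value,value_kind``
    (halo tables replace ``value``/``value_kind`` with ``r1_cm,r2_cm``,
    or ``d1_cm,d2_cm`` for full diameters, which are halved on read);

``plate_csv``
    an 8x12 optical-density grid per read time (96-well plate) plus a
    separate layout CSV mapping well coordinates to carbon-source names.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, IntegrityError, ParseError, SchemaError

SCHEMA_VERSION = "1.0"

#: identifying key of a measurement row
KEY_COLUMNS = ["strain", "assay", "condition", "unit", "replicate", "time_h"]

VALUE_COLUMNS = ["value", "value_kind"]
HALO_COLUMNS = ["r1_cm", "r2_cm"]
DIAMETER_COLUMNS = ["d1_cm", "d2_cm"]

VALUE_KINDS = {
    "diameter_cm",
    "area_cm2",
    "absorbance",
    "od",
    "concentration_mg_per_L",
    "pH",
    "cfu_per_ml",
}

#: value kinds bounded to the photometer range
_BOUNDED_04 = {"absorbance", "od"}

PLATE_ROWS = list(string.ascii_uppercase[:8])  # A..H
PLATE_COLS = [str(i) for i in range(1, 13)]


@dataclass
class AssayTable:
    """Validated long-format table of assay measurements.

    Parameters
    ----------
    df
        Long-format frame.  Must contain :data:`KEY_COLUMNS` plus either
        ``value``/``value_kind`` or ``r1_cm``/``r2_cm`` (halo layout).
        Extra columns (e.g. a ``truncated`` flag from the simulator) are
        preserved verbatim.
    strain_set
        Optional declared strain universe; rows with other strains are an
        integrity error.
    """

    df: pd.DataFrame
    schema_version: str = SCHEMA_VERSION
    strain_set: tuple[str, ...] | None = None

    def __post_init__(self):
        self.df = validate_assay_frame(self.df, strain_set=self.strain_set)

    # -- convenience -------------------------------------------------
    @property
    def is_halo(self) -> bool:
        return "r1_cm" in self.df.columns

    @property
    def strains(self) -> list[str]:
        return sorted(self.df["strain"].unique())

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, **filters) -> "AssayTable":
        """Rows matching column == value for every keyword filter."""
        mask = pd.Series(True, index=self.df.index)
        for col, val in filters.items():
            mask &= self.df[col] == val
        return AssayTable(self.df.loc[mask].reset_index(drop=True),
                          schema_version=self.schema_version)


def validate_assay_frame(df: pd.DataFrame,
                         strain_set: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Validate a long-format frame and return it (row order preserved)."""
    if not isinstance(df, pd.DataFrame):
        raise SchemaError("assay table must be a pandas DataFrame")
    missing = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    halo = all(c in df.columns for c in HALO_COLUMNS)
    if not halo:
        missing = [c for c in VALUE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(
                "missing required column(s): " + ", ".join(missing)
                + " (or r1_cm/r2_cm for halo tables)")

    df = df.copy()
    for col in ("time_h",) + (("r1_cm", "r2_cm") if halo else ("value",)):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce")
            rows = df.index[bad.isna() & df[col].notna()].tolist()
            raise ParseError(f"non-numeric value in column {col!r}, row(s) {rows}") from exc
    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)

    if (df["replicate"] < 1).any():
        raise IntegrityError("replicate must be a positive integer")
    if (df["time_h"] < 0).any():
        raise DomainError("time_h must be >= 0")

    if halo:
        if (df[["r1_cm", "r2_cm"]] < 0).any().any():
            raise DomainError("halo half-diameters must be >= 0")
        key_cols = KEY_COLUMNS
    else:
        unknown = set(df["value_kind"].unique()) - VALUE_KINDS
        if unknown:
            raise SchemaError(f"unknown value_kind(s): {sorted(unknown)}")
        nonneg = df["value_kind"] != "pH"
        if (df.loc[nonneg, "value"] < 0).any():
            raise DomainError("value must be >= 0 for all value kinds except pH")
        bounded = df["value_kind"].isin(_BOUNDED_04)
        if (df.loc[bounded, "value"] > 4).any():
            raise DomainError("absorbance/od readings must lie in [0, 4]")
        key_cols = KEY_COLUMNS + ["value_kind"]

    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        offending = df.loc[dup, key_cols].drop_duplicates().to_dict("records")
        raise IntegrityError(f"duplicate measurement key(s): {offending[:5]}")

    if strain_set is not None:
        alien = set(df["strain"].unique()) - set(strain_set)
        if alien:
            raise IntegrityError(f"strain(s) not in declared strain set: {sorted(alien)}")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# primitive transforms
# ---------------------------------------------------------------------------

def halo_area(r1_cm, r2_cm):
    """Rectangle-model halo area ``A = r1 * r2`` in cm².

    The two inputs are perpendicular half-diameters of the clearance (or
    spreading) halo; the area is bilinear and symmetric in them.  Accepts
    scalars or arrays.
    """
    r1 = np.asarray(r1_cm, dtype=float)
    r2 = np.asarray(r2_cm, dtype=float)
    if (r1 < 0).any() or (r2 < 0).any():
        raise DomainError("halo half-diameters must be >= 0")
    out = r1 * r2
    return float(out) if out.ndim == 0 else out


def log1p_transform(values):
    """Elementwise natural ``log(x + 1)``, the variance-stabilising
    transform applied to every halo-type response before model fitting.

    Values in ``(-1, 0)`` are tolerated with a warning (they can arise
    from blank subtraction); values ``<= -1`` are a domain error.
    """
    x = np.asarray(values, dtype=float)
    if (x <= -1).any():
        raise DomainError("log1p_transform requires values > -1")
    if (x < 0).any():
        warnings.warn("log1p_transform received negative values in (-1, 0)",
                      stacklevel=2)
    out = np.log1p(x)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_assay_table(path, layout: str = "long_csv", *,
                     layout_map=None, assay: str = "ecoplate",
                     value_kind: str = "od",
                     strain_set: tuple[str, ...] | None = None) -> AssayTable:
    """Read an assay table from disk.

    Parameters
    ----------
    path
        CSV file.  UTF-8, '.' decimal separator (no locale inference).
    layout
        ``"long_csv"`` (canonical) or ``"plate_csv"`` (96-well OD grids).
    layout_map
        Required for ``plate_csv``: path to a CSV with columns
        ``well,substrate`` mapping well coordinates (e.g. ``B3``) to carbon
        sources.  Well ``A1`` and any well mapped to ``water`` are blanks
        and are excluded; unmapped wells are ignored.
    assay, value_kind
        Metadata stamped on plate_csv rows (grids carry none).
    """
    if layout == "long_csv":
        df = pd.read_csv(path)
        if all(c in df.columns for c in DIAMETER_COLUMNS):
            # full diameters: halve to the r1/r2 half-diameter convention
            df["r1_cm"] = pd.to_numeric(df["d1_cm"], errors="coerce") / 2.0
            df["r2_cm"] = pd.to_numeric(df["d2_cm"], errors="coerce") / 2.0
            df = df.drop(columns=DIAMETER_COLUMNS)
        return AssayTable(df, strain_set=strain_set)
    if layout == "plate_csv":
        if layout_map is None:
            raise SchemaError("plate_csv layout requires a layout_map CSV")
        return _read_plate_csv(path, layout_map, assay=assay,
                               value_kind=value_kind, strain_set=strain_set)
    raise SchemaError(f"unknown layout {layout!r}")


def _read_plate_csv(path, layout_map, *, assay, value_kind, strain_set):
    layout = pd.read_csv(layout_map)
    for col in ("well", "substrate"):
        if col not in layout.columns:
            raise SchemaError(f"layout map is missing required column: {col}")
    has_rep = "replicate" in layout.columns
    well_map = {}
    for _, row in layout.iterrows():
        well = str(row["well"]).strip().upper()
        if well == "A1" or str(row["substrate"]).strip().lower() == "water":
            continue  # water blank
        well_map[well] = (str(row["substrate"]),
                          int(row["replicate"]) if has_rep else 1)

    grid = pd.read_csv(path)
    meta_cols = ["strain", "unit", "time_h", "row"]
    missing = [c for c in meta_cols if c not in grid.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    col_names = [c for c in PLATE_COLS if c in grid.columns]
    if not col_names:
        raise SchemaError("plate grid has no well columns named 1..12")

    records = []
    for _, row in grid.iterrows():
        letter = str(row["row"]).strip().upper()
        if letter not in PLATE_ROWS:
            raise ParseError(f"unknown plate row label {row['row']!r}")
        for col in col_names:
            cell = row[col]
            if pd.isna(cell):
                continue
            well = f"{letter}{col}"
            if well not in well_map:
                continue
            substrate, rep = well_map[well]
            try:
                od = float(cell)
            except (TypeError, ValueError) as exc:
                raise ParseError(f"non-numeric OD in well {well} "
                                 f"at time {row['time_h']}") from exc
            records.append({
                "strain": row["strain"], "assay": assay,
                "condition": substrate, "unit": row["unit"],
                "replicate": rep, "time_h": float(row["time_h"]),
                "value": od, "value_kind": value_kind,
            })
    return AssayTable(pd.DataFrame.from_records(records), strain_set=strain_set)


def write_assay_table(table: AssayTable, path) -> None:
    """Write a table as canonical long CSV (round-trips with the reader)."""
    table.df.to_csv(path, index=False)
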