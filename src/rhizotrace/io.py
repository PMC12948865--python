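"""CSV readers/writers and schema validation for the pipeline tables.

All data travel as tidy RFC-4180 CSV (UTF-8, ``.`` decimal).  Three input
tables are defined:

``measurements`` — one row per plot x compartment x layer x position::

    plot_id, system, regime, compartment, layer, position,
    delta13C_permil, c_concentration, mass_basis, mass_value

  ``compartment`` is one of grain, straw, crown_root, coarse_root, fine_root,
  soil.  ``mass_basis`` is ``area`` (mass_value in g dry matter m-2) or
  ``soil`` (mass_value in g dry matter per kg dry soil, scaled to area with
  the layer geometry).  ``c_concentration`` is g C per g dry matter.
  Aboveground compartments use layer ``aboveground``.

``references`` — natural-abundance delta-13C per treatment x layer::

    system, regime, layer, material, delta13C_permil

  ``material`` is ``plant`` or ``soil``; labelled measurements are paired
  with the reference of their own treatment, layer and material.

``geometry`` — per soil layer::

    layer, thickness_m, bulk_density_kg_m3
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import SchemaError

__all__ = [
    "MEASUREMENT_COLUMNS",
    "REFERENCE_COLUMNS",
    "GEOMETRY_COLUMNS",
    "COMPARTMENTS",
    "read_measurements",
    "read_references",
    "read_geometry",
]

MEASUREMENT_COLUMNS = (
    "plot_id", "system", "regime", "compartment", "layer", "position",
    "delta13C_permil", "c_concentration", "mass_basis", "mass_value",
)
REFERENCE_COLUMNS = ("system", "regime", "layer", "material", "delta13C_permil")
GEOMETRY_COLUMNS = ("layer", "thickness_m", "bulk_density_kg_m3")

COMPARTMENTS = ("grain", "straw", "crown_root", "coarse_root", "fine_root", "soil")
MASS_BASES = ("area", "soil")


def _require_columns(df: pd.DataFrame, columns: Iterable[str], table: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing column(s): {', '.join(missing)}")


def _rows(mask: pd.Series) -> str:
    """1-based data-row numbers (header excluded) for an error message."""
    return ", ".join(str(i + 1) for i in mask[mask].index[:10])


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read and validate the labelled measurement table.

    Checks column presence, value domains (delta > −1000 permil, carbon
    concentration in (0, 0.6) g g-1, non-negative masses, known compartments
    and mass bases) and uniqueness of (plot_id, compartment, layer, position).
    Raises :class:`SchemaError` naming the offending column and rows.
    """
    df = pd.read_csv(path)
    _require_columns(df, MEASUREMENT_COLUMNS, "measurements")
    for col in ("delta13C_permil", "c_concentration", "mass_value"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise SchemaError(f"measurements column {col!r} is not numeric")
        if df[col].isna().any():
            raise SchemaError(
                f"measurements column {col!r} has missing values in row(s) {_rows(df[col].isna())}"
            )
    bad = df["delta13C_permil"] <= -1000.0
    if bad.any():
        raise SchemaError(
            f"delta13C_permil <= -1000 permil is unphysical; row(s) {_rows(bad)}"
        )
    bad = ~df["c_concentration"].between(0.0, 0.6, inclusive="neither")
    if bad.any():
        raise SchemaError(
            f"c_concentration must lie in (0, 0.6) g C per g; row(s) {_rows(bad)}"
        )
    bad = df["mass_value"] < 0
    if bad.any():
        raise SchemaError(f"mass_value must be non-negative; row(s) {_rows(bad)}")
    bad = ~df["compartment"].isin(COMPARTMENTS)
    if bad.any():
        raise SchemaError(
            f"unknown compartment(s) {sorted(df.loc[bad, 'compartment'].unique())}; "
            f"row(s) {_rows(bad)}"
        )
    bad = ~df["mass_basis"].isin(MASS_BASES)
    if bad.any():
        raise SchemaError(f"mass_basis must be one of {MASS_BASES}; row(s) {_rows(bad)}")
    key = ["plot_id", "compartment", "layer", "position"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        raise SchemaError(
            f"duplicate (plot_id, compartment, layer, position) row(s): {_rows(dup)}"
        )
    return df


def read_references(path: str | Path) -> pd.DataFrame:
    """Read and validate the natural-abundance reference table."""
    df = pd.read_csv(path)
    _require_columns(df, REFERENCE_COLUMNS, "references")
    if df["delta13C_permil"].isna().any() or (df["delta13C_permil"] <= -1000).any():
        raise SchemaError("reference delta13C_permil values must be > -1000 permil")
    bad = ~df["material"].isin(("plant", "soil"))
    if bad.any():
        raise SchemaError(f"reference material must be plant or soil; row(s) {_rows(bad)}")
    key = ["system", "regime", "layer", "material"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        raise SchemaError(f"duplicate reference row(s) for {key}: {_rows(dup)}")
    return df


def read_geometry(path: str | Path) -> pd.DataFrame:
    """Read and validate the soil-layer geometry table."""
    df = pd.read_csv(path)
    _require_columns(df, GEOMETRY_COLUMNS, "geometry")
    if (df["thickness_m"] <= 0).any():
        raise SchemaError("layer thickness_m must be positive")
    if (~df["bulk_density_kg_m3"].between(800, 2000)).any():
        raise SchemaError("bulk_density_kg_m3 must lie in [800, 2000]")
    if df["layer"].duplicated().any():
        raise SchemaError("duplicate layer in geometry table")
    return df
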