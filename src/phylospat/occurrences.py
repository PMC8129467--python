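"""Occurrence-record cleaning and rasterization to a presence matrix.

Records arrive as a table with columns ``species``, ``lon``, ``lat`` (GBIF's
``decimalLongitude``/``decimalLatitude`` are accepted as aliases). Cleaning
attaches named flags rather than deleting rows, so every decision is
auditable; the retained set is the rows with no flags.

Cleaning rules
--------------
``invalid``  non-numeric or outside lon [-180, 180] / lat [-90, 90]
``zero``     both coordinates exactly 0 (a common database placeholder)
``equal``    lat == lon to within 1e-8 (transposition/copy errors)
``outlier``  great-circle distance to the species centroid exceeds
             ``k`` x the median absolute deviation of those distances
             (applied per species, only when the species has at least
             ``min_records_for_outlier`` numerically valid records)
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .grids import GridSpec, haversine_m

FLAG_INVALID = "invalid"
FLAG_ZERO = "zero"
FLAG_EQUAL = "equal"
FLAG_OUTLIER = "outlier"
ALL_FLAGS = (FLAG_INVALID, FLAG_ZERO, FLAG_EQUAL, FLAG_OUTLIER)

_ALIASES = {"decimallongitude": "lon", "decimallatitude": "lat"}


def _normalize(records: pd.DataFrame) -> pd.DataFrame:
    out = records.rename(columns={c: _ALIASES.get(c.lower(), c) for c in records.columns})
    missing = {"species", "lon", "lat"} - set(out.columns)
    if missing:
        raise ValueError(f"occurrence table lacks columns: {sorted(missing)}")
    return out


def clean_records(
    records: pd.DataFrame,
    k: float = 5.0,
    min_records_for_outlier: int = 5,
    equal_tol: float = 1e-8,
) -> pd.DataFrame:
    """Attach cleaning flags; returns the table with a ``flags`` column.

    ``flags`` holds a comma-joined string of rule names (empty = clean).
    Cleaning is idempotent: re-running on the retained rows flags nothing,
    because the outlier rule is evaluated on the rows that survive the
    coordinate rules.
    """
    records = _normalize(records)
    if len(records) == 0:
        warnings.warn("empty occurrence table", stacklevel=2)
        return records.assign(flags="")

    lon = pd.to_numeric(records["lon"], errors="coerce").to_numpy()
    lat = pd.to_numeric(records["lat"], errors="coerce").to_numpy()
    flags = [[] for _ in range(len(records))]

    invalid = (~np.isfinite(lon) | ~np.isfinite(lat)
               | (np.abs(lon) > 180.0) | (np.abs(lat) > 90.0))
    zero = ~invalid & (lon == 0.0) & (lat == 0.0)
    equal = ~invalid & ~zero & (np.abs(lon - lat) <= equal_tol)
    for i in np.flatnonzero(invalid):
        flags[i].append(FLAG_INVALID)
    for i in np.flatnonzero(zero):
        flags[i].append(FLAG_ZERO)
    for i in np.flatnonzero(equal):
        flags[i].append(FLAG_EQUAL)

    coord_ok = ~(invalid | zero | equal)
    species = records["species"].to_numpy()
    for sp in pd.unique(species):
        idx = np.flatnonzero((species == sp) & coord_ok)
        if len(idx) < min_records_for_outlier:
            continue
        c_lon, c_lat = lon[idx].mean(), lat[idx].mean()
        d = haversine_m(lon[idx], lat[idx], c_lon, c_lat)
        med = np.median(d)
        mad = np.median(np.abs(d - med))
        if mad <= 0:
            continue
        # robust location + scale rule, as in CoordinateCleaner's MAD method
        for i in idx[d > med + k * mad]:
            flags[i].append(FLAG_OUTLIER)

    out = records.copy()
    out["lon"] = lon
    out["lat"] = lat
    out["flags"] = [",".join(f) for f in flags]
    return out


def retained(records: pd.DataFrame) -> pd.DataFrame:
    """Rows that passed every cleaning rule."""
    if "flags" not in records.columns:
        raise ValueError("records have not been cleaned (no 'flags' column)")
    return records[records["flags"] == ""]


def assign_cells(records: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Attach ``cell_id`` to cleaned records (error on unclean coordinates)."""
    records = _normalize(records)
    lon = records["lon"].to_numpy(dtype=float)
    lat = records["lat"].to_numpy(dtype=float)
    bad = ~np.isfinite(lon) | ~np.isfinite(lat) | (np.abs(lon) > 180) | (np.abs(lat) > 90)
    if bad.any():
        rows = records.index[bad].tolist()[:10]
        raise ValueError(f"unclean coordinates in rows {rows}; run clean_records first")
    out = records.copy()
    out["cell_id"] = grid.cell_id(lon, lat)
    return out


def build_presence(records: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Cells x species binary incidence matrix (0/1 DataFrame).

    Rows are occupied cell ids (sorted), columns are species (sorted).
    Duplicate records in one cell collapse to a single presence. Species with
    zero retained records are absent by construction; a warning lists species
    present in the input but contributing no cell.
    """
    if "cell_id" not in records.columns:
        records = assign_cells(records, grid)
    if len(records) == 0:
        warnings.warn("no records to grid; empty presence matrix", stacklevel=2)
        return pd.DataFrame(dtype=np.int8)
    pairs = records[["cell_id", "species"]].drop_duplicates()
    P = (
        pairs.assign(one=np.int8(1))
        .pivot_table(index="cell_id", columns="species", values="one", fill_value=0)
        .astype(np.int8)
        .sort_index()
    )
    P.columns.name = "species"
    return P[sorted(P.columns)]


def range_sizes(P: pd.DataFrame) -> pd.Series:
    """Per-species occupied-cell counts R_s (column sums of the incidence)."""
    return P.sum(axis=0).astype(int)


def presence_to_triplets(P: pd.DataFrame) -> pd.DataFrame:
    """Sparse (cell_id, species, 1) triplet form for CSV serialization."""
    stacked = P.stack()
    stacked = stacked[stacked > 0]
    out = stacked.reset_index()
    out.columns = ["cell_id", "species", "presence"]
    return out


def triplets_to_presence(trip: pd.DataFrame) -> pd.DataFrame:
    P = (
        trip.assign(presence=1)
        .pivot_table(index="cell_id", columns="species", values="presence", fill_value=0)
        .astype(np.int8)
        .sort_index()
    )
    return P[sorted(P.columns)]
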