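"""Community count data containers and readers.

The working format is a long table with one row per observed count:
``species, time, location, replicate, count``, optionally accompanied by
location metadata (latitude/longitude in decimal degrees, habitat label).
A reader for the BioTIME raw-CSV dialect is provided with a configurable
column map, together with the zero-filling rule used throughout: for every
recorded sampling event (time, location, replicate) every registered
species absent from the event is an explicit zero count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CommunityTable",
    "DistanceMatrix",
    "read_biotime",
    "zero_fill",
    "haversine_matrix",
    "split_by_habitat",
]

COLUMNS = ["species", "time", "location", "replicate", "count"]

EARTH_RADIUS_KM = 6371.0

#: default column map for the BioTIME raw-CSV dialect
BIOTIME_COLUMNS = {
    "species": "GENUS_SPECIES",
    "time": "YEAR",
    "abundance": "sum.allrawdata.ABUNDANCE",
    "latitude": "LATITUDE",
    "longitude": "LONGITUDE",
    "plot": "PLOT",
    "date": "DATE",
    "habitat": None,
}


@dataclass
class CommunityTable:
    """Long-format community count data.

    Parameters
    ----------
    data :
        DataFrame with columns ``species, time, location, replicate, count``.
        ``time`` is real-valued (years for temporal data); ``replicate``
        may be a constant when there are no repeated observations.
    locations :
        Optional per-location metadata indexed by location identifier with
        any of columns ``latitude``, ``longitude``, ``habitat``.
    """

    data: pd.DataFrame
    locations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in ("replicate",):
            if col not in df:
                df[col] = 0
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        counts = df["count"].to_numpy()
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        if not np.array_equal(counts, np.asarray(counts, dtype=np.int64).astype(counts.dtype)):
            raise ValueError("counts must be integers (count data required)")
        df["count"] = df["count"].astype(np.int64)
        df["time"] = df["time"].astype(float)
        self.data = df[COLUMNS].reset_index(drop=True)

    # -- basic registry ---------------------------------------------------
    @property
    def species(self) -> list:
        return sorted(self.data["species"].unique().tolist())

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.data["time"].unique())

    @property
    def location_ids(self) -> list:
        return sorted(self.data["location"].unique().tolist())

    @property
    def n_obs(self) -> int:
        return len(self.data)

    def __len__(self) -> int:
        return len(self.data)

    # -- io ---------------------------------------------------------------
    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)
        if self.locations is not None:
            side = Path(path).with_suffix(".locations.csv")
            self.locations.to_csv(side, index_label="location")

    @classmethod
    def read_csv(cls, path: str | Path) -> "CommunityTable":
        df = pd.read_csv(path)
        side = Path(path).with_suffix(".locations.csv")
        locations = pd.read_csv(side, index_col="location") if side.exists() else None
        return cls(df, locations)

    def zero_fill(self) -> "CommunityTable":
        return zero_fill(self)


def zero_fill(table: CommunityTable) -> CommunityTable:
    """Add explicit zeros for registered species missing from recorded events.

    Every (time, location, replicate) combination already present in the
    data gains one zero row per absent species; no new sampling events are
    invented.  Idempotent, and preserves all positive counts.
    """
    df = table.data
    dup = df.duplicated(subset=["species", "time", "location", "replicate"])
    if dup.any():
        raise ValueError("duplicate (species, time, location, replicate) rows")
    events = df[["time", "location", "replicate"]].drop_duplicates()
    species = pd.DataFrame({"species": sorted(df["species"].unique())})
    full = events.merge(species, how="cross")
    out = full.merge(df, on=["species", "time", "location", "replicate"], how="left")
    out["count"] = out["count"].fillna(0).astype(np.int64)
    out = out.sort_values(["location", "time", "replicate", "species"]).reset_index(drop=True)
    return CommunityTable(out[COLUMNS], table.locations)


def read_biotime(
    path: str | Path,
    column_map: dict | str | Path | None = None,
    location_from: str = "coordinates",
    replicate_from: str | None = None,
) -> CommunityTable:
    """Read a BioTIME-style raw CSV into a :class:`CommunityTable`.

    Parameters
    ----------
    path :
        CSV file with at least species, year and abundance columns.
    column_map :
        Mapping from the roles in :data:`BIOTIME_COLUMNS` to column names
        in the file, or a path to a YAML/JSON file holding one.  Roles
        omitted fall back to the BioTIME defaults.
    location_from :
        ``"coordinates"`` (location identity = rounded lat/lon pair) or
        ``"plot"`` (use the plot column).
    replicate_from :
        Optional role (e.g. ``"date"``) whose column becomes the replicate
        key -- used for the bat-style repeated observations within years.
    """
    if isinstance(column_map, (str, Path)):
        p = Path(column_map)
        loaded = yaml.safe_load(p.read_text()) if p.suffix in (".yml", ".yaml") else json.loads(p.read_text())
        column_map = loaded
    cmap = dict(BIOTIME_COLUMNS)
    if column_map:
        cmap.update(column_map)

    df = pd.read_csv(path)
    for role in ("species", "time", "abundance"):
        col = cmap[role]
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} (role {role!r})")

    abundance = pd.to_numeric(df[cmap["abundance"]])
    if (abundance < 0).any():
        raise ValueError("negative abundance encountered")
    rounded = abundance.round()
    if not np.allclose(abundance, rounded, atol=1e-9):
        raise ValueError("non-integer abundances: count data required")

    out = pd.DataFrame(
        {
            "species": df[cmap["species"]],
            "time": pd.to_numeric(df[cmap["time"]]).astype(float),
            "count": rounded.astype(np.int64),
        }
    )

    lat_col, lon_col = cmap["latitude"], cmap["longitude"]
    have_coords = lat_col in df.columns and lon_col in df.columns
    if location_from == "plot":
        plot_col = cmap["plot"]
        if plot_col not in df.columns:
            raise ValueError(f"missing plot column {plot_col!r}")
        out["location"] = df[plot_col].astype(str)
    elif location_from == "coordinates":
        if not have_coords:
            raise ValueError("missing latitude/longitude columns")
        lat = pd.to_numeric(df[lat_col]).round(6)
        lon = pd.to_numeric(df[lon_col]).round(6)
        out["location"] = lat.astype(str) + "_" + lon.astype(str)
    else:
        raise ValueError("location_from must be 'coordinates' or 'plot'")

    if replicate_from is not None:
        rep_col = cmap.get(replicate_from, replicate_from)
        if rep_col not in df.columns:
            raise ValueError(f"missing replicate column {rep_col!r}")
        out["replicate"] = df[rep_col].astype(str)
    else:
        out["replicate"] = 0

    # counts recorded for the same key are summed (BioTIME rows can split
    # one sampling event across grid cells)
    grouped = (
        out.groupby(["species", "time", "location", "replicate"], as_index=False)["count"]
        .sum()
    )

    # per-location metadata keyed on the same location identity
    meta = pd.DataFrame({"location": out["location"]})
    if have_coords:
        meta["latitude"] = pd.to_numeric(df[lat_col]).to_numpy()
        meta["longitude"] = pd.to_numeric(df[lon_col]).to_numpy()
    hab = cmap.get("habitat")
    if hab and hab in df.columns:
        meta["habitat"] = df[hab].to_numpy()
    locations = meta.groupby("location").first() if meta.shape[1] > 1 else None

    return CommunityTable(grouped, locations)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances (km) with a location ordering registry."""

    locations: list
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.locations), len(self.locations)):
            raise ValueError("distance matrix shape does not match locations")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        if np.any(np.abs(np.diagonal(v)) > 1e-12):
            raise ValueError("diagonal must be zero")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        self.values = v

    def submatrix(self, locs: list) -> np.ndarray:
        idx = [self.locations.index(l) for l in locs]
        return self.values[np.ix_(idx, idx)]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.locations, columns=self.locations).to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(locations=df.index.tolist(), values=df.to_numpy(dtype=float))


def haversine_matrix(locations: pd.DataFrame) -> DistanceMatrix:
    """Great-circle distance matrix (km) from decimal-degree coordinates.

    ``locations`` is indexed by location id with ``latitude`` and
    ``longitude`` columns; Earth radius 6371 km.
    """
    lat = np.asarray(locations["latitude"], dtype=float)
    lon = np.asarray(locations["longitude"], dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("coordinates out of range")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(locations=locations.index.tolist(), values=d)


def split_by_habitat(table: CommunityTable, label: str) -> CommunityTable:
    """Subset the table to locations with the given habitat label.

    The species registry of the subset is restricted to species actually
    observed (count > 0) in it, so later zero-filling treats the subset as
    its own community.
    """
    if table.locations is None or "habitat" not in table.locations.columns:
        raise ValueError("no habitat metadata available")
    habitats = table.locations["habitat"]
    available = sorted(habitats.dropna().unique().tolist())
    if label not in available:
        raise ValueError(f"unknown habitat {label!r}; available: {available}")
    keep = habitats[habitats == label].index
    df = table.data[table.data["location"].isin(keep)]
    seen = df.loc[df["count"] > 0, "species"].unique()
    df = df[df["species"].isin(seen)].reset_index(drop=True)
    return CommunityTable(df, table.locations.loc[table.locations.index.isin(keep)])
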