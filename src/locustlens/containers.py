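"""Core data containers: region atlas, monthly climate grid, event records,
and the labelled presence/absence table.

The atlas is a set of named, pairwise-disjoint rectangular (country, region)
cells under the half-open convention ``[min, max)`` — an exact, offline
stand-in for reverse geocoding.  The climate grid holds monthly precipitation
(mm), maximum temperature (°C) and soil moisture (volumetric water content)
on a regular lat/lon grid, the three covariates the presence/absence
classifier consumes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .errors import (
    ContractError,
    FormatError,
    GridValidationError,
)

#: Column order of the labelled table (7 features + target).
GLAD_COLUMNS = [
    "start_month",
    "start_year",
    "country",
    "region",
    "soil_moisture",
    "precipitation",
    "max_temperature",
    "locust_present",
]

LABELS = ("yes", "no")


class EventRecord(NamedTuple):
    """One reported swarm sighting: a point event with a start year/month."""

    lat: float
    lon: float
    start_year: int
    start_month: int


@dataclass(frozen=True)
class AtlasCell:
    country: str
    region: str
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def contains(self, lat: float, lon: float) -> bool:
        """Half-open containment test: ``[min, max)`` on both axes."""
        return (
            self.lat_min <= lat < self.lat_max
            and self.lon_min <= lon < self.lon_max
        )

    @property
    def centroid(self) -> tuple[float, float]:
        return (
            0.5 * (self.lat_min + self.lat_max),
            0.5 * (self.lon_min + self.lon_max),
        )


@dataclass
class RegionAtlas:
    """Ordered list of named rectangular cells tiling the study area."""

    cells: list[AtlasCell]

    def __post_init__(self) -> None:
        for c in self.cells:
            if not (c.lat_min < c.lat_max and c.lon_min < c.lon_max):
                raise ContractError(f"degenerate cell {c.country}/{c.region}")
            if not (c.country and c.region):
                raise ContractError("cell with empty country or region name")

    def __len__(self) -> int:
        return len(self.cells)

    def lookup(self, lat: float, lon: float) -> AtlasCell | None:
        """Return the unique cell containing the point, or None."""
        if not (np.isfinite(lat) and np.isfinite(lon)):
            raise ContractError("non-finite coordinates")
        for c in self.cells:
            if c.contains(lat, lon):
                return c
        return None

    def cell_of(self, country: str, region: str) -> AtlasCell:
        for c in self.cells:
            if c.country == country and c.region == region:
                return c
        raise ContractError(f"no atlas cell named {country}/{region}")

    def countries(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.cells:
            seen.setdefault(c.country, None)
        return list(seen)

    def regions_of(self, country: str) -> list[AtlasCell]:
        return [c for c in self.cells if c.country == country]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (c.country, c.region, c.lat_min, c.lat_max, c.lon_min, c.lon_max)
                for c in self.cells
            ],
            columns=["country", "region", "lat_min", "lat_max", "lon_min", "lon_max"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RegionAtlas":
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"country", "region", "lat_min", "lat_max", "lon_min", "lon_max"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"atlas CSV missing columns: {sorted(missing)}")
        return cls(
            [
                AtlasCell(
                    str(r.country), str(r.region),
                    float(r.lat_min), float(r.lat_max),
                    float(r.lon_min), float(r.lon_max),
                )
                for r in df.itertuples()
            ]
        )


CLIMATE_VARS = ("ppt", "tmax", "soil")


def _months_contiguous(time_axis: Sequence[tuple[int, int]]) -> bool:
    for (y0, m0), (y1, m1) in zip(time_axis, time_axis[1:]):
        if (y1 * 12 + m1) - (y0 * 12 + m0) != 1:
            return False
    return True


@dataclass
class ClimateGrid:
    """Monthly gridded climate fields on (time, lat, lon) axes.

    ``ppt`` is precipitation in mm/month, ``tmax`` maximum temperature in °C,
    ``soil`` soil moisture in volumetric water content units.
    """

    lat_axis: np.ndarray
    lon_axis: np.ndarray
    time_axis: list[tuple[int, int]]  # ordered (year, month) pairs
    ppt: np.ndarray
    tmax: np.ndarray
    soil: np.ndarray

    def __post_init__(self) -> None:
        self.lat_axis = np.asarray(self.lat_axis, dtype=float)
        self.lon_axis = np.asarray(self.lon_axis, dtype=float)
        self.time_axis = [(int(y), int(m)) for y, m in self.time_axis]
        self.validate()

    def validate(self) -> None:
        if np.any(np.diff(self.lat_axis) <= 0):
            raise GridValidationError("latitude axis is not strictly increasing")
        if np.any(np.diff(self.lon_axis) <= 0):
            raise GridValidationError("longitude axis is not strictly increasing")
        if not all(1 <= m <= 12 for _, m in self.time_axis):
            raise GridValidationError("time axis has a month outside 1..12")
        if not _months_contiguous(self.time_axis):
            raise GridValidationError("time axis has calendar gaps")
        shape = (len(self.time_axis), len(self.lat_axis), len(self.lon_axis))
        for name in CLIMATE_VARS:
            arr = getattr(self, name)
            if arr.shape != shape:
                raise GridValidationError(
                    f"{name} has shape {arr.shape}, expected {shape}"
                )
        if np.any(self.ppt < 0):
            raise GridValidationError("negative precipitation")
        if np.any(self.soil < 0):
            raise GridValidationError("negative soil moisture")

    def time_index(self, year: int, month: int) -> int | None:
        try:
            return self.time_axis.index((int(year), int(month)))
        except ValueError:
            return None

    @property
    def grid_step(self) -> float:
        steps = []
        if len(self.lat_axis) > 1:
            steps.append(float(np.min(np.diff(self.lat_axis))))
        if len(self.lon_axis) > 1:
            steps.append(float(np.min(np.diff(self.lon_axis))))
        return min(steps) if steps else np.inf

    def to_dataset(self) -> xr.Dataset:
        years = np.array([y for y, _ in self.time_axis], dtype=np.int32)
        months = np.array([m for _, m in self.time_axis], dtype=np.int32)
        return xr.Dataset(
            {
                "ppt": (("time", "lat", "lon"), self.ppt),
                "tmax": (("time", "lat", "lon"), self.tmax),
                "soil": (("time", "lat", "lon"), self.soil),
                "year": ("time", years),
                "month": ("time", months),
            },
            coords={
                "time": np.arange(len(self.time_axis), dtype=np.int32),
                "lat": self.lat_axis,
                "lon": self.lon_axis,
            },
            attrs={"ppt_units": "mm/month", "tmax_units": "degC", "soil_units": "VWC"},
        )

    def to_netcdf(self, path) -> None:
        # scipy engine -> classic netCDF-3, readable anywhere
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "ClimateGrid":
        try:
            ds = xr.open_dataset(path, engine="scipy")
        except (OSError, ValueError) as exc:
            raise FormatError(f"cannot read climate netCDF: {exc}") from exc
        with ds:
            for dim in ("time", "lat", "lon"):
                if dim not in ds.dims:
                    raise FormatError(f"climate file missing dimension '{dim}'")
            for var in CLIMATE_VARS + ("year", "month"):
                if var not in ds.variables:
                    raise FormatError(f"climate file missing variable '{var}'")
            time_axis = list(
                zip(ds["year"].values.tolist(), ds["month"].values.tolist())
            )
            return cls(
                lat_axis=ds["lat"].values.astype(float),
                lon_axis=ds["lon"].values.astype(float),
                time_axis=time_axis,
                ppt=np.asarray(ds["ppt"].values, dtype=float),
                tmax=np.asarray(ds["tmax"].values, dtype=float),
                soil=np.asarray(ds["soil"].values, dtype=float),
            )


@dataclass
class GladDataset:
    """Labelled presence/absence table plus provenance counters.

    ``rows`` follows the 8-column schema in :data:`GLAD_COLUMNS`; the counters
    make the fusion bookkeeping auditable (rows read = rows kept + dropped).
    """

    rows: pd.DataFrame
    rows_read: int = 0
    rows_dropped: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in GLAD_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ContractError(f"labelled table missing columns: {missing}")
        bad = set(self.rows["locust_present"].unique()) - set(LABELS)
        if bad:
            raise ContractError(f"unknown label values: {sorted(bad)}")
        self.rows = self.rows[GLAD_COLUMNS].reset_index(drop=True)

    @property
    def n_positive(self) -> int:
        return int((self.rows["locust_present"] == "yes").sum())

    @property
    def n_negative(self) -> int:
        return int((self.rows["locust_present"] == "no").sum())

    def __len__(self) -> int:
        return len(self.rows)

    def counters(self) -> dict[str, int]:
        return {
            "rows_read": self.rows_read,
            "rows_dropped": self.rows_dropped,
            "positives": self.n_positive,
            "negatives": self.n_negative,
        }

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GladDataset":
        # round_trip parsing keeps write->read float-exact
        df = pd.read_csv(path, float_precision="round_trip")
        out = cls(rows=df)
        out.rows_read = len(df)
        return out


def events_to_csv(events: Sequence[EventRecord], path) -> None:
    pd.DataFrame(events, columns=["lat", "lon", "start_year", "start_month"]).to_csv(
        path, index=False
    )


def events_from_csv(path) -> list[EventRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"lat", "lon", "start_year", "start_month"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"events CSV missing columns: {sorted(missing)}")
    return [
        EventRecord(float(r.lat), float(r.lon), int(r.start_year), int(r.start_month))
        for r in df.itertuples()
    ]
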