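"""Data fusion: attach climate covariates and (country, region) names to
point swarm events, producing the positive (presence) class of the labelled
table.

The extraction rule is nearest-grid-cell, not interpolation: a query takes
the value of the grid node whose centre is closest in Euclidean degree
distance, with exact ties broken toward the smaller axis index.  The
year-month join is exact — an event in (1992, 7) gets the July 1992 field.
Events that fall outside every atlas cell, or whose covariates cannot be
sampled, are dropped and counted, mirroring the null-dropping cleaning rule.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    ClimateGrid,
    EventRecord,
    GLAD_COLUMNS,
    GladDataset,
    RegionAtlas,
)
from .errors import (
    ContractError,
    EmptyOutputError,
    SpatialCoverageError,
    TemporalCoverageError,
)


def read_climate(path) -> ClimateGrid:
    """Read a monthly climate grid from netCDF, validating axes and shapes."""
    return ClimateGrid.from_netcdf(path)


def write_climate(grid: ClimateGrid, path) -> None:
    grid.to_netcdf(path)


def reverse_geocode(
    atlas: RegionAtlas, lat: float, lon: float
) -> tuple[str, str] | None:
    """Map a coordinate to (country, region) names, or None if outside the
    atlas.  Cells are half-open ``[min, max)``, so a point on a shared edge
    belongs to the cell whose interval starts there."""
    cell = atlas.lookup(lat, lon)
    if cell is None:
        return None
    return cell.country, cell.region


def _nearest_index(axis: np.ndarray, value: float) -> int:
    # ties toward the smaller index: argmin returns the first minimum
    return int(np.argmin(np.abs(axis - value)))


def sample_climate(
    grid: ClimateGrid, lat: float, lon: float, year: int, month: int
) -> tuple[float, float, float]:
    """Return (ppt, tmax, soil) of the nearest grid node for that month.

    Raises :class:`TemporalCoverageError` if (year, month) is outside the
    grid span, and :class:`SpatialCoverageError` if the point is farther than
    one grid step outside the grid's bounding box.
    """
    t = grid.time_index(year, month)
    if t is None:
        raise TemporalCoverageError(
            f"({year}, {month}) outside climate span "
            f"{grid.time_axis[0]}..{grid.time_axis[-1]}"
        )
    step = grid.grid_step
    if (
        lat < grid.lat_axis[0] - step
        or lat > grid.lat_axis[-1] + step
        or lon < grid.lon_axis[0] - step
        or lon > grid.lon_axis[-1] + step
    ):
        raise SpatialCoverageError(
            f"point ({lat}, {lon}) farther than one grid step outside the grid"
        )
    i = _nearest_index(grid.lat_axis, lat)
    j = _nearest_index(grid.lon_axis, lon)
    return (
        float(grid.ppt[t, i, j]),
        float(grid.tmax[t, i, j]),
        float(grid.soil[t, i, j]),
    )


def build_positive_rows(
    events: Sequence[EventRecord],
    grid: ClimateGrid,
    atlas: RegionAtlas,
    collapse_region_months: bool = False,
) -> GladDataset:
    """One presence-labelled row per geocodable event.

    Events that reverse-geocode to nothing or whose covariates cannot be
    sampled are dropped (and counted).  Duplicate events in the same
    region-month each keep their own row unless ``collapse_region_months``.
    """
    records = []
    dropped = 0
    for ev in events:
        if not (1 <= ev.start_month <= 12):
            raise ContractError(f"event month {ev.start_month} outside 1..12")
        place = reverse_geocode(atlas, ev.lat, ev.lon)
        if place is None:
            dropped += 1
            continue
        try:
            ppt, tmax, soil = sample_climate(
                grid, ev.lat, ev.lon, ev.start_year, ev.start_month
            )
        except (TemporalCoverageError, SpatialCoverageError):
            dropped += 1
            continue
        if not all(np.isfinite(v) for v in (ppt, tmax, soil)):
            dropped += 1
            continue
        records.append(
            (
                ev.start_month,
                ev.start_year,
                place[0],
                place[1],
                soil,
                ppt,
                tmax,
                "yes",
            )
        )
    if not records:
        raise EmptyOutputError("no event survived geocoding and sampling")
    rows = pd.DataFrame(records, columns=GLAD_COLUMNS)
    if collapse_region_months:
        rows = rows.drop_duplicates(
            subset=["country", "region", "start_year", "start_month"],
            keep="first",
        ).reset_index(drop=True)
    out = GladDataset(rows=rows, rows_read=len(events), rows_dropped=dropped)
    return out
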