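"""Fusion stage: climate I/O, offline reverse geocoding, nearest-cell
covariate extraction, positive-row assembly."""

import numpy as np
import pytest
import xarray as xr

from locustlens.containers import AtlasCell, ClimateGrid, EventRecord, RegionAtlas
from locustlens.errors import (
    EmptyOutputError,
    FormatError,
    GridValidationError,
    SpatialCoverageError,
    TemporalCoverageError,
)
from locustlens.fusion import (
    build_positive_rows,
    read_climate,
    reverse_geocode,
    sample_climate,
    write_climate,
)


def tiny_grid(nlat=5, nlon=5, months=((2000, 1), (2000, 2)), seed=0):
    rng = np.random.default_rng(seed)
    shape = (len(months), nlat, nlon)
    return ClimateGrid(
        lat_axis=np.arange(nlat, dtype=float),
        lon_axis=np.arange(nlon, dtype=float),
        time_axis=list(months),
        ppt=rng.uniform(0, 100, shape),
        tmax=rng.uniform(10, 40, shape),
        soil=rng.uniform(0, 50, shape),
    )


class TestClimateIO:
    def test_round_trip(self, tmp_path):
        grid = tiny_grid()
        path = tmp_path / "c.nc"
        write_climate(grid, path)
        back = read_climate(path)
        assert np.allclose(back.ppt, grid.ppt)
        assert np.allclose(back.tmax, grid.tmax)
        assert np.allclose(back.soil, grid.soil)
        assert back.time_axis == grid.time_axis
        assert np.array_equal(back.lat_axis, grid.lat_axis)

    def test_missing_variable_named(self, tmp_path):
        path = tmp_path / "bad.nc"
        ds = tiny_grid().to_dataset().drop_vars("soil")
        ds.to_netcdf(path, engine="scipy")
        with pytest.raises(FormatError, match="soil"):
            read_climate(path)

    def test_non_monotone_latitude_rejected(self):
        with pytest.raises(GridValidationError, match="latitude"):
            ClimateGrid(
                lat_axis=np.array([0.0, 2.0, 1.0]),
                lon_axis=np.array([0.0, 1.0]),
                time_axis=[(2000, 1)],
                ppt=np.zeros((1, 3, 2)),
                tmax=np.zeros((1, 3, 2)),
                soil=np.zeros((1, 3, 2)),
            )

    def test_calendar_gap_rejected(self):
        with pytest.raises(GridValidationError, match="gap"):
            tiny_grid(months=((2000, 1), (2000, 3)))


ATLAS = RegionAtlas(
    [
        AtlasCell("A", "A-R1", 0.0, 1.0, 0.0, 1.0),
        AtlasCell("A", "A-R2", 0.0, 1.0, 1.0, 2.0),
        AtlasCell("B", "B-R1", 1.0, 2.0, 0.0, 2.0),
    ]
)


class TestReverseGeocode:
    def test_cell_centre(self):
        assert reverse_geocode(ATLAS, 0.5, 1.5) == ("A", "A-R2")

    def test_outside_every_cell(self):
        assert reverse_geocode(ATLAS, 5.0, 5.0) is None

    def test_shared_edge_belongs_to_higher_min_cell(self):
        # lon = 1.0 is the shared edge of A-R1/A-R2: half-open [min, max)
        assert reverse_geocode(ATLAS, 0.5, 1.0) == ("A", "A-R2")
        # lat = 1.0 is the shared edge of country A and B
        assert reverse_geocode(ATLAS, 1.0, 0.5) == ("B", "B-R1")

    def test_partition_at_most_one_cell(self, rng):
        for lat, lon in zip(rng.uniform(-1, 3, 100), rng.uniform(-1, 3, 100)):
            hits = [c for c in ATLAS.cells if c.contains(lat, lon)]
            assert len(hits) <= 1


class TestSampleClimate:
    def test_exact_node_identity(self):
        grid = tiny_grid()
        v = sample_climate(grid, 2.0, 3.0, 2000, 1)
        assert v == (grid.ppt[0, 2, 3], grid.tmax[0, 2, 3], grid.soil[0, 2, 3])

    def test_midpoint_tie_goes_to_lower_index(self):
        grid = tiny_grid()
        v = sample_climate(grid, 1.5, 0.0, 2000, 2)
        assert v[0] == grid.ppt[1, 1, 0]

    def test_agrees_with_brute_force_argmin(self, rng):
        grid = tiny_grid(seed=9)
        for _ in range(100):
            lat = rng.uniform(-0.5, 4.5)
            lon = rng.uniform(-0.5, 4.5)
            got = sample_climate(grid, lat, lon, 2000, 1)
            best = min(
                ((i, j) for i in range(5) for j in range(5)),
                key=lambda ij: (
                    (grid.lat_axis[ij[0]] - lat) ** 2
                    + (grid.lon_axis[ij[1]] - lon) ** 2,
                    ij,
                ),
            )
            assert got[0] == grid.ppt[0, best[0], best[1]]

    def test_temporal_coverage_error(self):
        with pytest.raises(TemporalCoverageError):
            sample_climate(tiny_grid(), 0.0, 0.0, 1999, 12)

    def test_spatial_coverage_error(self):
        with pytest.raises(SpatialCoverageError):
            sample_climate(tiny_grid(), 50.0, 0.0, 2000, 1)


class TestBuildPositiveRows:
    def test_out_of_atlas_events_dropped_and_counted(self, small_system):
        _, atlas, grid, events = small_system
        outside = EventRecord(lat=-50.0, lon=-50.0, start_year=2001, start_month=1)
        out = build_positive_rows(list(events[:4]) + [outside], grid, atlas)
        assert len(out) == 4
        assert out.rows_dropped == 1
        assert out.rows_read == 5

    def test_event_at_region_centre_maps_to_that_region(self, small_system):
        _, atlas, grid, _ = small_system
        cell = atlas.cells[2]
        lat, lon = cell.centroid
        ev = EventRecord(lat, lon, *grid.time_axis[0])
        row = build_positive_rows([ev], grid, atlas).rows.iloc[0]
        assert (row["country"], row["region"]) == (cell.country, cell.region)
        assert row["locust_present"] == "yes"

    def test_covariates_match_independent_requery(self, small_system):
        _, atlas, grid, events = small_system
        out = build_positive_rows(events, grid, atlas)
        for ev, row in zip(events, out.rows.itertuples()):
            ppt, tmax, soil = sample_climate(
                grid, ev.lat, ev.lon, ev.start_year, ev.start_month
            )
            assert (row.precipitation, row.max_temperature, row.soil_moisture) == (
                ppt, tmax, soil,
            )

    def test_no_missing_covariates_and_counters_conserve(self, small_system):
        _, atlas, grid, events = small_system
        out = build_positive_rows(events, grid, atlas)
        covs = out.rows[["precipitation", "max_temperature", "soil_moisture"]]
        assert np.isfinite(covs.to_numpy()).all()
        assert len(out) + out.rows_dropped == out.rows_read

    def test_zero_survivors_is_an_error(self, small_system):
        _, atlas, grid, _ = small_system
        outside = [EventRecord(-50.0, -50.0, 2001, 1)]
        with pytest.raises(EmptyOutputError):
            build_positive_rows(outside, grid, atlas)

    def test_collapse_flag_deduplicates_region_months(self, small_system):
        _, atlas, grid, events = small_system
        doubled = list(events) + list(events)
        full = build_positive_rows(doubled, grid, atlas)
        collapsed = build_positive_rows(doubled, grid, atlas,
                                        collapse_region_months=True)
        assert len(full) == 2 * len(events)
        key = ["country", "region", "start_year", "start_month"]
        assert len(collapsed) == len(full.rows.drop_duplicates(subset=key))
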