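"""Pseudo-absence (negative class) generation.

Reported swarm data contains only presences.  For every region of every
country with at least one reported attack, each study-span month with no
recorded attack becomes one absence-labelled row, with climate covariates
sampled at the region-cell centroid for that month.  Per region this is an
exact calendar complement: |absence months| + |attacked months| = span
months, so the negative class is conserved by construction rather than
resampled.
"""

from __future__ import annotations

import pandas as pd

from .containers import ClimateGrid, GLAD_COLUMNS, GladDataset, RegionAtlas
from .errors import (
    ConsistencyError,
    ContractError,
    EmptyOutputError,
    MappingError,
)
from .fusion import sample_climate

AttackCalendar = dict[tuple[str, str], set[tuple[int, int]]]


def attack_calendar(positives: GladDataset) -> AttackCalendar:
    """Exact set of attacked (year, month) pairs per (country, region)."""
    if len(positives) == 0:
        raise ContractError("positive table is empty")
    if (positives.rows["locust_present"] != "yes").any():
        raise ContractError("attack calendar input must be all presence rows")
    cal: AttackCalendar = {}
    for r in positives.rows.itertuples():
        cal.setdefault((r.country, r.region), set()).add(
            (int(r.start_year), int(r.start_month))
        )
    return cal


def span_months(span: tuple[int, int]) -> list[tuple[int, int]]:
    y0, y1 = span
    return [(y, m) for y in range(y0, y1 + 1) for m in range(1, 13)]


def generate_negatives(
    calendar: AttackCalendar,
    atlas: RegionAtlas,
    grid: ClimateGrid,
    span: tuple[int, int],
    attacked_regions_only: bool = False,
) -> GladDataset:
    """One absence row per (region, non-attacked span month).

    The region universe defaults to every atlas region of each country that
    has at least one presence row — known regions are informative absences
    even in months when only a sibling region was attacked.
    ``attacked_regions_only`` restricts to regions with their own history.
    """
    months = span_months(span)
    for year, month in (months[0], months[-1]):
        if grid.time_index(year, month) is None:
            raise ContractError(f"span month ({year}, {month}) outside climate grid")
    attacked_countries = {country for country, _ in calendar}
    if attacked_regions_only:
        universe = [atlas.cell_of(c, r) for c, r in calendar]
    else:
        universe = [
            cell
            for country in sorted(attacked_countries)
            for cell in atlas.regions_of(country)
        ]
        known = {(c.country, c.region) for c in universe}
        orphans = [key for key in calendar if key not in known]
        if orphans:
            raise MappingError(f"calendar regions missing from atlas: {orphans}")
    records = []
    for cell in universe:
        attacked = calendar.get((cell.country, cell.region), set())
        lat_c, lon_c = cell.centroid
        for year, month in months:
            if (year, month) in attacked:
                continue
            ppt, tmax, soil = sample_climate(grid, lat_c, lon_c, year, month)
            records.append(
                (month, year, cell.country, cell.region, soil, ppt, tmax, "no")
            )
    rows = pd.DataFrame(records, columns=GLAD_COLUMNS)
    return GladDataset(rows=rows, rows_read=len(rows))


def assemble_dataset(positives: GladDataset, negatives: GladDataset) -> GladDataset:
    """Concatenate presence and absence rows with consistency checks."""
    if len(negatives) == 0:
        raise EmptyOutputError("no negative rows: downstream needs both classes")
    if len(positives) == 0:
        raise EmptyOutputError("no positive rows: downstream needs both classes")
    key = ["country", "region", "start_year", "start_month"]
    pos_keys = set(map(tuple, positives.rows[key].itertuples(index=False)))
    neg_keys = set(map(tuple, negatives.rows[key].itertuples(index=False)))
    clash = pos_keys & neg_keys
    if clash:
        raise ConsistencyError(
            f"{len(clash)} region-months labelled both yes and no, "
            f"e.g. {sorted(clash)[0]}"
        )
    rows = pd.concat([positives.rows, negatives.rows], ignore_index=True)
    return GladDataset(
        rows=rows,
        rows_read=positives.rows_read + negatives.rows_read,
        rows_dropped=positives.rows_dropped + negatives.rows_dropped,
    )


def per_country_class_counts(dataset: GladDataset) -> pd.DataFrame:
    """Presence/absence row counts by country (audit table)."""
    return (
        dataset.rows.groupby(["country", "locust_present"])
        .size()
        .unstack(fill_value=0)
        .rename_axis(columns=None)
    )
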