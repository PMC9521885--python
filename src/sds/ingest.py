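"""Ingestion: read input tables, pool POIs to buildings, bin to six-hour
intervals, and attach open/complaint flags.

Every row that is filtered out anywhere in the pipeline is accounted for in a
:class:`FilterLedger`, which enforces rows_in - rows_dropped = rows_out at
each step. Intervals are half-open ``[t, t + 6h)`` in local clock time, with
starts at 00:00, 06:00, 12:00 and 18:00.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

INTERVAL_HOURS = 6

POI_COLUMNS = ["poi_id", "building_id", "zip", "poi_type", "floor_area"]
VISIT_COLUMNS = ["poi_id", "timestamp", "visits", "open"]
COMPLAINT_COLUMNS = ["complaint_id", "timestamp", "building_id"]


@dataclass
class FilterLedger:
    """Ordered audit trail of row counts through every filtering rule."""

    steps: list[dict] = field(default_factory=list)

    def record(self, rule: str, rows_in: int, rows_out: int) -> None:
        dropped = rows_in - rows_out
        if dropped < 0:
            raise ValueError(f"rule {rule!r} emitted more rows than it received")
        self.steps.append(
            {"rule": rule, "rows_in": int(rows_in), "rows_out": int(rows_out),
             "rows_dropped": int(dropped)}
        )

    def total_dropped(self) -> int:
        return sum(s["rows_dropped"] for s in self.steps)

    def to_json(self) -> str:
        return json.dumps(self.steps, indent=2)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _require_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{name} is missing required column(s): {', '.join(missing)}")


def load_tables(
    poi_path: str | Path,
    visits_path: str | Path,
    complaints_path: str | Path,
    ledger: FilterLedger | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, FilterLedger]:
    """Read and validate the three core CSVs.

    Malformed rows (unparseable timestamps, negative counts, non-positive
    floor areas) are dropped and recorded in the ledger; a missing required
    column is a hard error naming the column. An empty complaint file with a
    valid header is legitimate (a city with no complaints).
    """
    ledger = ledger or FilterLedger()

    poi = pd.read_csv(poi_path, dtype={"poi_id": str, "building_id": str, "zip": str})
    _require_columns(poi, POI_COLUMNS, "poi table")
    n = len(poi)
    poi["floor_area"] = pd.to_numeric(poi["floor_area"], errors="coerce")
    poi = poi[poi["floor_area"] > 0]
    ledger.record("poi: positive floor_area", n, len(poi))
    n = len(poi)
    poi = poi.drop_duplicates(subset="poi_id", keep="first")
    ledger.record("poi: unique poi_id", n, len(poi))

    visits = pd.read_csv(visits_path, dtype={"poi_id": str})
    _require_columns(visits, VISIT_COLUMNS, "visit table")
    n = len(visits)
    visits["timestamp"] = pd.to_datetime(visits["timestamp"], errors="coerce")
    visits["visits"] = pd.to_numeric(visits["visits"], errors="coerce")
    ok = visits["timestamp"].notna() & visits["visits"].notna() & (visits["visits"] >= 0)
    visits = visits[ok].copy()
    ledger.record("visits: parseable timestamp and non-negative count", n, len(visits))
    n = len(visits)
    visits = visits[visits["poi_id"].isin(set(poi["poi_id"]))]
    ledger.record("visits: known poi_id", n, len(visits))
    visits["visits"] = visits["visits"].astype(np.int64)
    visits["open"] = visits["open"].astype(bool)

    complaints = pd.read_csv(complaints_path, dtype={"complaint_id": str, "building_id": str})
    _require_columns(complaints, COMPLAINT_COLUMNS, "complaint table")
    n = len(complaints)
    complaints["timestamp"] = pd.to_datetime(complaints["timestamp"], errors="coerce")
    complaints = complaints[complaints["timestamp"].notna()]
    ledger.record("complaints: parseable timestamp", n, len(complaints))

    return poi.reset_index(drop=True), visits.reset_index(drop=True), \
        complaints.reset_index(drop=True), ledger


def pool_to_buildings(
    poi_table: pd.DataFrame,
    visit_table: pd.DataFrame,
    ledger: FilterLedger | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, FilterLedger]:
    """Pool POIs sharing a building into one scoring unit.

    Per building: floor areas add, same-hour visits add, the unit is open if
    any member is open, the type is the modal member type (ties broken by the
    lexicographically smallest label), and the zip is the modal member zip.
    POIs without a building id go to the ledger.
    """
    ledger = ledger or FilterLedger()
    n = len(poi_table)
    poi = poi_table[poi_table["building_id"].notna() & (poi_table["building_id"] != "")]
    ledger.record("pooling: POI has building id", n, len(poi))

    def _modal(s: pd.Series) -> str:
        counts = s.value_counts()
        top = counts.max()
        return sorted(counts[counts == top].index)[0]

    unit = (
        poi.groupby("building_id", sort=True)
        .agg(
            floor_area=("floor_area", "sum"),
            n_pois_pooled=("poi_id", "size"),
            poi_type=("poi_type", _modal),
            zip=("zip", _modal),
        )
        .reset_index()
        .rename(columns={"building_id": "unit_id"})
    )

    v = visit_table.merge(
        poi[["poi_id", "building_id"]], on="poi_id", how="inner"
    )
    ledger.record("pooling: visit rows with pooled POI", len(visit_table), len(v))
    unit_visits = (
        v.groupby(["building_id", "timestamp"], sort=True)
        .agg(visits=("visits", "sum"), open=("open", "any"))
        .reset_index()
        .rename(columns={"building_id": "unit_id"})
    )
    return unit, unit_visits, ledger


def bin_six_hour(
    unit_visit_table: pd.DataFrame,
    unit_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Aggregate hourly unit visits into half-open six-hour intervals.

    Visits sum; the interval is open if any member hour is open. Duplicate
    (unit, hour) rows are ambiguous source data and raise. When a unit table
    with floor areas is supplied, the interval activity intensity (visits per
    10,000 sq ft) is attached.
    """
    if unit_visit_table.duplicated(subset=["unit_id", "timestamp"]).any():
        raise ValueError("duplicate (unit_id, timestamp) rows: ambiguous hourly source")
    df = unit_visit_table.copy()
    df["interval_start"] = df["timestamp"].dt.floor(f"{INTERVAL_HOURS}h")
    out = (
        df.groupby(["unit_id", "interval_start"], sort=True)
        .agg(visits=("visits", "sum"), open=("open", "any"))
        .reset_index()
    )
    out["complaint"] = False
    if unit_table is not None:
        areas = unit_table.set_index("unit_id")["floor_area"]
        out["intensity"] = out["visits"] * 10_000.0 / out["unit_id"].map(areas)
    return out


def flag_complaints(
    interval_table: pd.DataFrame,
    complaint_table: pd.DataFrame,
    ledger: FilterLedger | None = None,
    polygons: list | None = None,
) -> tuple[pd.DataFrame, FilterLedger]:
    """Mark intervals containing at least one complaint for their unit.

    A complaint at time t flags the interval [floor6h(t), +6h) of the unit
    named by its building id. Complaints whose building id matches no unit
    are resolved by point-in-polygon against ``polygons`` when provided
    (features whose ``id`` property names a unit), otherwise routed to the
    ledger. The flag is boolean — a second complaint in the same interval
    changes nothing, so the operation is idempotent.
    """
    ledger = ledger or FilterLedger()
    units = set(interval_table["unit_id"].unique())
    c = complaint_table.copy()
    n = len(c)

    matched_unit = c["building_id"].where(c["building_id"].isin(units))
    if polygons is not None and matched_unit.isna().any():
        from sds.geo import assign_points

        todo = matched_unit.isna() & c.get("lon", pd.Series(dtype=float)).notna()
        if todo.any():
            assigned = assign_points(
                c.loc[todo, "lon"].to_numpy(float),
                c.loc[todo, "lat"].to_numpy(float),
                polygons,
            )
            matched_unit.loc[todo] = [a if a in units else None for a in assigned]
    c["unit_id"] = matched_unit
    c = c[c["unit_id"].notna()]
    ledger.record("complaints: resolvable to a scored unit", n, len(c))

    c["interval_start"] = c["timestamp"].dt.floor(f"{INTERVAL_HOURS}h")
    flagged = set(zip(c["unit_id"], c["interval_start"]))
    out = interval_table.copy()
    key = list(zip(out["unit_id"], out["interval_start"]))
    out["complaint"] = [k in flagged for k in key]
    return out, ledger


def mode_complaint_hour(
    complaint_table: pd.DataFrame, unit_table: pd.DataFrame
) -> pd.Series:
    """Most frequent clock hour of complaints per establishment type.

    Ties break toward the earliest hour; types with zero complaints are
    omitted.
    """
    c = complaint_table.merge(
        unit_table[["unit_id", "poi_type"]],
        left_on="building_id",
        right_on="unit_id",
        how="inner",
    )
    if c.empty:
        return pd.Series(dtype=int, name="mode_hour")
    c["hour"] = c["timestamp"].dt.hour

    def _mode(hours: pd.Series) -> int:
        counts = hours.value_counts()
        top = counts.max()
        return int(min(counts[counts == top].index))

    return c.groupby("poi_type")["hour"].apply(_mode).rename("mode_hour")
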