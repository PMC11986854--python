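"""Readers/writers for point tables, scenarios and results, plus the
dispatch-record cleaning pipeline.

Point tables are delimited text (header: id, x/lon, y/lat, supply or demand,
zone) or GeoJSON FeatureCollections of Point features with the same fields
as properties.  All outputs are UTF-8, newline-terminated, with fixed column
order so files diff cleanly.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .catchment import (
    ZONES,
    AccessibilityResult,
    DemandPoint,
    StationSite,
)
from .geometry import GeoPoint, Metric, _pairwise
from .synthetic_data import Scenario, ScenarioSpec, spec_to_dict

logger = logging.getLogger("ems2sfca")

_X_ALIASES = ("x", "lon", "longitude")
_Y_ALIASES = ("y", "lat", "latitude")


# ---------------------------------------------------------------------------
# point tables


def _pick_column(df: pd.DataFrame, aliases: Sequence[str], what: str) -> str:
    for a in aliases:
        if a in df.columns:
            return a
    raise ValueError(f"no {what} column found (expected one of {aliases})")


def _crs_mode_from_columns(xcol: str) -> str:
    return "geographic" if xcol in ("lon", "longitude") else "planar"


def _rows_from_geojson(path: Path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    rows = []
    for k, feat in enumerate(gj.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise ValueError(f"{path}: feature {k} is not a Point")
        props = dict(feat.get("properties") or {})
        x, y = geom["coordinates"][:2]
        props.setdefault("id", feat.get("id"))
        props["lon"], props["lat"] = x, y
        rows.append(props)
    return pd.DataFrame(rows)


def read_points(
    path: str | Path,
    role: Literal["station", "demand"],
    crs_mode: str | None = None,
) -> list[StationSite] | list[DemandPoint]:
    """Load typed station or demand points from CSV or GeoJSON.

    Missing zone defaults to ``non_main_urban`` (warned); missing supply
    defaults to 1; missing demand defaults to 0 (warned).  Duplicate ids,
    non-numeric coordinates and unknown zone labels are rejected with the
    offending row named.  GeoJSON input implies geographic coordinates; CSV
    infers the frame from the coordinate column names (lon/lat → geographic,
    x/y → planar) unless ``crs_mode`` overrides it.
    """
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        df = _rows_from_geojson(path)
        inferred = "geographic"
    else:
        df = pd.read_csv(path)
        xcol = _pick_column(df, _X_ALIASES, "x/longitude")
        inferred = _crs_mode_from_columns(xcol)
    mode = crs_mode or inferred

    xcol = _pick_column(df, _X_ALIASES, "x/longitude")
    ycol = _pick_column(df, _Y_ALIASES, "y/latitude")
    if "id" not in df.columns:
        raise ValueError(f"{path}: missing 'id' column")

    ids = df["id"].astype(str)
    dup = ids[ids.duplicated()]
    if len(dup) > 0:
        raise ValueError(f"{path}: duplicate id(s): {sorted(set(dup))}")

    if "zone" not in df.columns:
        warnings.warn(f"{path}: no 'zone' column; defaulting to non_main_urban")
        df = df.assign(zone="non_main_urban")
    df["zone"] = df["zone"].fillna("non_main_urban")

    out = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        rid = str(rec["id"])
        try:
            x, y = float(rec[xcol]), float(rec[ycol])
        except (TypeError, ValueError):
            raise ValueError(f"{path} row {row_no} (id={rid}): non-numeric coordinates")
        zone = str(rec["zone"])
        if zone not in ZONES:
            raise ValueError(f"{path} row {row_no} (id={rid}): unknown zone {zone!r}")
        pt = GeoPoint(id=rid, x=x, y=y, crs_mode=mode)
        if role == "station":
            supply = rec.get("supply")
            supply = 1.0 if supply is None or (isinstance(supply, float) and np.isnan(supply)) else float(supply)
            out.append(StationSite(point=pt, supply=supply, zone=zone))
        elif role == "demand":
            demand = rec.get("demand")
            if demand is None or (isinstance(demand, float) and np.isnan(demand)):
                warnings.warn(f"{path} row {row_no}: missing demand, defaulting to 0")
                demand = 0.0
            out.append(DemandPoint(point=pt, demand=float(demand), zone=zone))
        else:
            raise ValueError(f"unknown role {role!r}")
    return out


def _points_frame(entities, value_col: str) -> pd.DataFrame:
    rows = []
    for e in entities:
        rows.append(
            {
                "id": e.id,
                "x": e.point.x,
                "y": e.point.y,
                value_col: getattr(e, value_col),
                "zone": e.zone,
            }
        )
    return pd.DataFrame(rows, columns=["id", "x", "y", value_col, "zone"])


def write_points(entities, path: str | Path) -> None:
    """Write stations or demand points as a fixed-order CSV."""
    value_col = "supply" if entities and isinstance(entities[0], StationSite) else "demand"
    _points_frame(entities, value_col).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# results


def write_results(
    result: AccessibilityResult,
    demand_points: Sequence[DemandPoint],
    path: str | Path,
    format: Literal["csv", "geojson"] = "csv",
) -> None:
    """Write per-demand-point accessibility as CSV or GeoJSON.

    Numeric output is repr-precision doubles; unreachable demand points
    appear with A = 0 and a flag column/property.
    """
    ids = [p.id for p in demand_points]
    missing = [i for i in ids if i not in result.A]
    if missing:
        raise ValueError(f"result is missing demand ids: {missing[:5]}")
    unreachable = set(result.unreachable_demand_ids)
    path = Path(path)

    if format == "csv":
        df = pd.DataFrame(
            {
                "demand_id": ids,
                "A": [repr(result.A[i]) for i in ids],
                "zone": [p.zone for p in demand_points],
                "x": [p.point.x for p in demand_points],
                "y": [p.point.y for p in demand_points],
                "unreachable": [i in unreachable for i in ids],
            }
        )
        df.to_csv(path, index=False)
    elif format == "geojson":
        features = [
            {
                "type": "Feature",
                "id": p.id,
                "geometry": {"type": "Point", "coordinates": [p.point.x, p.point.y]},
                "properties": {
                    "A": result.A[p.id],
                    "zone": p.zone,
                    "unreachable": p.id in unreachable,
                },
            }
            for p in demand_points
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_result_csv(path: str | Path) -> pd.DataFrame:
    """Read an accessibility CSV back (A restored exactly)."""
    df = pd.read_csv(path, float_precision="round_trip")
    df["A"] = df["A"].astype(float)
    return df


# ---------------------------------------------------------------------------
# scenario directories


def write_scenario(scenario: Scenario, out_dir: str | Path) -> None:
    """Write stations.csv, demand.csv, observed.csv and provenance.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_points(scenario.stations, out / "stations.csv")
    write_points(scenario.demand_points, out / "demand.csv")
    pd.DataFrame(
        {
            "station_id": list(scenario.observed_cases),
            "observed": list(scenario.observed_cases.values()),
        }
    ).to_csv(out / "observed.csv", index=False)
    prov: dict = {"uncaptured_cases": scenario.uncaptured_cases}
    if scenario.generating_spec is not None:
        prov["generating_spec"] = spec_to_dict(scenario.generating_spec)
    with open(out / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(prov, fh, indent=2)
        fh.write("\n")


def read_scenario(in_dir: str | Path) -> Scenario:
    """Load a scenario directory written by :func:`write_scenario`."""
    d = Path(in_dir)
    stations = read_points(d / "stations.csv", "station")
    demand = read_points(d / "demand.csv", "demand")
    obs = pd.read_csv(d / "observed.csv")
    observed = dict(zip(obs["station_id"].astype(str), obs["observed"].astype(int)))
    spec = None
    uncaptured: dict[str, int] = {}
    prov_path = d / "provenance.json"
    if prov_path.exists():
        with open(prov_path, encoding="utf-8") as fh:
            prov = json.load(fh)
        uncaptured = {str(k): int(v) for k, v in prov.get("uncaptured_cases", {}).items()}
        if "generating_spec" in prov:
            spec = ScenarioSpec(**prov["generating_spec"])
    return Scenario(
        stations=stations,
        demand_points=demand,
        observed_cases=observed,
        uncaptured_cases=uncaptured,
        generating_spec=spec,
    )


# ---------------------------------------------------------------------------
# dispatch preprocessing


@dataclass(frozen=True)
class DispatchRecord:
    """One raw dispatch event from an emergency command center export."""

    record_id: str
    station_id: str
    delivery_x: float | None
    delivery_y: float | None
    outcome: Literal["transport", "empty_return", "other"] = "transport"
    timestamp: str = ""


@dataclass
class CleaningReport:
    """Ledger of the dispatch-cleaning pipeline; rules balance exactly."""

    n_input: int = 0
    n_duplicate: int = 0
    n_empty_return: int = 0
    n_missing_coords: int = 0
    n_retained: int = 0

    def balanced(self) -> bool:
        return (
            self.n_input
            == self.n_duplicate + self.n_empty_return + self.n_missing_coords + self.n_retained
        )


def preprocess_dispatches(
    records: Sequence[DispatchRecord],
    demand_points: Sequence[DemandPoint],
    metric: Metric | None = None,
    boundaries: Mapping[str, object] | None = None,
) -> tuple[dict[str, int], dict[str, int], CleaningReport]:
    """Clean dispatch events and aggregate them to stations and demand points.

    Rules, applied in order: duplicates are dropped (same record_id, or same
    station_id + timestamp + coordinates); empty-return events are excluded;
    events with missing coordinates are dropped and counted.  Each retained
    event increments its station's trip count and is assigned to the nearest
    demand centroid (ties go to the lexicographically smaller demand id), or
    — when ``boundaries`` maps demand ids to shapely polygons — to the
    polygon containing it, falling back to nearest centroid outside all
    polygons.

    Returns (per-station trip counts, per-demand-point case counts, report).
    """
    if len(demand_points) == 0:
        raise ValueError("demand point list is empty")
    report = CleaningReport(n_input=len(records))

    seen_ids: set[str] = set()
    seen_keys: set[tuple] = set()
    retained: list[DispatchRecord] = []
    for rec in records:
        key = (rec.station_id, rec.timestamp, rec.delivery_x, rec.delivery_y)
        if rec.record_id in seen_ids or key in seen_keys:
            report.n_duplicate += 1
            continue
        seen_ids.add(rec.record_id)
        seen_keys.add(key)
        if rec.outcome == "empty_return":
            report.n_empty_return += 1
            continue
        if rec.delivery_x is None or rec.delivery_y is None:
            report.n_missing_coords += 1
            continue
        retained.append(rec)
    report.n_retained = len(retained)

    station_counts: dict[str, int] = {}
    demand_counts: dict[str, int] = {p.id: 0 for p in demand_points}
    if not retained:
        return station_counts, demand_counts, report

    if metric is None:
        metric = "haversine" if demand_points[0].point.crs_mode == "geographic" else "euclidean"
    cxy = np.array([(p.point.x, p.point.y) for p in demand_points])
    rxy = np.array([(r.delivery_x, r.delivery_y) for r in retained], dtype=float)
    dist = _pairwise(rxy, cxy, metric)
    ids = [p.id for p in demand_points]

    for k, rec in enumerate(retained):
        station_counts[rec.station_id] = station_counts.get(rec.station_id, 0) + 1
        assigned = None
        if boundaries is not None:
            from shapely.geometry import Point as ShPoint

            pt = ShPoint(rec.delivery_x, rec.delivery_y)
            for did in sorted(boundaries):
                if boundaries[did].contains(pt) or boundaries[did].touches(pt):
                    assigned = did
                    break
        if assigned is None:
            row = dist[k]
            # ties go to the lexicographically smallest demand id
            assigned = min(ids[j] for j in np.flatnonzero(row == row.min()))
        demand_counts[assigned] = demand_counts.get(assigned, 0) + 1

    return station_counts, demand_counts, report


def dispatches_from_csv(path: str | Path) -> list[DispatchRecord]:
    """Read dispatch records from a CSV with the DispatchRecord columns."""
    df = pd.read_csv(path)
    recs = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        x = d.get("delivery_x")
        y = d.get("delivery_y")
        recs.append(
            DispatchRecord(
                record_id=str(d["record_id"]),
                station_id=str(d["station_id"]),
                delivery_x=None if pd.isna(x) else float(x),
                delivery_y=None if pd.isna(y) else float(y),
                outcome=str(d.get("outcome", "transport")),
                timestamp=str(d.get("timestamp", "")),
            )
        )
    return recs


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Defaults for a full run; config-file values override these, CLI flags
    override both."""

    model: str = "gp"
    lam: float = 2.4
    d0_main: float = 5.0
    d0_nonmain: float = 15.0
    attribution: str = "demand_zone"
    prob_scope: str = "within_threshold"
    epsilon_km: float = 0.001
    metric: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def load(cls, config_path: str | Path | None = None, **overrides) -> "RunConfig":
        """Build a config with precedence CLI override > file > default."""
        values: dict = {}
        if config_path is not None:
            with open(config_path, encoding="utf-8") as fh:
                data = yaml.safe_load(fh) or {}
            known = {f.name for f in fields(cls)}
            unknown = set(data) - known
            if unknown:
                raise ValueError(f"unknown config keys: {sorted(unknown)}")
            values.update(data)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)
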