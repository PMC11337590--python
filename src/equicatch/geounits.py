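"""Domain types and readers/writers for small-area units, resources,
unit geometries, and unit-by-resource travel-cost matrices.

Conventions
-----------
* Deprivation decile: 1 = most deprived tenth of units within a nation.
  Inputs using the reverse orientation must be flipped by the caller;
  nothing here guesses.
* Coordinates are WGS84 longitude/latitude in decimal degrees. Unit
  location is the supplied centroid; population-weighted centroids are
  recommended where available.
* ``area_km2`` is always taken from the attribute table, never recomputed
  from polygons, so analyses run without geometries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .errors import SchemaError, ValidationError

UNIT_COLUMNS = ["unit_id", "nation", "lon", "lat", "population", "area_km2", "imd_decile"]
RESOURCE_COLUMNS = ["resource_id", "base_id", "name", "nation", "lon", "lat"]


@dataclass(frozen=True)
class AreaUnit:
    """One small-area geography unit (e.g. an LSOA-like census unit)."""

    unit_id: str
    nation: str
    lon: float
    lat: float
    population: float
    area_km2: float
    imd_decile: int


@dataclass(frozen=True)
class Resource:
    """One operational team at a base location.

    Two resources may share a ``base_id`` (co-located teams); they must
    then share identical coordinates.
    """

    resource_id: str
    base_id: str
    name: str
    nation: str
    lon: float
    lat: float


@dataclass(frozen=True)
class UnitGeometry:
    """Polygon footprint of one unit, WGS84 coordinates."""

    unit_id: str
    polygon: BaseGeometry


class CostMatrix:
    """Dense unit-by-resource travel-cost table.

    Wraps a :class:`pandas.DataFrame` indexed by ``unit_id`` with one
    column per ``resource_id``. ``units`` declares the cost units
    ("km" or "minutes"). All cells must be finite and non-negative.
    """

    def __init__(self, table: pd.DataFrame, units: str = "km"):
        bad = table.apply(pd.to_numeric, errors="coerce")
        nan_mask = bad.isna()
        if nan_mask.to_numpy().any():
            r, c = next(zip(*nan_mask.to_numpy().nonzero()))
            raise ValidationError(
                f"non-numeric cost at unit {table.index[r]!r}, resource {table.columns[c]!r}"
            )
        neg_mask = bad < 0
        if neg_mask.to_numpy().any():
            r, c = next(zip(*neg_mask.to_numpy().nonzero()))
            raise ValidationError(
                f"negative cost at unit {table.index[r]!r}, resource {table.columns[c]!r}"
            )
        self.table = bad.astype(float)
        self.units = units

    def cost(self, unit_id: str, resource_id: str) -> float:
        try:
            return float(self.table.at[unit_id, resource_id])
        except KeyError:
            raise ValidationError(
                f"cost matrix has no cell for unit {unit_id!r}, resource {resource_id!r}"
            ) from None

    @property
    def unit_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def resource_ids(self) -> list[str]:
        return list(self.table.columns)


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table missing column(s): {', '.join(missing)}")


def _validate_coords(lon: float, lat: float, context: str) -> None:
    if not (-180.0 <= lon <= 180.0):
        raise ValidationError(f"{context}: longitude {lon} outside [-180, 180]")
    if not (-90.0 <= lat <= 90.0):
        raise ValidationError(f"{context}: latitude {lat} outside [-90, 90]")


def validate_unit(u: AreaUnit, row: int | None = None) -> None:
    where = f"unit {u.unit_id!r}" + (f" (row {row})" if row is not None else "")
    if not (1 <= u.imd_decile <= 10):
        raise ValidationError(f"{where}: imd_decile {u.imd_decile} outside 1..10")
    if u.population < 0:
        raise ValidationError(f"{where}: negative population {u.population}")
    if not u.area_km2 > 0:
        raise ValidationError(f"{where}: non-positive area_km2 {u.area_km2}")
    _validate_coords(u.lon, u.lat, where)


def read_units(path: str | Path) -> list[AreaUnit]:
    """Read an area-unit CSV (columns ``unit_id,nation,lon,lat,population,area_km2,imd_decile``)."""
    df = pd.read_csv(path, dtype={"unit_id": str, "nation": str}, float_precision="round_trip")
    _require_columns(df, UNIT_COLUMNS, "units")
    seen: set[str] = set()
    units: list[AreaUnit] = []
    for i, rec in enumerate(df.itertuples(index=False)):
        u = AreaUnit(
            unit_id=str(rec.unit_id),
            nation=str(rec.nation),
            lon=float(rec.lon),
            lat=float(rec.lat),
            population=float(rec.population),
            area_km2=float(rec.area_km2),
            imd_decile=int(rec.imd_decile),
        )
        if u.unit_id in seen:
            raise ValidationError(f"duplicate unit_id {u.unit_id!r} (row {i})")
        seen.add(u.unit_id)
        validate_unit(u, row=i)
        units.append(u)
    return units


def write_units(units: Iterable[AreaUnit], path: str | Path) -> None:
    df = pd.DataFrame([u.__dict__ for u in units], columns=UNIT_COLUMNS)
    df.to_csv(path, index=False)


def read_resources(path: str | Path) -> list[Resource]:
    """Read a resource CSV (columns ``resource_id,base_id,name,nation,lon,lat``)."""
    df = pd.read_csv(
        path,
        dtype={"resource_id": str, "base_id": str, "name": str, "nation": str},
        float_precision="round_trip",
    )
    _require_columns(df, RESOURCE_COLUMNS, "resources")
    seen: set[str] = set()
    out: list[Resource] = []
    for i, rec in enumerate(df.itertuples(index=False)):
        r = Resource(
            resource_id=str(rec.resource_id),
            base_id=str(rec.base_id),
            name=str(rec.name),
            nation=str(rec.nation),
            lon=float(rec.lon),
            lat=float(rec.lat),
        )
        if r.resource_id in seen:
            raise ValidationError(f"duplicate resource_id {r.resource_id!r} (row {i})")
        seen.add(r.resource_id)
        _validate_coords(r.lon, r.lat, f"resource {r.resource_id!r}")
        out.append(r)
    _check_colocated(out)
    return out


def _check_colocated(resources: Sequence[Resource]) -> None:
    by_base: dict[str, list[Resource]] = {}
    for r in resources:
        by_base.setdefault(r.base_id, []).append(r)
    for base_id, group in by_base.items():
        coords = {(r.lon, r.lat) for r in group}
        if len(coords) > 1:
            raise ValidationError(
                f"resources sharing base_id {base_id!r} have differing coordinates"
            )


def write_resources(resources: Iterable[Resource], path: str | Path) -> None:
    df = pd.DataFrame([r.__dict__ for r in resources], columns=RESOURCE_COLUMNS)
    df.to_csv(path, index=False)


def read_cost_matrix(path: str | Path, units: str = "km") -> CostMatrix:
    """Read a cost-matrix CSV: first column ``unit_id``, one column per resource_id."""
    df = pd.read_csv(path, dtype={"unit_id": str}, float_precision="round_trip")
    if "unit_id" not in df.columns:
        raise SchemaError("cost matrix missing column: unit_id")
    if df.shape[1] < 2:
        raise SchemaError("cost matrix has no resource columns")
    df = df.set_index("unit_id")
    return CostMatrix(df, units=units)


def write_cost_matrix(matrix: CostMatrix, path: str | Path) -> None:
    matrix.table.to_csv(path, index_label="unit_id")


def read_geometries(path: str | Path) -> list[UnitGeometry]:
    """Read unit polygons from a GeoJSON FeatureCollection (property ``unit_id``)."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise SchemaError("geometry file is not a GeoJSON FeatureCollection")
    geoms: list[UnitGeometry] = []
    for i, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        if "unit_id" not in props:
            raise SchemaError(f"feature {i} missing property 'unit_id'")
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            raise ValidationError(f"invalid polygon for unit {props['unit_id']!r}")
        geoms.append(UnitGeometry(unit_id=str(props["unit_id"]), polygon=geom))
    return geoms


def write_geometries(geoms: Iterable[UnitGeometry], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"unit_id": g.unit_id},
            "geometry": mapping(g.polygon),
        }
        for g in geoms
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
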