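"""Modelled service areas: assign each unit to its nearest eligible resource.

The default distance is the great-circle (haversine) distance between the
unit centroid and the resource base. A precomputed :class:`CostMatrix`
(road distance or travel time) can be supplied instead. Assignment is
constrained within nation by default, reflecting nationally delivered
emergency services; the constraint can be relaxed for sensitivity runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError
from .geounits import AreaUnit, CostMatrix, Resource, UnitGeometry

EARTH_RADIUS_KM = 6371.0


@dataclass
class Assignment:
    """Total mapping unit_id -> resource_id, with the realised cost per unit.

    ``metric_tag`` records the distance source: ``"greatcircle"`` or
    ``"matrix:<units>"``.
    """

    mapping: dict[str, str]
    metric_tag: str
    costs: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, unit_id: str) -> str:
        return self.mapping[unit_id]

    def __len__(self) -> int:
        return len(self.mapping)


def greatcircle_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Haversine distance in km on a sphere of radius 6371.0 km."""
    for lon, lat in ((lon1, lat1), (lon2, lat2)):
        if not (-180.0 <= lon <= 180.0):
            raise ValidationError(f"longitude {lon} outside [-180, 180]")
        if not (-90.0 <= lat <= 90.0):
            raise ValidationError(f"latitude {lat} outside [-90, 90]")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def _greatcircle_matrix(units: Sequence[AreaUnit], resources: Sequence[Resource]) -> np.ndarray:
    """Vectorised haversine, shape (n_units, n_resources)."""
    ulon = np.radians([u.lon for u in units])[:, None]
    ulat = np.radians([u.lat for u in units])[:, None]
    rlon = np.radians([r.lon for r in resources])[None, :]
    rlat = np.radians([r.lat for r in resources])[None, :]
    a = (
        np.sin((rlat - ulat) / 2.0) ** 2
        + np.cos(ulat) * np.cos(rlat) * np.sin((rlon - ulon) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def assign_units(
    units: Sequence[AreaUnit],
    resources: Sequence[Resource],
    cost: CostMatrix | None = None,
    within_nation: bool = True,
) -> Assignment:
    """Map every unit to its minimum-cost eligible resource.

    Ties (including co-located resources, which tie exactly) are broken by
    lexicographically smallest ``resource_id`` so runs are reproducible.
    """
    if not resources:
        raise ConfigurationError("no resources supplied")
    if within_nation:
        resource_nations = {r.nation for r in resources}
        for nation in {u.nation for u in units}:
            if nation not in resource_nations:
                raise ConfigurationError(
                    f"nation {nation!r} contains units but no resource; "
                    "cannot assign under the within-nation constraint"
                )

    # Sorting by resource_id makes argmin's first-minimum the lexicographic tie-break.
    res_sorted = sorted(resources, key=lambda r: r.resource_id)
    if cost is None:
        dist = _greatcircle_matrix(units, res_sorted)
        metric_tag = "greatcircle"
    else:
        try:
            dist = (
                cost.table.loc[[u.unit_id for u in units], [r.resource_id for r in res_sorted]]
                .to_numpy(dtype=float)
            )
        except KeyError as exc:
            raise ValidationError(f"cost matrix missing entry: {exc}") from None
        if np.isnan(dist).any():
            i, j = np.argwhere(np.isnan(dist))[0]
            raise ValidationError(
                f"cost matrix missing cell for unit {units[i].unit_id!r}, "
                f"resource {res_sorted[j].resource_id!r}"
            )
        metric_tag = f"matrix:{cost.units}"

    if within_nation:
        unit_nations = np.array([u.nation for u in units])
        res_nations = np.array([r.nation for r in res_sorted])
        ineligible = unit_nations[:, None] != res_nations[None, :]
        dist = np.where(ineligible, np.inf, dist)

    best = np.argmin(dist, axis=1)
    mapping: dict[str, str] = {}
    costs: dict[str, float] = {}
    for i, u in enumerate(units):
        j = int(best[i])
        mapping[u.unit_id] = res_sorted[j].resource_id
        costs[u.unit_id] = float(dist[i, j])
    return Assignment(mapping=mapping, metric_tag=metric_tag, costs=costs)


def catchment_polygons(
    assignment: Assignment, geoms: Sequence[UnitGeometry]
) -> list[tuple[str, object]]:
    """Dissolve unit polygons into one (multi)polygon per assigned resource.

    Returns ``(resource_id, polygon)`` pairs sorted by resource_id.
    """
    from shapely.ops import unary_union

    geom_by_unit = {g.unit_id: g.polygon for g in geoms}
    missing = [uid for uid in assignment.mapping if uid not in geom_by_unit]
    if missing:
        raise ValidationError(f"units without geometry: {', '.join(sorted(missing))}")
    by_resource: dict[str, list] = {}
    for unit_id, resource_id in assignment.mapping.items():
        by_resource.setdefault(resource_id, []).append(geom_by_unit[unit_id])
    return [(rid, unary_union(polys)) for rid, polys in sorted(by_resource.items())]
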