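"""Collapse assigned units into per-resource service-area summaries.

Each summary row carries the totals entering the equity regression:
total population, total area (km²), and the median deprivation decile of
the units in the catchment.

Co-located resources (two teams sharing one base) tie exactly under
nearest assignment, so the assignment stage hands their joint catchment
to one of them. ``summarize`` rebuilds one analysis row per *resource*:

* ``"split"`` (default): the shared catchment's population and area are
  divided equally between the co-located resources; the median decile is
  identical for both. National totals are conserved.
* ``"share"``: both resources carry the full catchment totals and are
  flagged ``shared=True``; national totals are then double-counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catchment import Assignment
from .errors import ConfigurationError, ValidationError
from .geounits import AreaUnit, Resource

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "resource_id",
    "n_units",
    "total_population",
    "total_area_km2",
    "median_decile",
    "shared",
]


@dataclass(frozen=True)
class ServiceAreaSummary:
    resource_id: str
    n_units: int
    total_population: float
    total_area_km2: float
    median_decile: float
    shared: bool = False


def _median_decile(deciles: Sequence[int], populations: Sequence[float], weighted: bool) -> float:
    if not weighted:
        return float(np.median(deciles))
    order = np.argsort(deciles, kind="stable")
    d = np.asarray(deciles, dtype=float)[order]
    w = np.asarray(populations, dtype=float)[order]
    cum = np.cumsum(w)
    if cum[-1] <= 0:
        return float(np.median(deciles))
    return float(d[np.searchsorted(cum, cum[-1] / 2.0)])


def summarize(
    units: Sequence[AreaUnit],
    assignment: Assignment,
    resources: Sequence[Resource],
    colocated_strategy: str = "split",
    weighted_median: bool = False,
) -> list[ServiceAreaSummary]:
    """One :class:`ServiceAreaSummary` per resource serving at least one unit.

    ``colocated_strategy`` governs bases hosting more than one resource
    (see module docstring); it must be ``"split"`` or ``"share"``.
    Resources whose base serves zero units are excluded with a warning.
    """
    if colocated_strategy not in ("split", "share"):
        raise ConfigurationError(
            f"colocated_strategy must be 'split' or 'share', got {colocated_strategy!r}"
        )
    unit_by_id = {u.unit_id: u for u in units}
    missing = [uid for uid in (u.unit_id for u in units) if uid not in assignment.mapping]
    if missing:
        raise ValidationError(f"assignment does not cover unit(s): {', '.join(missing[:5])}")
    known_resources = {r.resource_id for r in resources}
    for uid, rid in assignment.mapping.items():
        if rid not in known_resources:
            raise ValidationError(f"assignment maps unit {uid!r} to unknown resource {rid!r}")

    catchment: dict[str, list[AreaUnit]] = {r.resource_id: [] for r in resources}
    for uid, rid in assignment.mapping.items():
        if uid in unit_by_id:
            catchment[rid].append(unit_by_id[uid])

    by_base: dict[str, list[Resource]] = {}
    for r in resources:
        by_base.setdefault(r.base_id, []).append(r)

    summaries: list[ServiceAreaSummary] = []
    for base_id in sorted(by_base):
        group = sorted(by_base[base_id], key=lambda r: r.resource_id)
        base_units = [u for r in group for u in catchment[r.resource_id]]
        if not base_units:
            for r in group:
                logger.warning("resource %s serves zero units; excluded", r.resource_id)
            continue
        pop = float(sum(u.population for u in base_units))
        area = float(sum(u.area_km2 for u in base_units))
        med = _median_decile(
            [u.imd_decile for u in base_units],
            [u.population for u in base_units],
            weighted_median,
        )
        k = len(group)
        for r in group:
            if k == 1:
                summaries.append(
                    ServiceAreaSummary(r.resource_id, len(base_units), pop, area, med)
                )
            elif colocated_strategy == "split":
                summaries.append(
                    ServiceAreaSummary(
                        r.resource_id, len(base_units), pop / k, area / k, med, shared=True
                    )
                )
            else:  # share
                summaries.append(
                    ServiceAreaSummary(r.resource_id, len(base_units), pop, area, med, shared=True)
                )
    summaries.sort(key=lambda s: s.resource_id)
    return summaries


def summary_stats(summaries: Sequence[ServiceAreaSummary]) -> dict:
    """Median and range of catchment population and area, plus the row count."""
    if not summaries:
        raise ValidationError("summary_stats requires at least one summary")
    pops = np.array([s.total_population for s in summaries], dtype=float)
    areas = np.array([s.total_area_km2 for s in summaries], dtype=float)
    return {
        "n": len(summaries),
        "population": {
            "median": float(np.median(pops)),
            "min": float(pops.min()),
            "max": float(pops.max()),
        },
        "area_km2": {
            "median": float(np.median(areas)),
            "min": float(areas.min()),
            "max": float(areas.max()),
        },
    }


def write_summaries(summaries: Iterable[ServiceAreaSummary], path: str | Path) -> None:
    df = pd.DataFrame([s.__dict__ for s in summaries], columns=SUMMARY_COLUMNS)
    df.to_csv(path, index=False)


def read_summaries(path: str | Path) -> list[ServiceAreaSummary]:
    df = pd.read_csv(path, dtype={"resource_id": str})
    required = [c for c in SUMMARY_COLUMNS if c != "shared"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"summaries table missing column(s): {', '.join(missing)}")
    if "shared" not in df.columns:
        df["shared"] = False
    return [
        ServiceAreaSummary(
            resource_id=str(rec.resource_id),
            n_units=int(rec.n_units),
            total_population=float(rec.total_population),
            total_area_km2=float(rec.total_area_km2),
            median_decile=float(rec.median_decile),
            shared=bool(rec.shared),
        )
        for rec in df.itertuples(index=False)
    ]
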