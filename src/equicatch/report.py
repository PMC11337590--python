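"""Pipeline orchestration, bivariate classification, machine-readable outputs.

``run_pipeline`` chains assign → summarize → regress (univariate and
multivariate) → Spearman sensitivity → bivariate classification, writing
``assignment.csv``, ``summaries.csv``, ``result.json``, ``classes.csv``
and, when geometries are supplied, ``catchments.geojson``. Logging goes
to standard error; machine outputs go to files only. Reruns with the
same inputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregate import ServiceAreaSummary, summarize, summary_stats, write_summaries
from .catchment import assign_units, catchment_polygons
from .equity_stats import coef_to_percent, fit_loglinear, spearman
from .errors import ConfigurationError, EquicatchError, ValidationError
from .geounits import (
    read_cost_matrix,
    read_geometries,
    read_resources,
    read_units,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BivariateClass:
    resource_id: str
    pop_tercile: int
    depr_tercile: int

    @property
    def class_code(self) -> str:
        return f"T{self.pop_tercile}D{self.depr_tercile}"


def _terciles(values: Sequence[float]) -> np.ndarray:
    """Rank-based terciles, 1..3; ties take the lower class.

    Tied values share the tercile of their lowest rank, so identical
    inputs all land in tercile 1 and margin counts for distinct values
    differ by at most one.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    order = np.argsort(v, kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    # min rank among ties
    min_rank = {}
    for i in order:
        min_rank.setdefault(v[i], rank[i])
    return np.array([min_rank[x] * 3 // n + 1 for x in v], dtype=int)


def classify_bivariate(summaries: Sequence[ServiceAreaSummary]) -> list[BivariateClass]:
    """Cross-classify catchments by population and deprivation terciles."""
    if len(summaries) < 3:
        raise ValidationError(f"need at least 3 summaries to form terciles, got {len(summaries)}")
    pop_t = _terciles([s.total_population for s in summaries])
    dep_t = _terciles([s.median_decile for s in summaries])
    return [
        BivariateClass(s.resource_id, int(pt), int(dt))
        for s, pt, dt in zip(summaries, pop_t, dep_t)
    ]


def write_classes(classes: Sequence[BivariateClass], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "resource_id": c.resource_id,
                "pop_tercile": c.pop_tercile,
                "depr_tercile": c.depr_tercile,
                "class_code": c.class_code,
            }
            for c in classes
        ]
    )
    df.to_csv(path, index=False)


@dataclass
class RunConfig:
    units: str
    resources: str
    outdir: str
    cost_matrix: str | None = None
    geometries: str | None = None
    within_nation: bool = True
    colocated_strategy: str = "split"
    cost_units: str = "km"
    weighted_median: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        for key in ("units", "resources", "outdir"):
            if key not in raw:
                raise ConfigurationError(f"config missing required key {key!r}")
        return cls(**raw)

    def validate_paths(self) -> None:
        for key in ("units", "resources", "cost_matrix", "geometries"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{key} path does not exist: {p}")


def _regression_block(summaries, predictors):
    res = fit_loglinear(summaries, predictors)
    block = res.to_dict()
    block["percent_change"] = {}
    for name in predictors:
        pc = coef_to_percent(res, name)
        block["percent_change"][name] = {
            "percent": pc.percent,
            "ci_low_pct": pc.ci_low_pct,
            "ci_high_pct": pc.ci_high_pct,
            "rounded": list(pc.rounded),
        }
    return block, res


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a run report of stages and outputs."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    outputs: dict[str, str] = {}

    def _stage(name):
        def wrap(fn, *a, **kw):
            try:
                return fn(*a, **kw)
            except EquicatchError as exc:
                raise type(exc)(f"[{name}] {exc}") from exc

        return wrap

    units = _stage("read")(read_units, config.units)
    resources = _stage("read")(read_resources, config.resources)
    cost = (
        _stage("read")(read_cost_matrix, config.cost_matrix, config.cost_units)
        if config.cost_matrix
        else None
    )
    logger.info("read %d units, %d resources", len(units), len(resources))

    assignment = _stage("assign")(
        assign_units, units, resources, cost=cost, within_nation=config.within_nation
    )
    adf = pd.DataFrame(
        {
            "unit_id": list(assignment.mapping),
            "resource_id": [assignment.mapping[u] for u in assignment.mapping],
            "cost": [assignment.costs[u] for u in assignment.mapping],
        }
    )
    adf.to_csv(outdir / "assignment.csv", index=False)
    outputs["assignment"] = str(outdir / "assignment.csv")
    stages.append("assign")

    summaries = _stage("summarize")(
        summarize,
        units,
        assignment,
        resources,
        colocated_strategy=config.colocated_strategy,
        weighted_median=config.weighted_median,
    )
    write_summaries(summaries, outdir / "summaries.csv")
    outputs["summaries"] = str(outdir / "summaries.csv")
    stages.append("summarize")

    uni, _ = _stage("regress")(_regression_block, summaries, ["median_decile"])
    uni_area, _ = _stage("regress")(_regression_block, summaries, ["log_area"])
    multi, _ = _stage("regress")(_regression_block, summaries, ["median_decile", "log_area"])
    stages.append("regress")

    sp_dec = _stage("spearman")(
        spearman,
        [s.median_decile for s in summaries],
        [s.total_population for s in summaries],
    )
    sp_area = _stage("spearman")(
        spearman,
        [s.total_area_km2 for s in summaries],
        [s.total_population for s in summaries],
    )
    stages.append("spearman")

    classes = _stage("classify")(classify_bivariate, summaries)
    write_classes(classes, outdir / "classes.csv")
    outputs["classes"] = str(outdir / "classes.csv")
    stages.append("classify")

    result = {
        "version": __version__,
        "config": {
            "within_nation": config.within_nation,
            "colocated_strategy": config.colocated_strategy,
            "metric_tag": assignment.metric_tag,
            "weighted_median": config.weighted_median,
        },
        "n_units": len(units),
        "n_resources": len(resources),
        "summary_stats": summary_stats(summaries),
        "univariate_median_decile": uni,
        "univariate_log_area": uni_area,
        "multivariate": multi,
        "spearman": {
            "median_decile_vs_population": sp_dec.__dict__,
            "area_vs_population": sp_area.__dict__,
        },
    }
    with open(outdir / "result.json", "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)
    outputs["result"] = str(outdir / "result.json")

    if config.geometries:
        geoms = _stage("read")(read_geometries, config.geometries)
        polys = _stage("dissolve")(catchment_polygons, assignment, geoms)
        from shapely.geometry import mapping as shp_mapping

        features = [
            {
                "type": "Feature",
                "properties": {"resource_id": rid},
                "geometry": shp_mapping(poly),
            }
            for rid, poly in polys
        ]
        with open(outdir / "catchments.geojson", "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)
        outputs["catchments"] = str(outdir / "catchments.geojson")
        stages.append("dissolve")

    log_lines = [f"equicatch {__version__}", f"stages completed: {', '.join(stages)}"]
    for k, v in outputs.items():
        log_lines.append(f"output {k}: {v}")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    logger.info("pipeline complete: %d stages", len(stages))
    return {"stages": stages, "outputs": outputs, "n_rows": len(summaries)}
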