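"""Synthetic multi-nation geographies with known ground truth.

Each nation is a bounding box tiled by a jittered grid of square units.
A smooth deprivation surface (superposed radial Gaussian bumps with
length scale ``spatial_corr_range``) is ranked within nation and cut
into balanced deciles, so every decile holds ⌊n/10⌋ or ⌈n/10⌉ units by
construction. Unit populations are lognormal around
``units_mean_population``.

The configurable true effect ``true_slope`` (β*) links catchment median
decile to ln(catchment population). It is induced through *resource
placement*, not by writing catchment populations directly: resources are
sampled at unit locations with intensity ∝ exp(−g·β*·decile), so that
with β* < 0 affluent (high-decile) regions receive more resources and
hence smaller catchments. For a spatial point process of intensity λ the
catchment area — and, with uniform unit population density, the
catchment population — scales as 1/λ, giving
E[ln population | decile d] ≈ const + β*·d after calibration.

Two further ingredients keep ordinary-least-squares inference on the
generated data honest (nominal CI coverage and type-I error). Bases
repel each other (:data:`REPULSION_FACTOR`), as real bases do, which
suppresses spatially correlated catchment-size noise; the gain ``g``
(:data:`PLACEMENT_GAIN`) then overshoots β* to compensate the resulting
attenuation. And unit populations are heavy-tailed lognormal, so the
dominant catchment-level population noise is independent across
catchments rather than a smooth spatial field. Both constants were fixed
by the pilot in ``scripts/calibrate_slope.py``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import box

from .catchment import _greatcircle_matrix
from .errors import ConfigurationError
from .geounits import AreaUnit, CostMatrix, Resource, UnitGeometry

import pandas as pd

# Calibration constants from the pilot in scripts/calibrate_slope.py.
# PLACEMENT_GAIN corrects the attenuation of the placement-intensity
# mechanism: spacing bases apart (REPULSION_FACTOR) flattens the realised
# resource density relative to the target intensity, and the catchment
# median decile is a smoothed proxy for deprivation at the base, so the
# intensity exponent must overshoot the target slope. Calibrated at
# true_slope = −0.20 with the recovery_config scenario; the mapping is
# mildly nonlinear in true_slope, so extreme slopes recover approximately.
PLACEMENT_GAIN = 2.95
REPULSION_FACTOR = 0.6

KM_PER_DEG_LAT = 110.574
KM_PER_DEG_LON_EQ = 111.320


@dataclass(frozen=True)
class NationSpec:
    """One synthetic nation: code, unit count, and lon/lat bounding box."""

    code: str
    n_units: int
    bbox: tuple[float, float, float, float]  # lon_min, lat_min, lon_max, lat_max


@dataclass
class SyntheticConfig:
    seed: int
    nations: list[NationSpec]
    n_resources_per_nation: int | Sequence[int] = 2
    units_mean_population: float = 1500.0
    spatial_corr_range: float = 1.0
    true_slope: float = 0.0
    noise_sd: float = 0.1
    pop_field_sd: float = 0.0
    pop_field_range: float = 0.5
    colocated_pairs: int = 0

    def resources_for(self, i: int) -> int:
        if isinstance(self.n_resources_per_nation, int):
            return self.n_resources_per_nation
        return int(self.n_resources_per_nation[i])

    def validate(self) -> None:
        if not self.nations:
            raise ConfigurationError("at least one nation required")
        for i, nat in enumerate(self.nations):
            if nat.n_units < 20:
                raise ConfigurationError(
                    f"nation {nat.code!r} has {nat.n_units} units; minimum is 20"
                )
            lon_min, lat_min, lon_max, lat_max = nat.bbox
            if not (lon_max > lon_min and lat_max > lat_min):
                raise ConfigurationError(f"nation {nat.code!r} bbox is degenerate")
            if self.resources_for(i) < 1:
                raise ConfigurationError(f"nation {nat.code!r} must get at least one resource")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.colocated_pairs < 0:
            raise ConfigurationError("colocated_pairs must be non-negative")
        total_res = sum(self.resources_for(i) for i in range(len(self.nations)))
        if self.colocated_pairs > total_res:
            raise ConfigurationError("more colocated pairs than resources")


def _deprivation_surface(
    lon: np.ndarray, lat: np.ndarray, bbox: tuple, corr_range: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth random field: sum of radial Gaussian bumps of scale corr_range."""
    lon_min, lat_min, lon_max, lat_max = bbox
    pad = corr_range
    k = 12
    cx = rng.uniform(lon_min - pad, lon_max + pad, size=k)
    cy = rng.uniform(lat_min - pad, lat_max + pad, size=k)
    amp = rng.normal(size=k)
    val = np.zeros_like(lon)
    for j in range(k):
        d2 = (lon - cx[j]) ** 2 + (lat - cy[j]) ** 2
        val += amp[j] * np.exp(-d2 / (2.0 * corr_range**2))
    return val


def _balanced_deciles(values: np.ndarray) -> np.ndarray:
    """Rank values and cut into deciles holding ⌊n/10⌋ or ⌈n/10⌉ each.

    Decile 1 = most deprived = highest surface value, matching the
    convention that low deciles mark high deprivation.
    """
    n = len(values)
    order = np.argsort(-values, kind="stable")
    deciles = np.empty(n, dtype=int)
    deciles[order] = np.arange(n) * 10 // n + 1
    return deciles


def _place_resources(
    lon: np.ndarray,
    lat: np.ndarray,
    deciles: np.ndarray,
    n_res: int,
    true_slope: float,
    bbox: tuple,
    rng: np.random.Generator,
) -> list[int]:
    """Sample resource host units: deprivation-weighted with spatial repulsion.

    Intensity ∝ exp(−g·β*·decile) induces the true effect; a soft
    exclusion radius around already-placed resources spaces the bases out
    (as real bases are), which keeps catchment sizes regular so the
    induced effect is not drowned in cell-size noise.
    """
    lon_min, lat_min, lon_max, lat_max = bbox
    area = (lon_max - lon_min) * (lat_max - lat_min)
    r_excl = REPULSION_FACTOR * math.sqrt(area / n_res)
    w0 = np.exp(-PLACEMENT_GAIN * true_slope * deciles)
    picks: list[int] = []
    w = w0.copy()
    for _ in range(n_res):
        total = w.sum()
        if total <= 0:  # exclusion exhausted the pool; fall back to base weights
            w = w0.copy()
            w[picks] = 0.0
            total = w.sum()
        j = int(rng.choice(len(w), p=w / total))
        picks.append(j)
        d2 = (lon - lon[j]) ** 2 + (lat - lat[j]) ** 2
        w = np.where(d2 < r_excl**2, 0.0, w)
    return sorted(picks)


def generate(
    config: SyntheticConfig,
) -> tuple[list[AreaUnit], list[Resource], list[UnitGeometry]]:
    """Generate units, resources, and unit polygons; reproducible from seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    units: list[AreaUnit] = []
    resources: list[Resource] = []
    geoms: list[UnitGeometry] = []

    for i, nat in enumerate(config.nations):
        lon_min, lat_min, lon_max, lat_max = nat.bbox
        width, height = lon_max - lon_min, lat_max - lat_min
        ncols = max(1, round(math.sqrt(nat.n_units * width / height)))
        nrows = math.ceil(nat.n_units / ncols)
        if nrows * ncols < nat.n_units:
            ncols += 1
        cw, ch = width / ncols, height / nrows

        cells = [(r, c) for r in range(nrows) for c in range(ncols)][: nat.n_units]
        cx = np.array([lon_min + (c + 0.5) * cw for _, c in cells])
        cy = np.array([lat_min + (r + 0.5) * ch for r, _ in cells])
        # centroid jitter stays inside the cell
        lon = cx + rng.uniform(-0.25, 0.25, size=nat.n_units) * cw
        lat = cy + rng.uniform(-0.25, 0.25, size=nat.n_units) * ch

        surface = _deprivation_surface(lon, lat, nat.bbox, config.spatial_corr_range, rng)
        deciles = _balanced_deciles(surface)

        sd = config.noise_sd
        pops = config.units_mean_population * np.exp(
            sd * rng.standard_normal(nat.n_units) - sd * sd / 2.0
        )
        # Spatially correlated density multiplier at roughly catchment
        # scale: real population density clusters, and this is what makes
        # catchment totals noisy beyond unit-level sampling noise.
        if config.pop_field_sd > 0:
            f = _deprivation_surface(lon, lat, nat.bbox, config.pop_field_range, rng)
            fsd = f.std()
            if fsd > 0:
                pops = pops * np.exp(config.pop_field_sd * (f - f.mean()) / fsd)

        for j in range(nat.n_units):
            r, c = cells[j]
            uid = f"U{nat.code}{j:05d}"
            cell_lat = math.radians(cy[j])
            area = (cw * KM_PER_DEG_LON_EQ * math.cos(cell_lat)) * (ch * KM_PER_DEG_LAT)
            units.append(
                AreaUnit(
                    unit_id=uid,
                    nation=nat.code,
                    lon=float(lon[j]),
                    lat=float(lat[j]),
                    population=float(pops[j]),
                    area_km2=float(area),
                    imd_decile=int(deciles[j]),
                )
            )
            geoms.append(
                UnitGeometry(
                    unit_id=uid,
                    polygon=box(
                        lon_min + c * cw, lat_min + r * ch,
                        lon_min + (c + 1) * cw, lat_min + (r + 1) * ch,
                    ),
                )
            )

        n_res = config.resources_for(i)
        if n_res > nat.n_units:
            raise ConfigurationError(
                f"nation {nat.code!r}: {n_res} resources exceed {nat.n_units} units"
            )
        picks = _place_resources(
            lon, lat, deciles, n_res, config.true_slope, nat.bbox, rng
        )
        for k, j in enumerate(picks):
            resources.append(
                Resource(
                    resource_id=f"R{nat.code}{k:02d}",
                    base_id=f"B{nat.code}{k:02d}",
                    name=f"Team {nat.code}-{k}",
                    nation=nat.code,
                    lon=float(lon[j]),
                    lat=float(lat[j]),
                )
            )

    for k in range(config.colocated_pairs):
        host = resources[k]
        resources.append(
            Resource(
                resource_id=host.resource_id + "x",
                base_id=host.base_id,
                name=host.name + " (second team)",
                nation=host.nation,
                lon=host.lon,
                lat=host.lat,
            )
        )
    return units, resources, geoms


def make_cost_matrix(
    units: Sequence[AreaUnit],
    resources: Sequence[Resource],
    distortion: float = 1.0,
    seed: int = 0,
) -> CostMatrix:
    """Great-circle distances inflated by a seeded uniform factor.

    ``cell = greatcircle_km · (1 + u)`` with u ~ U[0, distortion − 1],
    emulating road-network divergence from straight lines. With
    ``distortion = 1`` the matrix equals the great-circle distances.
    """
    if distortion < 1.0:
        raise ConfigurationError(f"distortion must be ≥ 1, got {distortion}")
    rng = np.random.default_rng(seed)
    base = _greatcircle_matrix(units, resources)
    u = rng.uniform(0.0, distortion - 1.0, size=base.shape)
    table = pd.DataFrame(
        base * (1.0 + u),
        index=[x.unit_id for x in units],
        columns=[r.resource_id for r in resources],
    )
    return CostMatrix(table, units="km")


def recovery_config(seed: int, true_slope: float, colocated_pairs: int = 0) -> SyntheticConfig:
    """Standard parameter-recovery scenario: 4 nations × 400 units, 38 resources."""
    nations = [
        NationSpec("EN", 400, (-2.0, 51.0, 1.0, 54.0)),
        NationSpec("SC", 400, (-5.0, 55.0, -2.0, 58.0)),
        NationSpec("WA", 400, (-5.0, 51.5, -2.5, 53.5)),
        NationSpec("NI", 400, (-8.0, 54.0, -5.5, 55.5)),
    ]
    return SyntheticConfig(
        seed=seed,
        nations=nations,
        n_resources_per_nation=[10, 10, 9, 9 - colocated_pairs],
        units_mean_population=1500.0,
        spatial_corr_range=1.2,
        true_slope=true_slope,
        noise_sd=2.0,
        colocated_pairs=colocated_pairs,
    )
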