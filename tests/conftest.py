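import pytest

from equicatch.aggregate import ServiceAreaSummary
from equicatch.geounits import AreaUnit, Resource


@pytest.fixture
def small_units():
    return [
        AreaUnit("U001", "EN", -1.0, 52.0, 1000, 2.0, 3),
        AreaUnit("U002", "EN", -1.1, 52.1, 1500, 1.5, 7),
        AreaUnit("U003", "SC", -4.0, 56.0, 900, 3.0, 1),
    ]


@pytest.fixture
def small_resources():
    return [
        Resource("R01", "B01", "Alpha", "EN", -1.05, 52.05),
        Resource("R02", "B02", "Bravo", "SC", -4.1, 56.1),
    ]


def random_units(rng, n, nation="EN", bbox=(-2.0, 51.0, 1.0, 54.0)):
    lon_min, lat_min, lon_max, lat_max = bbox
    return [
        AreaUnit(
            unit_id=f"U{nation}{i:04d}",
            nation=nation,
            lon=float(rng.uniform(lon_min, lon_max)),
            lat=float(rng.uniform(lat_min, lat_max)),
            population=float(rng.integers(100, 5000)),
            area_km2=float(rng.uniform(0.5, 20.0)),
            imd_decile=int(rng.integers(1, 11)),
        )
        for i in range(n)
    ]


def random_resources(rng, n, nation="EN", bbox=(-2.0, 51.0, 1.0, 54.0), start=0):
    lon_min, lat_min, lon_max, lat_max = bbox
    return [
        Resource(
            resource_id=f"R{nation}{start + i:02d}",
            base_id=f"B{nation}{start + i:02d}",
            name=f"Team {start + i}",
            nation=nation,
            lon=float(rng.uniform(lon_min, lon_max)),
            lat=float(rng.uniform(lat_min, lat_max)),
        )
        for i in range(n)
    ]


def random_summaries(rng, n):
    return [
        ServiceAreaSummary(
            resource_id=f"R{i:03d}",
            n_units=int(rng.integers(5, 200)),
            total_population=float(rng.uniform(1e4, 1e7)),
            total_area_km2=float(rng.uniform(100, 30000)),
            median_decile=float(rng.integers(2, 20)) / 2.0,
            shared=False,
        )
        for i in range(n)
    ]
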