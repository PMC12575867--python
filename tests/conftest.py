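import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from forestconverge import ClassScheme, LandCoverRaster

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def two_class_scheme() -> ClassScheme:
    return ClassScheme(codes={"forest": 1, "cropland": 2}, nodata=0)


@pytest.fixture
def toy_pair(two_class_scheme):
    """4-pixel toy: [[F,F],[C,C]] after [[F,F],[F,C]]; flows F->F 2 ha,
    F->C 1 ha, C->C 1 ha by hand enumeration. 1 ha cells."""
    f, c = 1, 2
    a = LandCoverRaster(
        np.array([[f, f], [f, c]]), epoch=2000, cell_area_ha=1.0, scheme=two_class_scheme
    )
    b = LandCoverRaster(
        np.array([[f, f], [c, c]]), epoch=2005, cell_area_ha=1.0, scheme=two_class_scheme
    )
    return a, b


def brute_force_crosstab(map_a, map_b):
    """Independent per-pixel double-loop oracle for transition areas (ha)."""
    flows = {}
    rows, cols = map_a.grid.shape
    for i in range(rows):
        for j in range(cols):
            ca, cb = int(map_a.grid[i, j]), int(map_b.grid[i, j])
            if ca == map_a.scheme.nodata or cb == map_b.scheme.nodata:
                continue
            key = (map_a.scheme.label_of(ca), map_b.scheme.label_of(cb))
            flows[key] = flows.get(key, 0.0) + map_a.cell_area_ha
    return flows


def brute_force_change_areas(map_a, map_b):
    """Oracle for the change-map area tallies (ha)."""
    out = {
        "net_deforestation": 0.0,
        "net_regrowth": 0.0,
        "stable_forest": 0.0,
        "stable_nonforest": 0.0,
    }
    f = map_a.scheme.forest_code
    rows, cols = map_a.grid.shape
    for i in range(rows):
        for j in range(cols):
            ca, cb = int(map_a.grid[i, j]), int(map_b.grid[i, j])
            if ca == map_a.scheme.nodata or cb == map_b.scheme.nodata:
                continue
            if ca == f and cb != f:
                out["net_deforestation"] += map_a.cell_area_ha
            elif ca != f and cb == f:
                out["net_regrowth"] += map_a.cell_area_ha
            elif ca == f and cb == f:
                out["stable_forest"] += map_a.cell_area_ha
            else:
                out["stable_nonforest"] += map_a.cell_area_ha
    return out
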