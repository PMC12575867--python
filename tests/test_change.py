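"""Transition matrices, change maps, trends and the stability rule."""

import math

import numpy as np
import pytest

from forestconverge import (
    LandCoverRaster,
    PatchSeries,
    ThresholdConfig,
    change_areas_ha,
    change_map,
    classify_direction,
    crosstab_transitions,
    fit_trend,
    forest_area_series,
    net_change_percent,
    printed_percent,
)
from conftest import brute_force_change_areas, brute_force_crosstab


def test_identical_maps_give_diagonal_matrix(two_class_scheme):
    grid = np.array([[1, 1, 2], [2, 1, 2]])
    a = LandCoverRaster(grid, 2000, 0.5, two_class_scheme)
    b = LandCoverRaster(grid.copy(), 2005, 0.5, two_class_scheme)
    tm = crosstab_transitions(a, b)
    off = tm.flows - np.diag(np.diag(tm.flows))
    assert (off == 0).all()
    assert tm.flow("forest", "forest") == pytest.approx(3 * 0.5)
    assert tm.flow("cropland", "cropland") == pytest.approx(3 * 0.5)


def test_toy_four_pixel_enumeration(toy_pair):
    tm = crosstab_transitions(*toy_pair)
    assert tm.flow("forest", "forest") == pytest.approx(2.0)
    assert tm.flow("forest", "cropland") == pytest.approx(1.0)
    assert tm.flow("cropland", "cropland") == pytest.approx(1.0)
    assert tm.flow("cropland", "forest") == pytest.approx(0.0)
    assert tm.total_area_ha == pytest.approx(4.0)


def test_change_map_toy_and_antisymmetry(toy_pair):
    a, b = toy_pair
    areas = change_areas_ha(change_map(a, b), a.cell_area_ha)
    assert areas == {
        "net_deforestation": 1.0,
        "net_regrowth": 0.0,
        "stable_forest": 2.0,
        "stable_nonforest": 1.0,
    }
    # swapping the inputs swaps deforestation and regrowth
    b2 = LandCoverRaster(b.grid, 2000, 1.0, b.scheme)
    a2 = LandCoverRaster(a.grid, 2005, 1.0, a.scheme)
    rev = change_areas_ha(change_map(b2, a2), 1.0)
    assert rev["net_deforestation"] == areas["net_regrowth"]
    assert rev["net_regrowth"] == areas["net_deforestation"]


def test_all_stable_forest(two_class_scheme):
    grid = np.ones((3, 3), dtype=int)
    a = LandCoverRaster(grid, 2000, 1.0, two_class_scheme)
    b = LandCoverRaster(grid, 2010, 1.0, two_class_scheme)
    areas = change_areas_ha(change_map(a, b), 1.0)
    assert areas["stable_forest"] == 9.0
    assert sum(areas.values()) == 9.0


def test_nodata_pixels_excluded_and_conservation(two_class_scheme):
    rng = np.random.default_rng(0)
    ga = rng.choice([0, 1, 2], size=(12, 12), p=[0.2, 0.5, 0.3])
    gb = rng.choice([0, 1, 2], size=(12, 12), p=[0.1, 0.4, 0.5])
    a = LandCoverRaster(ga, 2000, 0.09, two_class_scheme)
    b = LandCoverRaster(gb, 2005, 0.09, two_class_scheme)
    tm = crosstab_transitions(a, b)
    n_valid = int(((ga != 0) & (gb != 0)).sum())
    assert tm.total_area_ha == pytest.approx(n_valid * 0.09)
    assert (tm.flows >= 0).all()
    # oracle equivalence on the same pair
    oracle = brute_force_crosstab(a, b)
    for (cf, ct), area in oracle.items():
        assert tm.flow(cf, ct) == pytest.approx(area)
    assert change_areas_ha(change_map(a, b), 0.09) == pytest.approx(
        brute_force_change_areas(a, b)
    )


def test_chained_marginals_conserve_class_areas(two_class_scheme):
    rng = np.random.default_rng(1)
    grids = [rng.choice([1, 2], size=(10, 10)) for _ in range(3)]
    maps = [
        LandCoverRaster(g, epoch, 1.0, two_class_scheme)
        for g, epoch in zip(grids, (2000, 2005, 2010))
    ]
    t01 = crosstab_transitions(maps[0], maps[1])
    t12 = crosstab_transitions(maps[1], maps[2])
    assert t01.col_sums() == pytest.approx(t12.row_sums())


def test_shape_and_scheme_mismatch_errors(two_class_scheme):
    a = LandCoverRaster(np.ones((2, 2), int), 2000, 1.0, two_class_scheme)
    b = LandCoverRaster(np.ones((3, 3), int), 2005, 1.0, two_class_scheme)
    with pytest.raises(ValueError, match="shape"):
        crosstab_transitions(a, b)
    nod = LandCoverRaster(np.zeros((2, 2), int), 2005, 1.0, two_class_scheme)
    with pytest.raises(ValueError, match="overlap"):
        crosstab_transitions(a, nod)
    with pytest.raises(ValueError, match="epoch"):
        crosstab_transitions(a, LandCoverRaster(np.ones((2, 2), int), 1995, 1.0, two_class_scheme))


# ---------------------------------------------------------------------------
# series, net change, trends


def test_forest_series_normalization(two_class_scheme):
    grids = [np.ones((4, 4), int), np.ones((4, 4), int)]
    grids[1][0, :] = 2  # lose 4 of 16 forest pixels
    maps = [
        LandCoverRaster(g, e, 1.0, two_class_scheme) for g, e in zip(grids, (2000, 2005))
    ]
    s = forest_area_series(maps, "p")
    assert s.normalized_pct == [100.0, 75.0]
    assert s.normalized_pct[s.epochs.index(s.baseline_epoch)] == 100.0


def test_series_from_printed_areas():
    s = PatchSeries("Ewè-Adakplamè", [2000, 2022], [619.0, 505.0], 2000)
    assert s.normalized_pct[0] == 100.0
    assert s.normalized_pct[1] == pytest.approx(81.58, abs=0.005)


def test_series_from_csv_pass_through(tmp_path):
    csv = tmp_path / "series.csv"
    csv.write_text(
        "patch_id,year,forest_area_ha\np,2000,100\np,2010,90\np,2022,80\nq,2000,5\n"
    )
    s = PatchSeries.from_csv(csv, "p")
    assert s.epochs == [2000, 2010, 2022]
    assert s.forest_area_ha == [100.0, 90.0, 80.0]


def test_zero_baseline_is_error():
    with pytest.raises(ValueError, match="baseline"):
        PatchSeries("p", [2000, 2010], [0.0, 10.0], 2000)


@pytest.mark.parametrize(
    "start,end,expected",
    [(619.0, 505.0, 18.4), (1285.0, 1283.9, 0.09), (1007.0, 991.2, 1.6), (1270.7, 1253.0, 1.4)],
)
def test_net_change_printed_precision(start, end, expected):
    assert printed_percent(net_change_percent(start, end)) == expected


def test_net_change_sign_and_errors():
    assert net_change_percent(100.0, 100.0) == 0.0
    assert net_change_percent(100.0, 120.0) == -20.0  # gain is negative
    with pytest.raises(ValueError):
        net_change_percent(0.0, 10.0)


def test_trend_on_collinear_points_is_exact():
    s = PatchSeries("p", [2000, 2005, 2010], [100.0, 90.0, 80.0], 2000)
    tr = fit_trend(s)
    assert tr.slope == pytest.approx(-2.0)
    assert tr.intercept == pytest.approx(100.0 + 2.0 * 2000)
    residuals = [
        y - (tr.intercept + tr.slope * x) for x, y in zip(s.epochs, s.normalized_pct)
    ]
    assert max(abs(r) for r in residuals) < 1e-9


def test_trend_constant_series_has_zero_slope_p_one():
    s = PatchSeries("p", [2010, 2015, 2020, 2022], [50.0] * 4, 2010)
    tr = fit_trend(s)
    assert tr.slope == 0.0
    assert tr.p_value == 1.0


def test_two_point_trend_p_undefined():
    s = PatchSeries("p", [2010, 2022], [100.0, 90.0], 2010)
    tr = fit_trend(s)
    assert math.isnan(tr.p_value)
    assert tr.slope == pytest.approx((90.0 - 100.0) / 12)


def test_absolute_flag_fits_hectares():
    s = PatchSeries("p", [2000, 2005, 2010], [600.0, 540.0, 480.0], 2000)
    assert fit_trend(s, absolute=True).slope == pytest.approx(-12.0)


@pytest.mark.parametrize(
    "areas,expected",
    [
        ((1285.0, 1283.9), "stable"),  # 0.09% net change, two-point p undefined
        ((586.9, 505.4), "decline"),
        ((100.0, 100.0), "stable"),
        ((100.0, 110.0), "increase"),
    ],
)
def test_direction_from_endpoint_areas(areas, expected):
    s = PatchSeries("p", [2010, 2022], list(areas), 2010)
    assert classify_direction(s, window=(2010, 2022)).direction == expected


def test_small_change_with_significant_trend_is_not_stable():
    # monotone 1.5% decline: under the 2% band but the trend is significant
    s = PatchSeries("p", [2010, 2013, 2016, 2019, 2022], [1000, 996, 992, 988, 985], 2010)
    tr = classify_direction(s, window=(2010, 2022))
    assert abs(tr.net_change_pct) < 2.0 and tr.p_value < 0.10
    assert tr.direction == "decline"


def test_stability_band_is_monotone():
    rng = np.random.default_rng(5)
    for _ in range(50):
        areas = 1000 + rng.normal(0, 15, size=5).cumsum()
        s = PatchSeries("p", [2010, 2013, 2016, 2019, 2022], list(areas), 2010)
        d1 = classify_direction(s, thresholds=ThresholdConfig(stable_max_net_change_pct=2.0)).direction
        d2 = classify_direction(s, thresholds=ThresholdConfig(stable_max_net_change_pct=5.0)).direction
        if d1 == "stable":
            assert d2 == "stable"


def test_window_subsetting():
    s = PatchSeries("p", [2000, 2005, 2010, 2015, 2020, 2022], [100, 98, 96, 94, 92, 90], 2000)
    tr = classify_direction(s, window=(2010, 2022))
    assert tr.window == (2010, 2022)
    assert tr.n_points == 4
    assert tr.net_change_pct == pytest.approx(100 * (96 - 90) / 96)
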