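"""Synthetic landscape and survey generators: designed ground truth holds."""

import numpy as np
import pandas as pd
import pytest

from forestconverge import (
    LandscapeScenario,
    SurveyScenario,
    compute_index,
    make_fixture_suite,
    simulate_landscape_series,
    simulate_survey,
    summarize_responses,
)
from forestconverge.synthetic import DEFAULT_EPOCHS


def test_identity_kernel_is_absorbing():
    sc = LandscapeScenario(
        grid_rows=16,
        grid_cols=16,
        initial_class_proportions={"forest": 1.0},
        annual_transition_rates={},
        clump_size=1,
        seed=7,
    )
    rasters = simulate_landscape_series(sc)
    assert len(rasters) == len(DEFAULT_EPOCHS)
    for r in rasters:
        assert (r.grid == r.scheme.forest_code).all()
        np.testing.assert_array_equal(r.grid, rasters[0].grid)


def test_markov_loss_matches_closed_form():
    # forest->cropland at 0.02/yr over 12 years: loss = 1 - 0.98**12 per pixel
    sc = LandscapeScenario(
        grid_rows=200,
        grid_cols=200,
        initial_class_proportions={"forest": 1.0},
        annual_transition_rates={("forest", "cropland"): 0.02},
        epochs=(2010, 2022),
        clump_size=1,
        seed=11,
    )
    first, last = simulate_landscape_series(sc)
    n = first.grid.size
    p_loss = 1.0 - 0.98**12
    realized = 1.0 - (last.grid == last.scheme.forest_code).sum() / n
    sd = np.sqrt(p_loss * (1 - p_loss) / n)
    assert abs(realized - p_loss) <= 3 * sd


def test_same_seed_same_rasters():
    sc = dict(
        grid_rows=24,
        grid_cols=24,
        initial_class_proportions={"forest": 0.6, "shrubland": 0.3, "cropland": 0.1},
        annual_transition_rates={("forest", "shrubland"): 0.01},
        clump_size=9,
        seed=42,
    )
    a = simulate_landscape_series(LandscapeScenario(**sc))
    b = simulate_landscape_series(LandscapeScenario(**sc))
    for ra, rb in zip(a, b):
        np.testing.assert_array_equal(ra.grid, rb.grid)


def test_class_frequencies_match_markov_prediction():
    # i.i.d. initial conditions (clump 1): per-class counts are binomial, so
    # each must sit within 4 SDs of the P0 @ K^t prediction on >=1e4 pixels
    props = {"forest": 0.5, "shrubland": 0.3, "cropland": 0.2}
    sc = LandscapeScenario(
        grid_rows=120,
        grid_cols=120,
        initial_class_proportions=props,
        annual_transition_rates={
            ("forest", "cropland"): 0.02,
            ("shrubland", "forest"): 0.01,
        },
        clump_size=1,
        seed=3,
    )
    rasters = simulate_landscape_series(sc)
    kernel = sc.kernel()
    labels = sc.scheme.labels
    p0 = np.array([props.get(l, 0.0) for l in labels])
    n = sc.grid_rows * sc.grid_cols
    for r in rasters:
        years = r.epoch - sc.epochs[0]
        pt = p0 @ np.linalg.matrix_power(kernel, years)
        for k, lab in enumerate(labels):
            if pt[k] in (0.0, 1.0):
                continue
            observed = (r.grid == sc.scheme.codes[lab]).sum()
            sd = np.sqrt(n * pt[k] * (1 - pt[k]))
            assert abs(observed - n * pt[k]) <= 4 * sd, (r.epoch, lab)


def test_clumped_initialization_matches_proportions_and_is_clumpy():
    props = {"forest": 0.6, "cropland": 0.4}
    sc = LandscapeScenario(
        grid_rows=100,
        grid_cols=100,
        initial_class_proportions=props,
        clump_size=25,
        seed=5,
        epochs=(2000, 2005),
    )
    r0 = simulate_landscape_series(sc)[0]
    frac = (r0.grid == r0.scheme.forest_code).mean()
    assert abs(frac - 0.6) < 0.15  # clumping inflates variance; loose bound
    # clumpiness: same-class neighbour agreement far above the i.i.d. rate
    same = (r0.grid[:, 1:] == r0.grid[:, :-1]).mean()
    assert same > 0.75  # i.i.d. rate would be 0.6^2 + 0.4^2 = 0.52


def test_unknown_class_in_kernel_is_configuration_error():
    with pytest.raises(ValueError, match="unknown class"):
        LandscapeScenario(
            grid_rows=4,
            grid_cols=4,
            initial_class_proportions={"forest": 1.0},
            annual_transition_rates={("forest", "lunar_regolith"): 0.1},
        )


def test_proportions_must_sum_to_one():
    with pytest.raises(ValueError, match="sum"):
        LandscapeScenario(
            grid_rows=4, grid_cols=4, initial_class_proportions={"forest": 0.5}
        )


def test_stacks_order_ndvi_by_class():
    sc = LandscapeScenario(
        grid_rows=40,
        grid_cols=40,
        initial_class_proportions={"forest": 0.4, "shrubland": 0.3, "waterbody": 0.3},
        clump_size=4,
        seed=9,
        epochs=(2000, 2005),
    )
    rasters, stacks = simulate_landscape_series(sc, include_stacks=True)
    ndvi = compute_index(stacks[0], "NDVI")
    grid = rasters[0].grid
    sch = rasters[0].scheme
    mean = {
        lab: ndvi[grid == sch.codes[lab]].mean()
        for lab in ("forest", "shrubland", "waterbody")
    }
    assert mean["forest"] > mean["shrubland"] > mean["waterbody"]


# --------------------------------------------------------------------------
# surveys


def test_degenerate_survey_all_decreased():
    sc = SurveyScenario(
        n_respondents=50,
        patch_id="p",
        direction_probs={"10y": {"Decreased": 1.0}},
        seed=1,
    )
    table = simulate_survey(sc)
    s = summarize_responses(table, "p", "10y")
    assert s.consensus_direction == "decline"
    assert s.consensus_proportion == 1.0


def test_survey_proportions_within_binomial_bound():
    p = 0.93
    sc = SurveyScenario(
        n_respondents=300,
        patch_id="p",
        direction_probs={
            "10y": {"Decreased": p, "Increased": 0.03, "No change": 0.02, "Don't know": 0.02}
        },
        seed=2,
    )
    s = summarize_responses(simulate_survey(sc), "p", "10y")
    assert abs(s.proportions["Decreased"] - p) <= 3 * np.sqrt(p * (1 - p) / 300)


def test_survey_estimator_error_shrinks_with_n():
    p = 0.6
    errs = {}
    for n in (50, 500, 5000):
        sc = SurveyScenario(
            n_respondents=n,
            patch_id="p",
            direction_probs={"10y": {"Decreased": p, "Increased": 1 - p}},
            seed=123,
        )
        s = summarize_responses(simulate_survey(sc), "p", "10y")
        err = abs(s.proportions["Decreased"] - p)
        errs[n] = err
        assert err <= 4 * np.sqrt(p * (1 - p) / n)  # consistent at the 1/sqrt(n) rate
    assert errs[5000] < 4 * np.sqrt(p * (1 - p) / 5000)


def test_demographic_effects_shift_response_odds():
    shift = {"gender": {"female": {"Increased": 2.0, "Decreased": -2.0}}}
    sc = SurveyScenario(
        n_respondents=4000,
        patch_id="p",
        direction_probs={"10y": {"Decreased": 0.5, "Increased": 0.5}},
        demographic_effects=shift,
        seed=4,
    )
    t = simulate_survey(sc)
    inc = t.groupby("gender")["perceived_change_10y"].apply(
        lambda s: (s == "Increased").mean()
    )
    assert inc["female"] > inc["male"] + 0.2


def test_survey_reproducible_under_seed():
    sc = dict(
        n_respondents=80,
        patch_id="p",
        direction_probs={"10y": {"Decreased": 0.7, "Increased": 0.3}},
        seed=99,
    )
    a = simulate_survey(SurveyScenario(**sc))
    b = simulate_survey(SurveyScenario(**sc))
    pd.testing.assert_frame_equal(a, b)


def test_invalid_direction_probs_rejected():
    with pytest.raises(ValueError, match="sum"):
        SurveyScenario(
            n_respondents=10, patch_id="p", direction_probs={"10y": {"Decreased": 0.5}}
        )


# --------------------------------------------------------------------------
# fixture suite


def test_fixture_suite_is_byte_identical(tmp_path):
    b1 = make_fixture_suite(1, tmp_path / "a")
    b2 = make_fixture_suite(1, tmp_path / "b")
    files1 = sorted(p.relative_to(tmp_path / "a") for p in (tmp_path / "a").rglob("*") if p.is_file())
    files2 = sorted(p.relative_to(tmp_path / "b") for p in (tmp_path / "b").rglob("*") if p.is_file())
    assert files1 == files2
    for rel in files1:
        a = (tmp_path / "a" / rel).read_bytes()
        b = (tmp_path / "b" / rel).read_bytes().replace(
            str(tmp_path / "b").encode(), str(tmp_path / "a").encode()
        )
        assert a == b, rel
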