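"""Simulate a declining landscape and run post-classification change detection.

A 96x96 landscape (0.09 ha cells, i.e. 30 m pixels) starts 65% forest and
loses forest to cropland at 2%/yr. We detect the change with transition
matrices, a change map, and a linear trend on the normalized forest series.
"""

from forestconverge import (
    LandscapeScenario,
    change_areas_ha,
    change_map,
    classify_direction,
    crosstab_transitions,
    forest_area_series,
    sankey_flows,
    simulate_landscape_series,
)

scenario = LandscapeScenario(
    grid_rows=96,
    grid_cols=96,
    initial_class_proportions={"forest": 0.65, "shrubland": 0.20, "cropland": 0.15},
    annual_transition_rates={("forest", "cropland"): 0.02},
    clump_size=16,
    seed=42,
)
rasters = simulate_landscape_series(scenario)

series = forest_area_series(rasters, "demo")
print("forest area (ha) by epoch:")
for ep, ha, pct in zip(series.epochs, series.forest_area_ha, series.normalized_pct):
    print(f"  {ep}: {ha:7.2f} ha  ({pct:5.1f}% of 2000 baseline)")

trend = classify_direction(series, window=(2010, 2022))
print(
    f"\n2010-2022 trend: slope {trend.slope:+.2f} %/yr, p = {trend.p_value:.4f},"
    f" net change {trend.net_change_pct:.1f}% -> {trend.direction}"
)

tm = crosstab_transitions(rasters[0], rasters[-1])
print(f"\nforest -> cropland 2000-2022: {tm.flow('forest', 'cropland'):.2f} ha")
areas = change_areas_ha(change_map(rasters[0], rasters[-1]), scenario.cell_area_ha)
print("change map tallies (ha):", {k: round(v, 2) for k, v in areas.items()})

flows = sankey_flows([crosstab_transitions(a, b) for a, b in zip(rasters, rasters[1:])])
print(f"\ntop transition flows of {len(flows)} records (for Sankey rendering):")
print(flows.groupby("period").head(2).to_string(index=False))
print(
    "\nThe designed 2%/yr loss compounds to ~1-0.98^22 = 36% of the initial forest;"
    "\nthe fitted slope and the F->C flow recover that signal from the maps alone."
)
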