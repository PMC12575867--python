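"""Stratified accuracy assessment of a (synthetically degraded) classified map.

We simulate a landscape, draw a stratified reference sample proportional to
class area, corrupt the reference labels at a known 10% rate to mimic
classifier error, and report overall / producer's / user's accuracies with
binomial standard errors. Producer's accuracies should sit near 0.90.
"""

import numpy as np

from forestconverge import (
    LandscapeScenario,
    accuracy_metrics,
    confusion_from_refs,
    simulate_landscape_series,
    stratified_sample,
)

scenario = LandscapeScenario(
    grid_rows=120,
    grid_cols=120,
    initial_class_proportions={"forest": 0.5, "shrubland": 0.3, "cropland": 0.2},
    clump_size=16,
    seed=3,
    epochs=(2020, 2022),
)
lc_map = simulate_landscape_series(scenario)[0]

samples = stratified_sample(lc_map, n_total=500, seed=3)
print("sample allocation:", samples["mapped_class"].value_counts().to_dict())

rng = np.random.default_rng(3)
labels = sorted(samples["mapped_class"].unique())
reference = [
    m if rng.random() > 0.10 else rng.choice([l for l in labels if l != m])
    for m in samples["mapped_class"]
]

report = accuracy_metrics(confusion_from_refs(samples["mapped_class"], reference))
print(f"\noverall accuracy: {report.overall.accuracy:.3f} ± {report.overall.se:.3f}")
print(report.to_frame().round(3).to_string(index=False))
print(
    "\nSE = sqrt(p(1-p)/n) on each metric's own marginal n. With a designed 10%"
    "\nreference disagreement, accuracies near 0.90 confirm the bookkeeping."
)
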