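"""Run the full pipeline on the synthetic three-patch fixture suite.

`make_fixture_suite` writes three designed patches to disk (strong decline +
90% "Decreased"; perfectly stable + 95% "Decreased"; decline + mixed 45/35
responses) and a pipeline config. `run_pipeline` then reproduces the three
designed verdicts end to end from the files alone.
"""

import tempfile
from pathlib import Path

from forestconverge import make_fixture_suite, run_pipeline

with tempfile.TemporaryDirectory() as td:
    bundle = make_fixture_suite(seed=1, out_dir=Path(td) / "fixtures")
    report = run_pipeline(bundle["config"], Path(td) / "out")
    print(report["summary"].to_string(index=False))
    print("\noutputs written:", sorted(p.name for p in (Path(td) / "out").iterdir()))

print(
    "\nEach patch directory gains assessment.json, transitions.csv and"
    "\nsankey_flows.csv; convergence_matrix.csv consolidates the verdicts."
)
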