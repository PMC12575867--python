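"""Convergence matrix: reconciling satellite and local-knowledge evidence.

Each forest patch gets a satellite verdict (decline / stable / increase, from
the trend and stability rule in :mod:`forestconverge.change`) and a
local-knowledge response summary. Let *m* be the proportion of respondents
whose answer matches the satellite direction (stable ↔ "No change") and *o*
the largest proportion among the non-matching directional answers. Then, with
inclusive thresholds (defaults 0.65 / 0.35):

1. m ≥ 0.65 → **full convergence** (both sources agree, strong consensus);
2. else o ≥ 0.65 → **dissonance** (a strong consensus contradicts the map);
3. else → **partial convergence** (weak or mixed local consensus).

Patches where no single response category reaches the full-convergence
threshold carry a ``mixed_flag``. "Don't know" answers never count toward
*m* or *o*.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .change import ThresholdConfig, TransitionMatrix, TrendResult
from .survey import DIRECTION_OF_RESPONSE, RESPONSE_OF_DIRECTION, ResponseSummary

CATEGORIES = ("full_convergence", "partial_convergence", "dissonance")


@dataclass
class ConvergenceAssessment:
    """The joined verdict for one patch."""

    patch_id: str
    rs_direction: str
    lk_consensus_direction: str
    lk_consensus_proportion: float
    matching_proportion: float  # m
    opposing_proportion: float  # o
    category: str
    mixed_flag: bool
    recall_period: str
    window: tuple[int, int] | None
    thresholds: ThresholdConfig

    def to_dict(self) -> dict:
        return {
            "patch_id": self.patch_id,
            "rs_direction": self.rs_direction,
            "lk_consensus_direction": self.lk_consensus_direction,
            "lk_consensus_proportion": self.lk_consensus_proportion,
            "matching_proportion": self.matching_proportion,
            "opposing_proportion": self.opposing_proportion,
            "category": self.category,
            "mixed_flag": self.mixed_flag,
            "recall_period": self.recall_period,
            "window": list(self.window) if self.window else None,
            "thresholds": {
                "full_convergence_min": self.thresholds.full_convergence_min,
                "partial_min": self.thresholds.partial_min,
                "stable_max_net_change_pct": self.thresholds.stable_max_net_change_pct,
                "stable_min_trend_p": self.thresholds.stable_min_trend_p,
            },
        }


def classify_convergence(
    rs: "TrendResult | str",
    lk: ResponseSummary,
    thresholds: ThresholdConfig | None = None,
) -> ConvergenceAssessment:
    """Classify one patch's satellite-vs-local-knowledge agreement.

    ``rs`` may be a completed :class:`TrendResult` or a bare direction string
    (``decline`` / ``stable`` / ``increase``).
    """
    thresholds = thresholds or ThresholdConfig()
    direction = rs if isinstance(rs, str) else rs.direction
    if direction not in RESPONSE_OF_DIRECTION:
        raise ValueError(f"missing or invalid satellite direction {direction!r}")

    matching_response = RESPONSE_OF_DIRECTION[direction]
    m = lk.proportions.get(matching_response, 0.0)
    o = max(
        lk.proportions.get(c, 0.0)
        for c in DIRECTION_OF_RESPONSE
        if c != matching_response
    )
    if m >= thresholds.full_convergence_min:
        category = "full_convergence"
    elif o >= thresholds.full_convergence_min:
        category = "dissonance"
    else:
        category = "partial_convergence"
    mixed = (
        max(lk.proportions.get(c, 0.0) for c in DIRECTION_OF_RESPONSE)
        < thresholds.full_convergence_min
    )
    return ConvergenceAssessment(
        patch_id=lk.patch_id,
        rs_direction=direction,
        lk_consensus_direction=lk.consensus_direction,
        lk_consensus_proportion=lk.consensus_proportion,
        matching_proportion=m,
        opposing_proportion=o,
        category=category,
        mixed_flag=mixed,
        recall_period=lk.recall_period,
        window=None if isinstance(rs, str) else rs.window,
        thresholds=thresholds,
    )


def sankey_flows(matrices: list[TransitionMatrix]) -> pd.DataFrame:
    """Long-format flow records for Sankey rendering elsewhere.

    Columns: period, class_from, class_to, area_ha. Zero flows are omitted;
    records are ordered by period, then area descending.
    """
    if not matrices:
        return pd.DataFrame(columns=["period", "class_from", "class_to", "area_ha"])
    schemes = {tuple(sorted(m.scheme.codes.items())) for m in matrices}
    if len(schemes) > 1:
        raise ValueError("transition matrices disagree in class scheme")
    frames = []
    for m in sorted(matrices, key=lambda m: (m.epoch_from, m.epoch_to)):
        df = m.to_long()
        df = df[df["area_ha"] > 0].copy()
        df["period"] = f"{m.epoch_from}-{m.epoch_to}"
        df = df.sort_values("area_ha", ascending=False, kind="stable")
        frames.append(df[["period", "class_from", "class_to", "area_ha"]])
    return pd.concat(frames, ignore_index=True)
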