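"""Post-classification change detection and trend classification.

Given co-registered classified maps at successive epochs this module builds
land-cover transition matrices (area flows in hectares), categorical change
maps (deforestation / regrowth / stable forest / stable non-forest), forest
area trajectories normalized to a baseline epoch (baseline = 100%), ordinary
least-squares trends on those trajectories, and the decline / stable /
increase verdict used by the convergence analysis.

The stability rule: a patch is *stable* over the analysis window when its net
forest change is below ``stable_max_net_change_pct`` (default 2% of the
window-start area) and the linear trend is non-significant
(p >= ``stable_min_trend_p``, default 0.10) or undefined (two-point series).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .raster import LandCoverRaster
from .scheme import ClassScheme

CHANGE_CLASSES = {
    "net_deforestation": 1,
    "net_regrowth": 2,
    "stable_forest": 3,
    "stable_nonforest": 4,
}
CHANGE_NODATA = 0


@dataclass(frozen=True)
class ThresholdConfig:
    """Decision thresholds for stability and convergence classification."""

    stable_max_net_change_pct: float = 2.0
    stable_min_trend_p: float = 0.10
    full_convergence_min: float = 0.65
    partial_min: float = 0.35

    def __post_init__(self) -> None:
        if not (0 < self.partial_min < self.full_convergence_min < 1):
            raise ValueError("need 0 < partial_min < full_convergence_min < 1")
        if self.stable_max_net_change_pct <= 0:
            raise ValueError("stable_max_net_change_pct must be > 0")


@dataclass
class TransitionMatrix:
    """K x K area flows (ha) between two epochs; entry (i, j) = area i -> j."""

    epoch_from: int
    epoch_to: int
    flows: np.ndarray  # (K, K) in scheme label order
    scheme: ClassScheme

    @property
    def labels(self) -> list[str]:
        return self.scheme.labels

    @property
    def total_area_ha(self) -> float:
        return float(self.flows.sum())

    def flow(self, class_from: str, class_to: str) -> float:
        i = self.labels.index(class_from)
        j = self.labels.index(class_to)
        return float(self.flows[i, j])

    def row_sums(self) -> dict[str, float]:
        return dict(zip(self.labels, self.flows.sum(axis=1).tolist()))

    def col_sums(self) -> dict[str, float]:
        return dict(zip(self.labels, self.flows.sum(axis=0).tolist()))

    def to_long(self) -> pd.DataFrame:
        """Long format: epoch_from, epoch_to, class_from, class_to, area_ha."""
        rows = []
        for i, a in enumerate(self.labels):
            for j, b in enumerate(self.labels):
                rows.append(
                    {
                        "epoch_from": self.epoch_from,
                        "epoch_to": self.epoch_to,
                        "class_from": a,
                        "class_to": b,
                        "area_ha": float(self.flows[i, j]),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class PatchSeries:
    """Forest area per epoch for one patch, normalized to a baseline epoch."""

    patch_id: str
    epochs: list[int]
    forest_area_ha: list[float]
    baseline_epoch: int
    normalized_pct: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.epochs) != len(self.forest_area_ha):
            raise ValueError("epochs and areas disagree in length")
        if len(self.epochs) < 2:
            raise ValueError("a series needs at least 2 epochs")
        if self.baseline_epoch not in self.epochs:
            raise ValueError(f"baseline epoch {self.baseline_epoch} not in series")
        if any(a < 0 for a in self.forest_area_ha):
            raise ValueError("areas must be >= 0")
        base = self.forest_area_ha[self.epochs.index(self.baseline_epoch)]
        if base <= 0:
            raise ValueError("baseline forest area is 0; cannot normalize")
        if not self.normalized_pct:
            self.normalized_pct = [100.0 * a / base for a in self.forest_area_ha]

    def area_at(self, epoch: int) -> float:
        return self.forest_area_ha[self.epochs.index(epoch)]

    @classmethod
    def from_csv(
        cls, path: str | Path, patch_id: str, baseline_epoch: int | None = None
    ) -> "PatchSeries":
        """Load (patch_id, year, forest_area_ha) rows from CSV."""
        df = pd.read_csv(path)
        df = df[df["patch_id"].astype(str) == str(patch_id)].sort_values("year")
        if df.empty:
            raise ValueError(f"no rows for patch {patch_id!r} in {path}")
        epochs = df["year"].astype(int).tolist()
        return cls(
            patch_id=str(patch_id),
            epochs=epochs,
            forest_area_ha=df["forest_area_ha"].astype(float).tolist(),
            baseline_epoch=int(baseline_epoch if baseline_epoch is not None else epochs[0]),
        )


@dataclass
class TrendResult:
    """OLS trend on the normalized series plus the direction verdict."""

    slope: float  # % of baseline per year (or ha/yr if absolute)
    intercept: float
    p_value: float  # NaN when undefined (2-point window)
    net_change_pct: float  # positive = loss
    direction: str  # decline | stable | increase
    window: tuple[int, int]
    n_points: int

    @property
    def p_defined(self) -> bool:
        return not math.isnan(self.p_value)


def _check_pair(map_a: LandCoverRaster, map_b: LandCoverRaster) -> None:
    if map_a.grid.shape != map_b.grid.shape:
        raise ValueError("rasters disagree in shape")
    if map_a.scheme.to_dict() != map_b.scheme.to_dict():
        raise ValueError("rasters disagree in class scheme")
    if map_a.cell_area_ha != map_b.cell_area_ha:
        raise ValueError("rasters disagree in cell area")
    if map_a.epoch >= map_b.epoch:
        raise ValueError("epoch_from must precede epoch_to")


def crosstab_transitions(
    map_a: LandCoverRaster, map_b: LandCoverRaster
) -> TransitionMatrix:
    """Cross-tabulate pixel transitions between two classified maps.

    Pixels nodata in either epoch are excluded from the tabulation, so row
    sums equal epoch-a class areas over the jointly valid extent and the grand
    total equals the valid-overlap area.
    """
    _check_pair(map_a, map_b)
    valid = map_a.valid_mask & map_b.valid_mask
    if not valid.any():
        raise ValueError("zero valid overlap between epochs")
    labels = map_a.scheme.labels
    code_to_idx = {map_a.scheme.codes[lab]: k for k, lab in enumerate(labels)}
    k = len(labels)
    a = map_a.grid[valid]
    b = map_b.grid[valid]
    ai = np.vectorize(code_to_idx.__getitem__, otypes=[np.int64])(a)
    bi = np.vectorize(code_to_idx.__getitem__, otypes=[np.int64])(b)
    counts = np.bincount(ai * k + bi, minlength=k * k).reshape(k, k)
    return TransitionMatrix(
        epoch_from=map_a.epoch,
        epoch_to=map_b.epoch,
        flows=counts.astype(float) * map_a.cell_area_ha,
        scheme=map_a.scheme,
    )


def change_map(map_a: LandCoverRaster, map_b: LandCoverRaster) -> np.ndarray:
    """Categorical forest-change grid between two epochs.

    Codes (see :data:`CHANGE_CLASSES`): forest→non-forest = net deforestation,
    non-forest→forest = net regrowth, forest→forest = stable forest, other
    valid pixels = stable non-forest; nodata in either epoch = 0.
    """
    _check_pair(map_a, map_b)
    valid = map_a.valid_mask & map_b.valid_mask
    if not valid.any():
        raise ValueError("zero valid overlap between epochs")
    f = map_a.scheme.forest_code
    fa = map_a.grid == f
    fb = map_b.grid == f
    out = np.full(map_a.grid.shape, CHANGE_NODATA, dtype=np.int64)
    out[valid & fa & ~fb] = CHANGE_CLASSES["net_deforestation"]
    out[valid & ~fa & fb] = CHANGE_CLASSES["net_regrowth"]
    out[valid & fa & fb] = CHANGE_CLASSES["stable_forest"]
    out[valid & ~fa & ~fb] = CHANGE_CLASSES["stable_nonforest"]
    return out


def change_areas_ha(change: np.ndarray, cell_area_ha: float) -> dict[str, float]:
    """Area tally per change category (ha)."""
    return {
        name: float(np.count_nonzero(change == code)) * cell_area_ha
        for name, code in CHANGE_CLASSES.items()
    }


def forest_area_series(
    maps: list[LandCoverRaster],
    patch_id: str,
    baseline_epoch: int | None = None,
) -> PatchSeries:
    """Extract the per-epoch forest area of a patch from classified maps."""
    if len(maps) < 2:
        raise ValueError("need at least 2 epochs")
    maps = sorted(maps, key=lambda m: m.epoch)
    epochs = [m.epoch for m in maps]
    if baseline_epoch is None:
        baseline_epoch = epochs[0]
    areas = [m.forest_area_ha() for m in maps]
    return PatchSeries(
        patch_id=patch_id,
        epochs=epochs,
        forest_area_ha=areas,
        baseline_epoch=int(baseline_epoch),
    )


def net_change_percent(area_start: float, area_end: float) -> float:
    """Signed net change as % of the start area; positive = loss."""
    if area_start <= 0:
        raise ValueError("area_start must be > 0")
    return 100.0 * (area_start - area_end) / area_start


def printed_percent(value: float) -> float:
    """Round half-up at the reporting convention: 1 decimal, 2 when |v| < 0.1.

    Applied only when reporting; internal arithmetic stays at full precision.
    """
    places = Decimal("0.01") if abs(value) < 0.1 else Decimal("0.1")
    return float(Decimal(repr(value)).quantize(places, rounding=ROUND_HALF_UP))


def _window_subset(
    series: PatchSeries, window: tuple[int, int] | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[int, int]]:
    epochs = np.asarray(series.epochs, dtype=float)
    norm = np.asarray(series.normalized_pct, dtype=float)
    areas = np.asarray(series.forest_area_ha, dtype=float)
    if window is None:
        window = (series.epochs[0], series.epochs[-1])
    lo, hi = window
    sel = (epochs >= lo) & (epochs <= hi)
    if sel.sum() < 2:
        raise ValueError(f"fewer than 2 epochs inside window {window}")
    return epochs[sel], norm[sel], areas[sel], (int(lo), int(hi))


def fit_trend(
    series: PatchSeries,
    window: tuple[int, int] | None = None,
    absolute: bool = False,
) -> TrendResult:
    """OLS of the normalized trajectory (baseline=100) on calendar year.

    Slopes are in % of baseline per year (``absolute=True`` fits raw
    hectares). The two-sided slope p-value comes from the t distribution with
    n-2 df; with exactly two points the fit is exact and p is undefined (NaN).
    A zero-variance trajectory has slope 0 and p = 1 by convention.
    """
    x, norm, areas, window = _window_subset(series, window)
    y = areas if absolute else norm
    n = len(x)
    if np.ptp(y) == 0:
        slope, intercept, p = 0.0, float(y[0]), 1.0
    elif n == 2:
        slope = float((y[1] - y[0]) / (x[1] - x[0]))
        intercept = float(y[0] - slope * x[0])
        p = float("nan")
    else:
        res = stats.linregress(x, y)
        slope, intercept, p = float(res.slope), float(res.intercept), float(res.pvalue)
    net = net_change_percent(float(areas[0]), float(areas[-1]))
    return TrendResult(
        slope=slope,
        intercept=intercept,
        p_value=p,
        net_change_pct=net,
        direction="",  # filled by classify_direction
        window=window,
        n_points=n,
    )


def classify_direction(
    series: PatchSeries,
    window: tuple[int, int] | None = None,
    thresholds: ThresholdConfig | None = None,
) -> TrendResult:
    """Apply the stability rule and return the completed :class:`TrendResult`.

    Stable iff |net change| < ``stable_max_net_change_pct`` and the trend is
    non-significant (p >= ``stable_min_trend_p``) or undefined; otherwise
    decline when net change is a loss, increase when a gain; exact-zero net
    change with a significant trend falls back to the slope sign.
    """
    thresholds = thresholds or ThresholdConfig()
    tr = fit_trend(series, window)
    no_trend = (not tr.p_defined) or tr.p_value >= thresholds.stable_min_trend_p
    if abs(tr.net_change_pct) < thresholds.stable_max_net_change_pct and no_trend:
        direction = "stable"
    elif tr.net_change_pct > 0:
        direction = "decline"
    elif tr.net_change_pct < 0:
        direction = "increase"
    else:
        direction = "decline" if tr.slope < 0 else "increase"
    tr.direction = direction
    return tr


def transitions_to_csv(matrices: list[TransitionMatrix], path: str | Path) -> Path:
    """Write a list of transition matrices in long CSV format."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.concat([m.to_long() for m in matrices], ignore_index=True)
    df.to_csv(path, index=False)
    return path
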