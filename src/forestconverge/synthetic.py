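"""Synthetic landscapes, reflectance stacks and survey tables.

Every downstream stage of the pipeline is testable without external data:
this module fabricates (a) multi-epoch categorical landscapes driven by a
per-year Markov transition kernel with spatially clumped initial conditions,
(b) class-conditional reflectance stacks whose NDVI ordering separates forest
from shrubland and from built/water, and (c) household-survey tables with
designed direction consensus, "don't know" fractions and optional demographic
effects on the response odds.

Epochs default to 2000, 2005, 2010, 2015, 2020, 2022 (five-year composites
plus a recent year) and cells default to 0.09 ha (a 30 m pixel). Inter-epoch
gaps are handled by raising the annual kernel to the gap in years; no
intermediate rasters are materialized. A single integer seed drives one
numpy Generator stream per simulation call, so identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import BAND_NAMES, LandCoverRaster, SpectralStack, write_text_raster
from .scheme import ClassScheme, DEFAULT_SCHEME
from .survey import RESPONSE_CATEGORIES

DEFAULT_EPOCHS = (2000, 2005, 2010, 2015, 2020, 2022)
#: 30 m Landsat pixel
DEFAULT_CELL_AREA_HA = 0.09

#: class-conditional reflectance means (blue, green, red, nir, swir);
#: chosen so NDVI(forest) > NDVI(shrubland) > NDVI(built-up/waterbody)
REFLECTANCE_MEANS = {
    "forest": (0.04, 0.07, 0.05, 0.45, 0.18),
    "shrubland": (0.06, 0.10, 0.09, 0.32, 0.22),
    "cropland": (0.08, 0.12, 0.12, 0.28, 0.26),
    "built_up": (0.12, 0.14, 0.15, 0.20, 0.30),
    "wetland": (0.05, 0.09, 0.07, 0.30, 0.15),
    "waterbody": (0.06, 0.08, 0.05, 0.06, 0.03),
    "sparse_vegetation": (0.10, 0.13, 0.13, 0.22, 0.28),
}
REFLECTANCE_SD = 0.02


@dataclass
class LandscapeScenario:
    """Parameters for a simulated categorical landscape time series."""

    grid_rows: int
    grid_cols: int
    initial_class_proportions: dict[str, float]
    annual_transition_rates: dict[tuple[str, str], float] = field(default_factory=dict)
    epochs: tuple[int, ...] = DEFAULT_EPOCHS
    cell_area_ha: float = DEFAULT_CELL_AREA_HA
    clump_size: float = 25.0
    seed: int = 0
    scheme: ClassScheme = field(default_factory=lambda: DEFAULT_SCHEME)

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid must be at least 1x1")
        if self.clump_size < 1:
            raise ValueError("clump_size must be >= 1")
        if any(b <= a for a, b in zip(self.epochs, self.epochs[1:])):
            raise ValueError("epochs must be strictly increasing")
        total = sum(self.initial_class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"initial proportions sum to {total}, not 1")
        labels = set(self.scheme.labels)
        bad = set(self.initial_class_proportions) - labels
        if bad:
            raise ValueError(f"unknown classes in proportions: {sorted(bad)}")
        for a, b in self.annual_transition_rates:
            if a not in labels or b not in labels:
                raise ValueError(f"unknown class in transition kernel: {(a, b)}")
        self.kernel()  # validates row sums

    def kernel(self) -> np.ndarray:
        """Annual K x K transition kernel in scheme label order.

        Off-diagonals come from ``annual_transition_rates``; each diagonal is
        the residual so every row sums to exactly 1.
        """
        labels = self.scheme.labels
        k = len(labels)
        m = np.zeros((k, k))
        for (a, b), rate in self.annual_transition_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate for {(a, b)} outside [0, 1]")
            if a != b:
                m[labels.index(a), labels.index(b)] = rate
        resid = 1.0 - m.sum(axis=1)
        if (resid < -1e-12).any():
            raise ValueError("off-diagonal rates exceed 1 for some class")
        np.fill_diagonal(m, np.clip(resid, 0.0, 1.0))
        return m


def _clumped_initial(
    scenario: LandscapeScenario, rng: np.random.Generator
) -> np.ndarray:
    """Seeded region growing: random seeds, randomized breadth-first accretion.

    Returns a grid of class *indices* (0..K-1 in scheme label order).
    """
    rows, cols = scenario.grid_rows, scenario.grid_cols
    n = rows * cols
    labels = scenario.scheme.labels
    probs = np.array([scenario.initial_class_proportions.get(l, 0.0) for l in labels])
    n_seeds = max(1, int(round(n / scenario.clump_size)))
    grid = np.full((rows, cols), -1, dtype=np.int64)
    seed_idx = rng.choice(n, size=n_seeds, replace=False)
    grid.flat[seed_idx] = rng.choice(len(labels), size=n_seeds, p=probs)
    # accrete one ring per round; each unassigned pixel adopts a random
    # already-assigned 4-neighbour
    while (grid < 0).any():
        neigh = np.full((4, rows, cols), -1, dtype=np.int64)
        neigh[0, 1:, :] = grid[:-1, :]
        neigh[1, :-1, :] = grid[1:, :]
        neigh[2, :, 1:] = grid[:, :-1]
        neigh[3, :, :-1] = grid[:, 1:]
        priority = rng.random((4, rows, cols))
        priority[neigh < 0] = -1.0
        pick = priority.argmax(axis=0)
        chosen = np.take_along_axis(neigh, pick[None], axis=0)[0]
        adopt = (grid < 0) & (chosen >= 0)
        if not adopt.any():  # isolated pixels with no assigned neighbour yet
            continue
        grid[adopt] = chosen[adopt]
    return grid


def _step_markov(
    idx_grid: np.ndarray, kernel_pow: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Apply a multi-year transition kernel independently per pixel."""
    out = idx_grid.copy()
    u = rng.random(idx_grid.shape)
    cum = np.cumsum(kernel_pow, axis=1)
    for i in range(kernel_pow.shape[0]):
        mask = idx_grid == i
        if mask.any():
            out[mask] = np.searchsorted(cum[i], u[mask], side="right")
    return np.clip(out, 0, kernel_pow.shape[0] - 1)


def _stack_for(
    idx_grid: np.ndarray,
    labels: list[str],
    epoch: int,
    rng: np.random.Generator,
) -> SpectralStack:
    bands = {b: np.empty(idx_grid.shape) for b in BAND_NAMES}
    for i, lab in enumerate(labels):
        mask = idx_grid == i
        if not mask.any():
            continue
        means = REFLECTANCE_MEANS[lab]
        for b, mu in zip(BAND_NAMES, means):
            vals = rng.normal(mu, REFLECTANCE_SD, size=int(mask.sum()))
            bands[b][mask] = np.clip(vals, 0.0, 1.0)
    return SpectralStack(bands=bands, epoch=epoch)


def simulate_landscape_series(
    scenario: LandscapeScenario, include_stacks: bool = False
):
    """Simulate one classified raster per epoch (optionally with reflectance).

    Epoch 0 is drawn by clumped seeding matching the initial class proportions
    in expectation; each later epoch applies the annual kernel raised to the
    inter-epoch gap, independently per pixel.

    Returns a list of :class:`LandCoverRaster`, or ``(rasters, stacks)`` when
    ``include_stacks`` is true.
    """
    rng = np.random.default_rng(scenario.seed)
    labels = scenario.scheme.labels
    codes = np.array([scenario.scheme.codes[l] for l in labels], dtype=np.int64)
    kernel = scenario.kernel()

    idx = _clumped_initial(scenario, rng)
    grids = [idx]
    for prev, cur in zip(scenario.epochs, scenario.epochs[1:]):
        gap = cur - prev
        idx = _step_markov(idx, np.linalg.matrix_power(kernel, gap), rng)
        grids.append(idx)

    rasters = [
        LandCoverRaster(
            grid=codes[g],
            epoch=int(ep),
            cell_area_ha=scenario.cell_area_ha,
            scheme=scenario.scheme,
        )
        for ep, g in zip(scenario.epochs, grids)
    ]
    if not include_stacks:
        return rasters
    stacks = [
        _stack_for(g, labels, int(ep), rng) for ep, g in zip(scenario.epochs, grids)
    ]
    return rasters, stacks


# ---------------------------------------------------------------------------
# surveys

DEFAULT_DEMOGRAPHICS: dict[str, dict[str, float]] = {
    "gender": {"male": 0.70, "female": 0.30},
    "age_class": {"20-35": 0.20, "35-50": 0.35, "50-65": 0.30, ">65": 0.15},
    "education": {"none": 0.30, "primary": 0.25, "secondary": 0.35, "tertiary": 0.10},
    "community": {"community_a": 0.40, "community_b": 0.35, "community_c": 0.25},
    "residency_class": {"<5": 0.10, "5-10": 0.10, "10-15": 0.15, "15-20": 0.15, ">20": 0.50},
    "marital_status": {"married": 0.75, "single": 0.15, "widowed": 0.10},
    "occupation": {
        "farming": 0.60,
        "crafts_trades": 0.15,
        "household": 0.10,
        "hunters": 0.05,
        "unemployed": 0.05,
        "others": 0.05,
    },
}

DEFAULT_DRIVER_MENU: list[tuple[str, str, float]] = [
    ("logging", "negative", 0.45),
    ("slash_and_burn", "negative", 0.30),
    ("bush_fires", "negative", 0.25),
    ("population_growth", "negative", 0.15),
    ("ntfp_collection", "negative", 0.10),
    ("nothing_to_report", "neutral", 0.15),
    ("forest_regrowth", "positive", 0.08),
    ("law_enforcement", "positive", 0.08),
]


@dataclass
class SurveyScenario:
    """Parameters for a simulated household-survey table for one patch."""

    n_respondents: int
    patch_id: str
    direction_probs: dict[str, dict[str, float]]  # period -> category -> prob
    driver_menu: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(DEFAULT_DRIVER_MENU)
    )
    demographic_specs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DEMOGRAPHICS.items()}
    )
    demographic_effects: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=dict
    )  # field -> level -> category -> log-odds shift
    mean_household_size: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")
        for period, probs in self.direction_probs.items():
            bad = set(probs) - set(RESPONSE_CATEGORIES)
            if bad:
                raise ValueError(f"unknown response categories: {sorted(bad)}")
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{period} direction_probs sum to {total}, not 1")
        for _, valence, prob in self.driver_menu:
            if valence not in ("positive", "neutral", "negative"):
                raise ValueError(f"unknown valence {valence!r}")
            if not 0.0 <= prob <= 1.0:
                raise ValueError("citation probability outside [0, 1]")
        for spec in self.demographic_specs.values():
            total = sum(spec.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("demographic marginals must sum to 1")

    def driver_valences(self) -> dict[str, str]:
        return {label: val for label, val, _ in self.driver_menu}


def _sample_categorical(
    rng: np.random.Generator, levels: list[str], probs: np.ndarray, n: int
) -> np.ndarray:
    return np.array(levels, dtype=object)[
        rng.choice(len(levels), size=n, p=probs / probs.sum())
    ]


def _response_draw(
    rng: np.random.Generator,
    base: dict[str, float],
    demo: pd.DataFrame,
    effects: dict[str, dict[str, dict[str, float]]],
) -> np.ndarray:
    """Sample responses; demographic effects shift category log-odds (softmax)."""
    n = len(demo)
    cats = list(RESPONSE_CATEGORIES)
    with np.errstate(divide="ignore"):
        logits = np.tile(
            np.log(np.array([base.get(c, 0.0) for c in cats])), (n, 1)
        )
    for fld, by_level in effects.items():
        levels = demo[fld].astype(str)
        for ci, c in enumerate(cats):
            shift = levels.map(
                lambda lev: by_level.get(lev, {}).get(c, 0.0)
            ).to_numpy(dtype=float)
            logits[:, ci] += shift
    logits[np.isneginf(logits)] = -np.inf
    z = logits - logits.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(n)
    cum = np.cumsum(p, axis=1)
    picks = (u[:, None] > cum).sum(axis=1)
    return np.array(cats, dtype=object)[picks]


def simulate_survey(scenario: SurveyScenario) -> pd.DataFrame:
    """Simulate one survey table (one row per respondent) for a patch.

    Empirical direction proportions converge to ``direction_probs`` (after
    any demographic log-odds shifts) as n grows; everything is reproducible
    under a fixed seed.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_respondents
    demo = pd.DataFrame(
        {
            fld: _sample_categorical(
                rng, list(spec), np.array(list(spec.values())), n
            )
            for fld, spec in scenario.demographic_specs.items()
        }
    )
    demo["household_size"] = rng.poisson(scenario.mean_household_size - 1, size=n) + 1

    table = pd.DataFrame(
        {
            "respondent_id": [f"{scenario.patch_id}_{i:05d}" for i in range(n)],
            "patch_id": scenario.patch_id,
        }
    )
    table = pd.concat([table, demo], axis=1)

    for period in ("5y", "10y"):
        base = scenario.direction_probs.get(
            period, scenario.direction_probs[next(iter(scenario.direction_probs))]
        )
        table[f"perceived_change_{period}"] = _response_draw(
            rng, base, demo, scenario.demographic_effects
        )
        cites = []
        menu = scenario.driver_menu
        draws = rng.random((n, len(menu)))
        for i in range(n):
            cited = [m[0] for j, m in enumerate(menu) if draws[i, j] < m[2]]
            cites.append(";".join(cited))
        table[f"drivers_{period}"] = cites
    return table


# ---------------------------------------------------------------------------
# canonical fixture suite


def _fixture_scenarios(seed: int) -> dict[str, tuple[LandscapeScenario, SurveyScenario]]:
    base = int(seed) % (2**31 - 10)
    declining = {("forest", "cropland"): 0.03}
    out = {}
    out["full"] = (
        LandscapeScenario(
            grid_rows=48,
            grid_cols=48,
            initial_class_proportions={"forest": 0.70, "shrubland": 0.20, "cropland": 0.10},
            annual_transition_rates=declining,
            clump_size=16,
            seed=base + 1,
        ),
        SurveyScenario(
            n_respondents=120,
            patch_id="full",
            direction_probs={
                "5y": {"Decreased": 0.90, "Increased": 0.03, "No change": 0.04, "Don't know": 0.03},
                "10y": {"Decreased": 0.90, "Increased": 0.03, "No change": 0.04, "Don't know": 0.03},
            },
            seed=base + 2,
        ),
    )
    out["dissonance"] = (
        LandscapeScenario(
            grid_rows=48,
            grid_cols=48,
            initial_class_proportions={"forest": 0.75, "shrubland": 0.15, "cropland": 0.10},
            annual_transition_rates={},  # identity kernel: perfectly stable
            clump_size=16,
            seed=base + 3,
        ),
        SurveyScenario(
            n_respondents=120,
            patch_id="dissonance",
            direction_probs={
                "5y": {"Decreased": 0.95, "Increased": 0.02, "No change": 0.02, "Don't know": 0.01},
                "10y": {"Decreased": 0.95, "Increased": 0.02, "No change": 0.02, "Don't know": 0.01},
            },
            seed=base + 4,
        ),
    )
    out["partial"] = (
        LandscapeScenario(
            grid_rows=48,
            grid_cols=48,
            initial_class_proportions={"forest": 0.70, "shrubland": 0.20, "cropland": 0.10},
            annual_transition_rates=declining,
            clump_size=16,
            seed=base + 5,
        ),
        SurveyScenario(
            n_respondents=120,
            patch_id="partial",
            direction_probs={
                "5y": {"Decreased": 0.35, "Increased": 0.45, "No change": 0.12, "Don't know": 0.08},
                "10y": {"Decreased": 0.35, "Increased": 0.45, "No change": 0.12, "Don't know": 0.08},
            },
            seed=base + 6,
        ),
    )
    return out


def make_fixture_suite(seed: int, out_dir: str | Path) -> dict:
    """Write the canonical three-patch test bundle to disk.

    One designed "full convergence" patch (strong simulated decline + 90%
    "Decreased"), one "dissonance" patch (stable landscape + 95% "Decreased")
    and one "partial convergence" patch (decline + mixed 45/35 responses),
    each 48x48 pixels. Emits per-epoch text rasters, a survey CSV per patch,
    and a pipeline ``config.json``. Re-running with the same seed is
    byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scenarios = _fixture_scenarios(seed)
    patches = []
    for name, (land, surv) in scenarios.items():
        pdir = out_dir / name
        pdir.mkdir(parents=True, exist_ok=True)
        rasters = simulate_landscape_series(land)
        raster_paths = [
            str(write_text_raster(r, pdir / f"lc_{r.epoch}")) for r in rasters
        ]
        survey_csv = pdir / "survey.csv"
        simulate_survey(surv).to_csv(survey_csv, index=False)
        patches.append(
            {
                "patch_id": name,
                "rasters": raster_paths,
                "survey_csv": str(survey_csv),
            }
        )
    config = {
        "seed": int(seed),
        "window": [2010, 2022],
        "recall_period": "10y",
        "baseline_epoch": 2000,
        "patches": patches,
    }
    config_path = out_dir / "config.json"
    config_path.write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")
    return {"config": config_path, "patches": patches, "scenarios": scenarios}
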