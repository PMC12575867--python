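# Methods

This note documents the models, parameters, numerical choices and known
limitations of `forestconverge`, module by module.

## Change detection and trend classification

Post-classification comparison is exact bookkeeping, not estimation: two
co-registered classified maps are cross-tabulated pixel-by-pixel, and entry
(i, j) of the transition matrix is the pixel count moving from class i to
class j times the cell area (default 0.09 ha, a 30 m pixel). Pixels that are
nodata in **either** epoch are excluded from both the matrix and the change
map, so no phantom flows appear and the matrix total always equals the
jointly-valid area. Consequently row sums of the (t1→t2) matrix equal column
sums of the (t0→t1) matrix whenever the valid masks coincide.

Forest trajectories are normalized to a baseline epoch (100%), so trend
slopes read as percent of baseline per year; fitting raw hectares is
available via `absolute=True`. The slope p-value is the usual two-sided
t-test with n−2 degrees of freedom. Two degenerate cases are handled
explicitly:

- **two points in the window** — the fit is exact and the p-value is
  undefined (NaN); the stability rule then degrades to its net-change
  condition alone. This matters because published patch summaries often give
  only endpoint areas.
- **zero-variance trajectory** — slope 0 and p = 1 by convention (a constant
  series is the strongest possible evidence of "no trend"; the naive t-test
  is 0/0 there).

The direction verdict uses the stability rule: *stable* iff |net change| <
`stable_max_net_change_pct` (default 2% of the window-start area) **and** the
trend is non-significant (p ≥ `stable_min_trend_p`, default 0.10) or
undefined. Otherwise the sign of the net change decides decline vs increase,
with an exact-zero tie resolved by the slope sign. The default analysis
window is 2010–2022, matching the ten-year survey recall horizon; both the
window and the thresholds are configurable. Rounding to the reporting
convention (half-up; one decimal, two when |value| < 0.1) happens only in
`printed_percent`, never inside the arithmetic.

## Accuracy assessment

Reference labels always arrive as data. Stratified sampling allocates
proportionally to class area by largest-remainder apportionment with a
minimum of one sample per nonempty class (borrowed from the largest
allocations), capped at the stratum size, without replacement, seeded.
Accuracies are simple count-based ratios: overall = trace/n, producer's =
diagonal/column sum (reference-conditional), user's = diagonal/row sum
(map-conditional), each with the binomial standard error sqrt(p(1−p)/n) on
its own marginal n. A zero marginal yields NaN (undefined), never 0.
Area-weighted (Olofsson-style) estimators are deliberately out of scope: the
reporting they would feed uses simple accuracies.

## Survey summarization and association tests

Site-level proportions keep "Don't know" in the denominator — observed
percentage pairs like 46%/35% across named categories only make sense with an
inclusive denominator — while the consensus direction is the modal category
among the three directional answers only (ties → `none`).

`test_association` dispatches on the number of factor levels (default cap 4):

- **Fisher's exact test** for few-level factors. 2×2 tables use the standard
  two-sided exact test. Larger r×c tables are tested exactly by full
  enumeration of fixed-margin tables (summing hypergeometric probabilities ≤
  the observed one, ties at 1e-7 relative tolerance) whenever an upper bound
  on the number of tables stays below `exact_table_limit` (2e5); beyond that,
  a seeded Monte-Carlo estimate samples fixed-margin tables
  (`scipy.stats.random_table`) and uses the add-one estimator (B+1)/(N+1),
  default 1e5 draws.
- **Kruskal–Wallis H** for many-level factors, on the documented ordinal
  coding Decreased(0) < No change(1) < Increased(2) with "Don't know"
  excluded. When every retained response is identical the statistic is 0 and
  p = 1 (scipy would raise on zero rank variance).

The level cap is configurable because "few levels" is a judgment call — a
4-level factor can reasonably go either way; the default sends gender,
marital status and age to Fisher and community (often >4 communities) to
Kruskal–Wallis.

## Convergence matrix

With m = proportion of responses matching the satellite direction and o = the
largest non-matching directional proportion, the precedence is: m ≥ 0.65 →
full convergence; else o ≥ 0.65 → dissonance; else partial convergence.
Design choices worth stating:

- **Inclusive thresholds (≥).** A site with exactly 65% opposing responses
  classifies as dissonance; a strict ">" would flip such borderline sites to
  partial convergence.
- **No separate "weak/no convergence" outcome.** Under this precedence,
  agreement below 35% always co-occurs with either a strong opposing
  consensus (→ dissonance) or mixed responses (→ partial); the matching
  proportion m is recorded on every assessment so users can re-derive a
  four-way rule if they want one.
- **"Don't know" never counts** toward m or o; the mixed flag fires when no
  directional category reaches the full-convergence threshold.
- **Ten-year recall is the default** comparison period against the 2010–2022
  window; five-year is a flag.

`run_pipeline` executes change analysis → survey summary → convergence per
patch from a single JSON/YAML config; a failing patch is logged and skipped.
All outputs are deterministic (sorted-key JSON, no timestamps), so reruns are
byte-identical — the run log records the package version, seed and thresholds
instead of a wall clock.

## Spectral indices

NDBI = (SWIR−NIR)/(SWIR+NIR), NDVI = (NIR−Red)/(NIR+Red), NDWI =
(Green−NIR)/(Green+NIR), EVI = G(NIR−Red)/(NIR + C1·Red − C2·Blue + L) with
defaults G = 2.5, C1 = 6, C2 = 7.5, L = 1. Denominators within 1e-12 of zero
produce NaN (nodata) rather than ±inf, keeping grids finite. Reflectances
outside [0, 1] are accepted with a warning because sensor scaling dialects
vary. Indices are exposed as standalone products; no classifier is trained
here (classified maps are inputs).

## Synthetic data: what it emulates, and what it does not

The generator exists so that every downstream stage has known ground truth.

**Landscapes.** Epoch 0 is drawn by seeded region growing: ~n/clump_size
random seed pixels take classes from the initial proportions, then unassigned
pixels repeatedly adopt a uniformly random already-assigned 4-neighbour —
breadth-first accretion with randomized tie-breaks, giving patchy maps whose
expected class shares match the proportions (clump_size = 1 reduces to i.i.d.
draws). Later epochs apply the annual Markov kernel raised to the inter-epoch
gap (5, 5, 5, 5, 2 years for the default 2000–2022 epochs), independently per
pixel; no intermediate years are materialized. Off-diagonal kernel entries
come from the configured rates; diagonals are the residual so rows sum to 1
exactly. Per-pixel class frequencies therefore follow P0·Kᵗ, and with
clump_size = 1 the class counts are exactly binomial — the property the tests
check at 4 SDs.

**Reflectance stacks.** Band values are Gaussian around fixed class means
(SD 0.02, clipped to [0, 1]) chosen to order NDVI(forest) > NDVI(shrubland) >
NDVI(built-up/waterbody) — enough to validate index code, not a radiative
transfer model.

**Surveys.** Respondent demographics are sampled from configurable marginals
(defaults reflect the study region: ~70% male respondents, predominantly
middle-aged, >20-year residency the largest class, mean household size 5).
Perceived-change answers are drawn from the designed category probabilities
after applying per-level log-odds shifts through a softmax, so probabilities
always stay valid; driver citations are independent Bernoulli draws from the
menu. Direction proportions are consistent estimators of the designed
probabilities (error shrinking as 1/√n).

**What passing tests do not show.** Real landscapes have spatially correlated
*transitions* (clearing fronts, fires), not just correlated initial states;
real surveys have non-response, recall bias and within-community correlation;
real classified maps carry spatially structured classifier error. Results on
synthetic data validate the bookkeeping and the statistical machinery, not
the ecological realism of any particular study area.

**Fixture suite.** Three designed 48×48 patches: "full" (forest→cropland at
0.03/yr, ~30% window loss, 90% "Decreased"), "dissonance" (identity kernel —
perfectly stable — with 95% "Decreased") and "partial" (same decline, mixed
45/35 Increased/Decreased responses), 120 respondents each. A single integer
seed derives all per-scenario seeds; reruns are byte-identical.

## Problem sizes and precision knobs

The test and acceptance workloads use: 200 random map pairs ≤32×32 for oracle
equivalence; every 2×2 contingency table with n ≤ 30 (~45k tables) for the
Fisher check; 200 replicates of 128×128 landscapes at the designed 2%/yr loss
for parameter recovery; and 500 simulated surveys (n = 300) for type-I
calibration, where the Monte-Carlo Fisher runs at 4 000 draws — the resulting
p-value noise (SD ≤ 0.008) is an order of magnitude below the 0.1 KS
acceptance band, while the production default stays at 1e5 draws.

## Known limitations

- No geodetic awareness: rasters must be co-registered and equal-area;
  text-grid and plain single-band TIFF I/O only (no GeoTIFF CRS tags).
- Sankey output is a long-format flow table; rendering is left to plotting
  tools.
- National-scale rate aggregation is not implemented (the rate formula and
  baseline areas such aggregates require are analysis-specific).
- The Kruskal–Wallis ordinal coding is a convention; alternative codings
  (e.g. treating "No change" as non-ordinal) would change H for strongly
  mixed sites.
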