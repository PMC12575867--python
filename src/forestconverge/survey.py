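"""Household-survey ingestion, summarization and association testing.

A survey table is a pandas DataFrame, one row per respondent, with
demographics, a perceived-change answer per recall period (5y / 10y) drawn
from {"Decreased", "Increased", "No change", "Don't know"}, and the drivers a
respondent cited (semicolon-joined labels in ``drivers_5y`` / ``drivers_10y``).

Summaries keep "Don't know" in the denominator (site-level percentages need
not sum to 100 over the named directions), while the consensus direction is
the modal answer among the three directional categories only.

Association tests dispatch on the number of factor levels: Fisher's exact
test for factors with few levels (default cap 4), the Kruskal–Wallis H test
otherwise, with responses rank-coded Decreased < No change < Increased and
"Don't know" excluded from the ordinal coding. Fisher on tables larger than
2x2 uses exact enumeration when feasible and otherwise a seeded Monte-Carlo
estimate over fixed-margin tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

RESPONSE_CATEGORIES = ("Decreased", "Increased", "No change", "Don't know")
DIRECTION_OF_RESPONSE = {
    "Decreased": "decline",
    "Increased": "increase",
    "No change": "stable",
}
RESPONSE_OF_DIRECTION = {v: k for k, v in DIRECTION_OF_RESPONSE.items()}
#: ordinal coding for rank tests; "Don't know" is excluded
ORDINAL_CODE = {"Decreased": 0, "No change": 1, "Increased": 2}
RECALL_COLUMNS = {"5y": "perceived_change_5y", "10y": "perceived_change_10y"}
DRIVER_COLUMNS = {"5y": "drivers_5y", "10y": "drivers_10y"}
VALENCES = ("positive", "neutral", "negative")


@dataclass
class ResponseSummary:
    """Per-patch, per-recall-period response proportions and consensus."""

    patch_id: str
    recall_period: str
    n: int
    proportions: dict[str, float]  # over the four categories, sums to 1
    consensus_direction: str  # decline | increase | stable | none
    consensus_proportion: float

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, not 1")

    @classmethod
    def from_percentages(
        cls, patch_id: str, recall_period: str, percentages: dict[str, float]
    ) -> "ResponseSummary":
        """Build a summary from published site-level percentages (0–100).

        Any unstated remainder is booked under "Don't know" so proportions
        sum to 1 without inventing directional answers.
        """
        props = {c: percentages.get(c, 0.0) / 100.0 for c in RESPONSE_CATEGORIES}
        remainder = 1.0 - sum(props.values())
        if remainder < -1e-9:
            raise ValueError("percentages exceed 100")
        props["Don't know"] += max(remainder, 0.0)
        return cls(
            patch_id=patch_id,
            recall_period=recall_period,
            n=0,  # counts unknown when built from percentages
            proportions=props,
            **_consensus(props),
        )


def _consensus(props: dict[str, float]) -> dict:
    directional = {c: props.get(c, 0.0) for c in DIRECTION_OF_RESPONSE}
    top = max(directional.values())
    winners = [c for c, v in directional.items() if v == top]
    if top == 0 or len(winners) > 1:
        return {"consensus_direction": "none", "consensus_proportion": top}
    return {
        "consensus_direction": DIRECTION_OF_RESPONSE[winners[0]],
        "consensus_proportion": top,
    }


@dataclass
class DriverSummary:
    """Per-driver citation percentages and per-valence citation totals."""

    patch_id: str
    recall_period: str
    n: int
    citation_pct: dict[str, float]  # driver label -> % of patch respondents
    valence_counts: dict[str, int]  # valence -> total citations

    def __post_init__(self) -> None:
        for label, pct in self.citation_pct.items():
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"citation percentage out of range for {label!r}")


def _patch_rows(table: pd.DataFrame, patch_id: str) -> pd.DataFrame:
    rows = table[table["patch_id"].astype(str) == str(patch_id)]
    if rows.empty:
        raise ValueError(f"no respondents for patch {patch_id!r}")
    return rows


def summarize_responses(
    table: pd.DataFrame, patch_id: str, recall_period: str
) -> ResponseSummary:
    """Aggregate one patch's perceived-change answers for a recall period."""
    if recall_period not in RECALL_COLUMNS:
        raise ValueError(f"recall_period must be one of {sorted(RECALL_COLUMNS)}")
    rows = _patch_rows(table, patch_id)
    answers = rows[RECALL_COLUMNS[recall_period]]
    unknown = set(answers.unique()) - set(RESPONSE_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown response categories: {sorted(unknown)}")
    n = len(answers)
    props = {c: float((answers == c).sum()) / n for c in RESPONSE_CATEGORIES}
    return ResponseSummary(
        patch_id=str(patch_id),
        recall_period=recall_period,
        n=n,
        proportions=props,
        **_consensus(props),
    )


def summarize_drivers(
    table: pd.DataFrame,
    patch_id: str,
    recall_period: str,
    valences: dict[str, str],
) -> DriverSummary:
    """Citation percentage per driver; a respondent citing k drivers counts in k."""
    rows = _patch_rows(table, patch_id)
    col = DRIVER_COLUMNS[recall_period]
    n = len(rows)
    counts: dict[str, int] = {}
    for cell in rows[col].fillna(""):
        for label in [d for d in str(cell).split(";") if d]:
            counts[label] = counts.get(label, 0) + 1
    bad = {d: valences.get(d) for d in counts if valences.get(d) not in VALENCES}
    if bad:
        raise ValueError(f"drivers with unknown valence: {sorted(bad)}")
    valence_counts = {v: 0 for v in VALENCES}
    for label, c in counts.items():
        valence_counts[valences[label]] += c
    return DriverSummary(
        patch_id=str(patch_id),
        recall_period=recall_period,
        n=n,
        citation_pct={d: 100.0 * c / n for d, c in sorted(counts.items())},
        valence_counts=valence_counts,
    )


# ---------------------------------------------------------------------------
# Fisher's exact test for r x c tables


def _log_table_prob(table: np.ndarray) -> float:
    """Log hypergeometric probability of a table given its margins."""
    table = np.asarray(table, dtype=np.int64)
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(r + 1).sum()
        + gammaln(c + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def _enumerate_tables(row_sums: np.ndarray, col_sums: np.ndarray):
    """Yield every contingency table with the given margins."""
    n_rows = len(row_sums)

    def rec(i: int, cols_left: np.ndarray, built: list[np.ndarray]):
        if i == n_rows - 1:
            yield np.array(built + [cols_left.copy()])
            return
        for comp in _row_compositions(int(row_sums[i]), cols_left):
            yield from rec(i + 1, cols_left - comp, built + [comp])

    yield from rec(0, col_sums.copy(), [])


def _row_compositions(total: int, caps: np.ndarray):
    """Compositions of `total` into len(caps) parts with part j <= caps[j]."""
    k = len(caps)

    def rec(j: int, left: int, cur: list[int]):
        if j == k - 1:
            if left <= caps[j]:
                yield np.array(cur + [left], dtype=np.int64)
            return
        hi = min(left, int(caps[j]))
        lo = max(0, left - int(caps[j + 1 :].sum()))
        for v in range(lo, hi + 1):
            yield from rec(j + 1, left - v, cur + [v])

    yield from rec(0, total, [])


def fisher_exact_enumeration(table: np.ndarray) -> float:
    """Two-sided Fisher p by full enumeration of fixed-margin tables.

    p = sum of hypergeometric probabilities of all tables at most as probable
    as the observed one (ties included with a 1e-7 relative tolerance, the
    usual convention for two-sided Fisher).
    """
    table = np.asarray(table, dtype=np.int64)
    lp_obs = _log_table_prob(table)
    p = 0.0
    for t in _enumerate_tables(table.sum(axis=1), table.sum(axis=0)):
        lp = _log_table_prob(t)
        if lp <= lp_obs + 1e-7:
            p += math.exp(lp)
    return min(p, 1.0)


def _enumeration_size_bound(table: np.ndarray) -> float:
    """Upper bound on the number of fixed-margin tables (compositions)."""
    r = table.sum(axis=1)
    c = table.shape[1]
    log_bound = sum(gammaln(ri + c) - gammaln(ri + 1) - gammaln(c) for ri in r)
    with np.errstate(over="ignore"):
        return float(np.exp(log_bound))


def fisher_monte_carlo(
    table: np.ndarray, draws: int = 100_000, seed: int = 0
) -> float:
    """Monte-Carlo two-sided Fisher p over fixed-margin tables (seeded).

    Uses the add-one estimator (B+1)/(N+1), which never returns 0.
    """
    table = np.asarray(table, dtype=np.int64)
    dist = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    lp_obs = dist.logpmf(table)
    rng = np.random.default_rng(seed)
    samples = dist.rvs(draws, random_state=rng)
    lp = dist.logpmf(samples)
    b = int(np.count_nonzero(lp <= lp_obs + 1e-7))
    return (b + 1) / (draws + 1)


@dataclass(frozen=True)
class AssociationConfig:
    """Dispatch and precision settings for :func:`test_association`."""

    fisher_level_cap: int = 4  # factor levels <= cap -> Fisher, else KW
    exact_table_limit: float = 2e5  # enumerate when table count bound below this
    mc_draws: int = 100_000
    seed: int = 0


def test_association(
    table: pd.DataFrame,
    factor: str,
    response: str = "perceived_change_10y",
    config: AssociationConfig | None = None,
) -> tuple[float, float, str]:
    """Test whether perceived change varies with a demographic factor.

    Returns ``(statistic, p_value, test_name)``. Fisher's exact test when the
    factor has at most ``fisher_level_cap`` levels (statistic = odds ratio for
    2x2, observed-table log-probability otherwise); Kruskal–Wallis H on the
    ordinal response coding for factors with more levels.
    """
    config = config or AssociationConfig()
    sub = table[[factor, response]].dropna()
    levels = sorted(sub[factor].astype(str).unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 nonempty levels")
    if (sub[response] == "Don't know").all():
        raise ValueError("all responses are \"Don't know\"; nothing to test")

    if len(levels) <= config.fisher_level_cap:
        ct = pd.crosstab(sub[factor].astype(str), sub[response])
        ct = ct.loc[(ct.sum(axis=1) > 0), (ct.sum(axis=0) > 0)]
        obs = ct.to_numpy(dtype=np.int64)
        if obs.shape == (2, 2):
            odds, p = stats.fisher_exact(obs, alternative="two-sided")
            return float(odds), float(p), "fisher_exact"
        if _enumeration_size_bound(obs) <= config.exact_table_limit:
            return (
                _log_table_prob(obs),
                fisher_exact_enumeration(obs),
                "fisher_exact_enumeration",
            )
        p = fisher_monte_carlo(obs, draws=config.mc_draws, seed=config.seed)
        return _log_table_prob(obs), p, "fisher_monte_carlo"

    coded = sub[sub[response] != "Don't know"]
    groups = [
        coded.loc[coded[factor].astype(str) == lev, response]
        .map(ORDINAL_CODE)
        .to_numpy(dtype=float)
        for lev in levels
    ]
    groups = [g for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("fewer than 2 factor levels with directional responses")
    flat = np.concatenate(groups)
    if np.ptp(flat) == 0:  # identical responses everywhere: no rank variation
        return 0.0, 1.0, "kruskal_wallis"
    h, p = stats.kruskal(*groups)
    return float(h), float(p), "kruskal_wallis"


def association_grid(
    table: pd.DataFrame,
    factors: list[str],
    response: str = "perceived_change_10y",
    config: AssociationConfig | None = None,
) -> pd.DataFrame:
    """Factor x test x p grid across demographic variables."""
    rows = []
    for f in factors:
        stat, p, name = test_association(table, f, response, config)
        rows.append({"factor": f, "test": name, "statistic": stat, "p_value": p})
    return pd.DataFrame(rows)


def read_survey_csv(
    path: str | Path, data_dictionary: str | Path | None = None
) -> pd.DataFrame:
    """Load a survey CSV; optionally remap local response wordings.

    ``data_dictionary`` is a JSON file ``{"responses": {"local wording":
    "canonical category", ...}}`` applied to both recall-period columns.
    """
    import json

    df = pd.read_csv(path)
    if data_dictionary is not None:
        mapping = json.loads(Path(data_dictionary).read_text()).get("responses", {})
        for col in RECALL_COLUMNS.values():
            if col in df:
                df[col] = df[col].map(lambda v: mapping.get(v, v))
    return df
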