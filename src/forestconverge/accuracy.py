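"""Thematic-map accuracy assessment on stratified reference samples.

Reference labels always arrive as data (e.g. interpreted from high-resolution
imagery elsewhere); this module allocates a stratified random sample over a
classified map, tabulates the confusion matrix, and reports overall,
producer's and user's accuracies with binomial standard errors
SE = sqrt(p(1-p)/n), each on its own marginal n. Accuracies are simple
(count-based), not area-weighted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import LandCoverRaster


@dataclass
class ConfusionMatrix:
    """Counts; entry (i, j) = samples mapped as class i, referenced as j."""

    counts: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.shape[0] != len(self.labels):
            raise ValueError("labels length must match matrix size")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClassAccuracy:
    accuracy: float  # NaN when marginal n is 0 (undefined, not 0)
    se: float
    n: int


@dataclass
class AccuracyReport:
    overall: ClassAccuracy
    producers: dict[str, ClassAccuracy]
    users: dict[str, ClassAccuracy]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lab in self.producers:
            p, u = self.producers[lab], self.users[lab]
            rows.append(
                {
                    "class": lab,
                    "producers_accuracy": p.accuracy,
                    "producers_se": p.se,
                    "reference_n": p.n,
                    "users_accuracy": u.accuracy,
                    "users_se": u.se,
                    "mapped_n": u.n,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        def d(c: ClassAccuracy) -> dict:
            return {"accuracy": c.accuracy, "se": c.se, "n": c.n}

        return {
            "overall": d(self.overall),
            "producers": {k: d(v) for k, v in self.producers.items()},
            "users": {k: d(v) for k, v in self.users.items()},
        }


def _largest_remainder(shares: np.ndarray, n_total: int) -> np.ndarray:
    """Apportion n_total by largest remainder, minimum 1 per nonempty stratum."""
    k = len(shares)
    quotas = shares / shares.sum() * n_total
    alloc = np.floor(quotas).astype(int)
    remainder = n_total - alloc.sum()
    order = np.argsort(-(quotas - alloc), kind="stable")
    alloc[order[:remainder]] += 1
    # enforce the minimum, borrowing from the largest allocations
    while (alloc == 0).any():
        alloc[np.argmax(alloc == 0)] += 1
        alloc[np.argmax(alloc)] -= 1
    assert alloc.sum() == n_total and (alloc >= 1).all()
    return alloc


def stratified_sample(
    lc_map: LandCoverRaster, n_total: int, seed: int
) -> pd.DataFrame:
    """Stratified random sample of pixels, proportional to class area.

    Allocation uses largest-remainder apportionment with a minimum of one
    sample per nonempty class; sampling is without replacement within each
    stratum and reproducible by seed. Returns columns row, col, mapped_class.
    """
    rng = np.random.default_rng(seed)
    strata = [
        (lab, code)
        for lab, code in lc_map.scheme.codes.items()
        if np.count_nonzero(lc_map.grid == code) > 0
    ]
    if n_total < len(strata):
        raise ValueError(
            f"n_total={n_total} below the number of nonempty strata ({len(strata)})"
        )
    sizes = np.array(
        [np.count_nonzero(lc_map.grid == code) for _, code in strata], dtype=float
    )
    alloc = _largest_remainder(sizes, n_total)
    alloc = np.minimum(alloc, sizes.astype(int))  # cannot exceed stratum size
    records = []
    for (lab, code), take in zip(strata, alloc):
        rows, cols = np.nonzero(lc_map.grid == code)
        idx = rng.choice(len(rows), size=int(take), replace=False)
        for i in np.sort(idx):
            records.append({"row": int(rows[i]), "col": int(cols[i]), "mapped_class": lab})
    return pd.DataFrame(records)


def confusion_from_refs(
    mapped: "list[str] | pd.Series",
    reference: "list[str] | pd.Series",
    labels: list[str] | None = None,
) -> ConfusionMatrix:
    """Tabulate mapped-vs-reference labels into a confusion matrix."""
    mapped = list(mapped)
    reference = list(reference)
    if len(mapped) != len(reference):
        raise ValueError("mapped and reference differ in length")
    if labels is None:
        labels = sorted(set(mapped) | set(reference))
    bad = [x for x in set(mapped) | set(reference) if x not in labels]
    if bad:
        raise ValueError(f"labels outside scheme: {sorted(bad)}")
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for m, r in zip(mapped, reference):
        counts[index[m], index[r]] += 1
    return ConfusionMatrix(counts=counts, labels=list(labels))


def _binom(correct: float, n: float) -> ClassAccuracy:
    if n == 0:
        return ClassAccuracy(accuracy=float("nan"), se=float("nan"), n=0)
    p = correct / n
    return ClassAccuracy(accuracy=p, se=math.sqrt(p * (1 - p) / n), n=int(n))


def accuracy_metrics(cm: ConfusionMatrix) -> AccuracyReport:
    """Overall, producer's (column-wise) and user's (row-wise) accuracies.

    A class with a zero marginal gets NaN (undefined), never 0.
    """
    if cm.n_total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(cm.counts).astype(float)
    col = cm.counts.sum(axis=0).astype(float)
    row = cm.counts.sum(axis=1).astype(float)
    return AccuracyReport(
        overall=_binom(float(diag.sum()), float(cm.n_total)),
        producers={lab: _binom(diag[j], col[j]) for j, lab in enumerate(cm.labels)},
        users={lab: _binom(diag[i], row[i]) for i, lab in enumerate(cm.labels)},
    )


def samples_to_csv(samples: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    samples.to_csv(path, index=False)
    return path
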