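"""Supply–demand balance index and natural-breaks typologies.

The balance index per zone is BI = supply − demand. Because monetary supply
(10⁸ yuan) and the dimensionless demand index live on incommensurate scales,
the default mode min–max rescales both sides to [0, 1] within each year
before subtracting, so BI ∈ [−1, 1]; ``mode="raw"`` subtracts literally.

Classification uses Jenks natural breaks (the Fisher optimal partition of a
sorted 1-D sample into k contiguous classes minimising total within-class
sum of squared deviations), computed by exact dynamic programming. Supply
and demand are graded on five levels (low … high); the balance index on a
seven-class surplus/deficit typology whose middle class — the one containing
zero — is named "balance".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Five-level grade names for supply and demand, ascending.
LEVEL_LABELS_5 = ("low", "lower", "general", "higher", "high")

_SIDE_GRADES = ("general", "higher", "high")


class ZoneMismatchError(ValueError):
    """Supply and demand tables cover different zone sets."""


def _minmax(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def balance_index(
    supply: pd.DataFrame,
    demand: pd.DataFrame,
    mode: str = "normalized",
    supply_col: str = "esv",
    demand_col: str = "X",
) -> pd.DataFrame:
    """Join per-zone supply and demand and compute BI per (zone, year).

    ``supply`` needs columns ``zone, year, <supply_col>``; ``demand`` needs
    ``zone, year, <demand_col>``. In normalized mode both sides are min–max
    scaled within each year before subtracting.
    """
    if mode not in ("normalized", "raw"):
        raise ValueError(f"mode must be 'normalized' or 'raw', got {mode!r}")
    s = supply[["zone", "year", supply_col]].rename(columns={supply_col: "supply"})
    d = demand[["zone", "year", demand_col]].rename(columns={demand_col: "demand"})
    merged = s.merge(d, on=["zone", "year"], how="outer", indicator=True)
    bad = merged[merged["_merge"] != "both"]
    if len(bad):
        missing = sorted(set(map(tuple, bad[["zone", "year"]].itertuples(index=False))))
        raise ZoneMismatchError(f"unmatched (zone, year) pairs: {missing}")
    merged = merged.drop(columns="_merge")
    if mode == "raw":
        merged["supply_scaled"] = merged["supply"]
        merged["demand_scaled"] = merged["demand"]
    else:
        merged["supply_scaled"] = merged.groupby("year")["supply"].transform(
            lambda v: _minmax(v.to_numpy())
        )
        merged["demand_scaled"] = merged.groupby("year")["demand"].transform(
            lambda v: _minmax(v.to_numpy())
        )
    merged["BI"] = merged["supply_scaled"] - merged["demand_scaled"]
    merged.attrs["mode"] = mode
    return merged


@dataclass
class ClassificationScheme:
    """A fitted k-class partition of a 1-D variable.

    ``bounds`` has length k+1: bounds[0] is the fitted minimum, bounds[i]
    for i ≥ 1 the maximum of class i−1 (the classic Jenks break values).
    Assignment is by v ≤ bounds[i+1], so ties at a break fall in the lower
    class; values outside the fitted range go to the nearest terminal class
    (with a warning logged).
    """

    bounds: np.ndarray
    k: int
    labels: tuple[str, ...] = ()
    within_ssd: float = 0.0

    def __post_init__(self) -> None:
        self.bounds = np.asarray(self.bounds, dtype=float)
        if len(self.bounds) != self.k + 1:
            raise ValueError("bounds must have length k + 1")
        if self.labels and len(self.labels) != self.k:
            raise ValueError("need one label per class")

    @property
    def breaks(self) -> np.ndarray:
        """The k−1 interior cut values."""
        return self.bounds[1:-1]


def _class_ssd_matrix(x: np.ndarray) -> np.ndarray:
    """ssd[i, j] = within-class SSD of sorted x[i..j] inclusive, via prefix sums."""
    n = len(x)
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    cnt = j - i + 1
    tot = s1[j + 1] - s1[i]
    sq = s2[j + 1] - s2[i]
    with np.errstate(invalid="ignore", divide="ignore"):
        ssd = sq - tot * tot / cnt
    return np.where(cnt >= 1, np.maximum(ssd, 0.0), np.inf)


def jenks_breaks(values, k: int) -> ClassificationScheme:
    """Fisher–Jenks optimal k-class partition of a numeric vector.

    Exact O(k·n²) dynamic programme minimising total within-class sum of
    squared deviations over contiguous partitions of the sorted sample.
    Deterministic: among equal-cost partitions the one with the earliest
    split points is returned.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = len(x)
    n_distinct = len(np.unique(x))
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_distinct < k:
        raise ValueError(f"need at least k={k} distinct values, got {n_distinct}")
    ssd = _class_ssd_matrix(x)
    # cost[c, j]: minimal SSD of splitting x[0..j] into c+1 classes
    cost = np.full((k, n), np.inf)
    split = np.zeros((k, n), dtype=int)  # first index of the last class
    cost[0] = ssd[0]
    for c in range(1, k):
        for j in range(c, n):
            cand = cost[c - 1, c - 1 : j] + ssd[c : j + 1, j]
            best = int(np.argmin(cand))
            cost[c, j] = cand[best]
            split[c, j] = best + c
    # backtrack class boundaries
    bounds = np.empty(k + 1)
    bounds[0], bounds[-1] = x[0], x[-1]
    j = n - 1
    starts = np.empty(k, dtype=int)
    for c in range(k - 1, -1, -1):
        i = split[c, j] if c > 0 else 0
        starts[c] = i
        j = i - 1
    for c in range(1, k):
        bounds[c] = x[starts[c] - 1]
    return ClassificationScheme(bounds=bounds, k=k, within_ssd=float(cost[k - 1, n - 1]))


def classify(values, scheme: ClassificationScheme) -> np.ndarray:
    """Assign each value its class index (0-based, ascending with value)."""
    v = np.asarray(values, dtype=float).ravel()
    below, above = v < scheme.bounds[0], v > scheme.bounds[-1]
    if below.any() or above.any():
        logger.warning(
            "%d value(s) outside fitted range [%g, %g]; assigned to terminal classes",
            int(below.sum() + above.sum()),
            scheme.bounds[0],
            scheme.bounds[-1],
        )
    # v <= bounds[i+1] puts break-value ties in the lower class
    idx = np.searchsorted(scheme.bounds[1:-1], v, side="left")
    return np.clip(idx, 0, scheme.k - 1)


def classify_labels(values, scheme: ClassificationScheme) -> np.ndarray:
    """Class labels for each value (requires a labelled scheme)."""
    if not scheme.labels:
        raise ValueError("scheme carries no labels")
    return np.asarray(scheme.labels, dtype=object)[classify(values, scheme)]


def _effective_k(values, k: int) -> int:
    """Collapse k to the number of distinct values when the sample is too
    coarse to support k classes (degenerate but classifiable input)."""
    n_distinct = len(np.unique(np.asarray(values, dtype=float)))
    if n_distinct < k:
        logger.warning(
            "only %d distinct value(s); reducing class count from %d", n_distinct, k
        )
        return n_distinct
    return k


def level_scheme(values, k: int = 5) -> ClassificationScheme:
    """Five-level (low … high) natural-breaks grading for supply or demand."""
    k = _effective_k(values, k)
    sch = jenks_breaks(values, k)
    if k == len(LEVEL_LABELS_5):
        labels = LEVEL_LABELS_5
    else:
        labels = tuple(f"level {i + 1}" for i in range(k))
    return ClassificationScheme(sch.bounds, k, labels, sch.within_ssd)


def _grade_name(j: int) -> str:
    """Name of the j-th class away from balance (1 = nearest)."""
    return _SIDE_GRADES[j - 1] if j <= 3 else f"high+{j - 3}"


def balance_scheme(bi_values, k: int = 7) -> ClassificationScheme:
    """Surplus/deficit typology: Jenks with k classes on BI, the class
    containing 0 (or nearest to 0) named "balance", classes above it surplus
    grades, below it deficit grades. All-equal input collapses to a single
    "balance" class."""
    k = _effective_k(bi_values, k)
    sch = jenks_breaks(bi_values, k)
    if sch.bounds[0] > 0:
        zero_class = 0
    elif sch.bounds[-1] < 0:
        zero_class = k - 1
    else:
        zero_class = int(classify(np.array([0.0]), sch)[0])
    labels = []
    for c in range(k):
        if c == zero_class:
            labels.append("balance")
        elif c > zero_class:
            labels.append(f"{_grade_name(c - zero_class)} surplus")
        else:
            labels.append(f"{_grade_name(zero_class - c)} deficit")
    return ClassificationScheme(sch.bounds, k, tuple(labels), sch.within_ssd)


def classify_balance_table(
    bi: pd.DataFrame,
    k_balance: int = 7,
    k_levels: int = 5,
    per_year: bool = True,
) -> pd.DataFrame:
    """Label every zone-year with supply level, demand level and balance class.

    ``per_year=True`` refits breaks within each year (year-by-year maps);
    ``False`` fits one scheme on all years pooled, for temporal comparability.
    """
    out = bi.copy()

    def _label(group: pd.DataFrame) -> pd.DataFrame:
        g = group.copy()
        g["supply_level"] = classify_labels(
            g["supply_scaled"], level_scheme(g["supply_scaled"], k_levels)
        )
        g["demand_level"] = classify_labels(
            g["demand_scaled"], level_scheme(g["demand_scaled"], k_levels)
        )
        g["balance_class"] = classify_labels(g["BI"], balance_scheme(g["BI"], k_balance))
        return g

    if per_year:
        parts = [_label(g) for _, g in out.groupby("year", sort=True)]
        return pd.concat(parts, ignore_index=True)
    return _label(out)
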