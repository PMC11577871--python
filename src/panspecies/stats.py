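"""Exact and asymptotic contingency-table statistics.

Fisher's exact test is implemented with the "sum of small p" two-sided
convention used by standard statistical software: the p-value is the total
probability, under the (multivariate) hypergeometric null with fixed
margins, of all tables whose probability does not exceed that of the
observed table (within a small relative slack to absorb floating-point
ties).  The r x c test enumerates all tables with the observed margins by
depth-first search; a seeded Monte Carlo estimator is available when the
enumeration space is too large.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2_contingency, hypergeom

from .delineation import ClusterPartition

__all__ = [
    "ContingencyTable",
    "FisherResult",
    "BgcFrequencyRow",
    "fisher_2x2",
    "fisher_rxc",
    "chisq_profile",
    "bgc_frequency_table",
]

_REL_SLACK = 1e-7  # relative tolerance for "no more probable than observed"


@dataclass
class ContingencyTable:
    """r x c non-negative integer counts with margins."""

    counts: np.ndarray
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = _validate_table(self.counts)

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _validate_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if not np.all(t == np.floor(t)):
        raise ValueError("counts must be integers")
    t = t.astype(np.int64)
    if t.sum() < 1:
        raise ValueError("table total must be >= 1")
    return t


def fisher_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Sums hypergeometric probabilities of every table with the observed
    margins that is no more probable than the observed one.
    """
    t = _validate_table(table)
    if t.shape != (2, 2):
        raise ValueError("fisher_2x2 requires a 2x2 table")
    a = int(t[0, 0])
    r1 = int(t[0].sum())
    c1 = int(t[:, 0].sum())
    N = int(t.sum())
    lo = max(0, r1 + c1 - N)
    hi = min(r1, c1)
    xs = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(xs, N, c1, r1)
    p_obs = hypergeom.pmf(a, N, c1, r1)
    p = float(pmf[pmf <= p_obs * (1 + _REL_SLACK)].sum())
    return min(1.0, max(p, np.finfo(float).tiny))


def _log_table_prob_const(row_m: np.ndarray, col_m: np.ndarray) -> float:
    N = row_m.sum()
    return float(
        gammaln(row_m + 1).sum() + gammaln(col_m + 1).sum() - gammaln(N + 1)
    )


@dataclass
class FisherResult:
    """p-value of an exact or Monte Carlo Fisher r x c test."""

    p: float
    method: str
    se: float | None = None
    n_draws: int | None = None

    def __float__(self) -> float:
        return self.p


def fisher_rxc(
    table,
    method: str = "exact",
    seed: int | None = None,
    max_tables: int = 10_000_000,
    n_draws: int = 100_000,
) -> FisherResult:
    """Fisher exact test on an r x c table.

    method='exact' enumerates all tables with the observed margins
    (multivariate hypergeometric) and sums the probabilities of those no
    more probable than the observed table; it errors if the enumeration
    exceeds ``max_tables``, instructing the caller to use Monte Carlo.
    method='montecarlo' draws ``n_draws`` margin-preserving tables with the
    given seed and reports the estimate with its standard error.
    """
    t = _validate_table(table)
    row_m = t.sum(axis=1)
    col_m = t.sum(axis=0)
    const = _log_table_prob_const(row_m, col_m)
    logp_obs = const - float(gammaln(t + 1).sum())
    cutoff = logp_obs + np.log1p(_REL_SLACK)

    if method == "exact":
        # the accumulator works with the margin-free part of the log
        # probability (-sum gammaln(cell+1)); shift the cutoff accordingly
        acc = _ExactAccumulator(row_m, col_m, cutoff - const, max_tables)
        acc.run()
        return FisherResult(p=min(1.0, float(np.exp(const) * acc.mass)), method="exact")
    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        hits = 0
        remaining_draws = n_draws
        batch = 20_000
        while remaining_draws > 0:
            b = min(batch, remaining_draws)
            logps = _sample_log_probs(row_m, col_m, const, b, rng)
            hits += int((logps <= cutoff).sum())
            remaining_draws -= b
        p = (hits + 1) / (n_draws + 1)
        se = float(np.sqrt(p * (1 - p) / n_draws))
        return FisherResult(p=p, method="montecarlo", se=se, n_draws=n_draws)
    raise ValueError("method must be 'exact' or 'montecarlo'")


class _ExactAccumulator:
    """DFS over tables with fixed margins, accumulating the extreme mass."""

    def __init__(self, row_m, col_m, log_cutoff, max_tables):
        self.row_m = np.asarray(row_m, dtype=np.int64)
        self.col_m = np.asarray(col_m, dtype=np.int64)
        self.log_cutoff = log_cutoff
        self.max_tables = max_tables
        self.mass = 0.0  # sum over extreme tables of exp(-sum gammaln(cell+1))
        self.visited = 0

    def run(self) -> None:
        self._fill_row(0, self.col_m.copy(), 0.0)

    def _fill_row(self, i: int, rem_cols: np.ndarray, neg_lgamma: float) -> None:
        r = len(self.row_m)
        if i == r - 1:
            # last row forced by the remaining column margins
            self.visited += 1
            if self.visited > self.max_tables:
                raise RuntimeError(
                    "exact enumeration bound exceeded; use method='montecarlo'"
                )
            logp = neg_lgamma - float(gammaln(rem_cols + 1).sum())
            if logp <= self.log_cutoff:
                self.mass += np.exp(logp)
            return
        self._fill_cell(i, 0, int(self.row_m[i]), rem_cols, neg_lgamma)

    def _fill_cell(self, i, j, rem_row, rem_cols, neg_lgamma) -> None:
        c = len(self.col_m)
        if j == c - 1:
            if rem_row <= rem_cols[j]:
                rem_cols[j] -= rem_row
                self._fill_row(i + 1, rem_cols, neg_lgamma - float(gammaln(rem_row + 1)))
                rem_cols[j] += rem_row
            return
        # cell value bounded by remaining row and column margins; also leave
        # enough for the rest of the row
        rest_capacity = int(rem_cols[j + 1 :].sum())
        lo = max(0, rem_row - rest_capacity)
        hi = min(rem_row, int(rem_cols[j]))
        for v in range(lo, hi + 1):
            rem_cols[j] -= v
            self._fill_cell(
                i, j + 1, rem_row - v, rem_cols, neg_lgamma - float(gammaln(v + 1))
            )
            rem_cols[j] += v


def _sample_log_probs(row_m, col_m, const, size, rng) -> np.ndarray:
    """Log-probabilities of margin-preserving tables sampled row by row."""
    r = len(row_m)
    out = np.full(size, const)
    for s in range(size):
        rem = col_m.copy()
        lg = 0.0
        for i in range(r - 1):
            row = rng.multivariate_hypergeometric(rem, int(row_m[i]))
            lg -= float(gammaln(np.asarray(row) + 1).sum())
            rem = rem - row
        lg -= float(gammaln(rem + 1).sum())
        out[s] += lg
    return out


def chisq_profile(counts_a, counts_b) -> tuple[float, int, float]:
    """Pearson chi-square comparing two category-count profiles.

    Builds the 2 x k table of the two profiles, drops categories empty in
    both, and returns (statistic, df, p) with df = k - 1 and no continuity
    correction.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be equal-length vectors")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    keep = (a + b) > 0
    a, b = a[keep], b[keep]
    if a.size == 0:
        raise ValueError("all categories are empty")
    if a.size == 1:
        return 0.0, 0, 1.0
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("one profile is entirely zero")
    stat, p, df, _ = chi2_contingency(np.vstack([a, b]), correction=False)
    return float(stat), int(df), float(p)


@dataclass
class BgcFrequencyRow:
    """Producer frequency of one metabolite across clusters.

    per_cluster maps cluster -> (producer count, cluster size, percent
    rounded to 2 decimals).  ``significant`` is False ("ns") when p > alpha.
    """

    metabolite: str
    per_cluster: dict[int, tuple[int, int, float]]
    p_value: float
    significant: bool


def bgc_frequency_table(
    bgc_counts: pd.DataFrame,
    partition: ClusterPartition,
    alpha: float = 0.05,
    method: str = "exact",
    seed: int | None = None,
    clusters: Sequence[int] | None = None,
) -> list[BgcFrequencyRow]:
    """Per-metabolite producer frequencies and Fisher tests across clusters.

    ``bgc_counts`` is a strains x metabolites count table; a strain is a
    producer of a metabolite iff its count is >= 1.  Each row carries the
    producer/non-producer by cluster Fisher exact p-value (r x c across all
    clusters, or restricted to ``clusters`` for a pairwise comparison).
    """
    unknown = [s for s in bgc_counts.index if s not in partition.labels]
    if unknown:
        raise ValueError(f"strains not in partition: {unknown}")
    use = sorted(set(partition.labels.values())) if clusters is None else list(clusters)
    sizes = {c: len(partition.members(c)) for c in use}
    rows: list[BgcFrequencyRow] = []
    for met in bgc_counts.columns:
        producers = bgc_counts[met] >= 1
        per_cluster: dict[int, tuple[int, int, float]] = {}
        table = np.zeros((2, len(use)), dtype=int)
        for k, c in enumerate(use):
            members = [s for s in bgc_counts.index if partition.labels[s] == c]
            count = int(producers.loc[members].sum())
            size = sizes[c]
            per_cluster[c] = (count, size, round(100.0 * count / size, 2))
            table[0, k] = count
            table[1, k] = size - count
        p = float(fisher_rxc(table, method=method, seed=seed))
        rows.append(
            BgcFrequencyRow(
                metabolite=str(met),
                per_cluster=per_cluster,
                p_value=p,
                significant=p <= alpha,
            )
        )
    return rows
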