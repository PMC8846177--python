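"""Exact tests on graft survival and junction-breakage count data.

The core routine is an r x c Fisher exact test (Freeman-Halton): conditioning
on the observed margins, every table with those margins is enumerated
recursively and the two-sided p-value is the total multivariate hypergeometric
probability of tables no more probable than the observed one — the convention
of standard statistical software, reducing to the classical two-sided 2x2
test. Tables too large to enumerate fall back to Monte-Carlo sampling of the
margin-conditional distribution. Pairwise column comparisons are summarized
with a compact letter display (greedy insert-and-absorb).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as importlib_resources
from math import lgamma
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTableError, InvalidConfigError

# Relative tolerance when comparing table probabilities to the observed one
# (tables with p <= p_obs * (1 + EPS) are counted, as in common software).
_REL_EPS = 1e-7

__all__ = [
    "ContingencyTable",
    "fisher_exact",
    "pairwise_fisher",
    "compact_letters",
    "two_sample_t",
    "load_breakage_counts",
]


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise InvalidConfigError("counts must be a 2-D table")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise InvalidConfigError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise InvalidConfigError("counts must be nonnegative")
        if len(self.row_labels) != self.counts.shape[0]:
            raise InvalidConfigError("row_labels length mismatch")
        if len(self.col_labels) != self.counts.shape[1]:
            raise InvalidConfigError("col_labels length mismatch")

    @classmethod
    def from_csv(cls, path: str | Path, row_label_col: str | None = None) -> "ContingencyTable":
        df = pd.read_csv(path, index_col=0, comment="#")
        return cls(df.to_numpy(), tuple(map(str, df.index)), tuple(map(str, df.columns)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.col_labels))


def _log_table_prob(table: np.ndarray, lg: np.vectorize | None = None) -> float:
    """Log multivariate hypergeometric probability given the table margins."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    N = table.sum()
    num = sum(lgamma(r + 1) for r in rows) + sum(lgamma(c + 1) for c in cols)
    den = lgamma(N + 1) + sum(lgamma(x + 1) for x in table.ravel())
    return num - den


def _enumerate_pvalue(counts: np.ndarray) -> float:
    """Exact two-sided p by recursive enumeration of margin-fixed tables."""
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    r, c = counts.shape
    logp_obs = _log_table_prob(counts)
    cutoff = logp_obs + np.log1p(_REL_EPS)
    # constant part of every table's log-probability
    const = (sum(lgamma(x + 1) for x in rows) + sum(lgamma(x + 1) for x in cols)
             - lgamma(counts.sum() + 1))
    total = 0.0

    col_rem = cols.astype(np.int64).copy()

    def rec(i: int, row_left: np.ndarray, acc_lfact: float) -> None:
        """Fill row i; acc_lfact = sum of lgamma(cell+1) filled so far."""
        nonlocal total
        if i == r - 1:
            # last row forced by column remainders
            lf = acc_lfact + sum(lgamma(x + 1) for x in col_rem)
            logp = const - lf
            if logp <= cutoff:
                total += np.exp(logp)
            return
        cells = np.zeros(c, dtype=np.int64)

        def fill(j: int, left: int, lf: float) -> None:
            if j == c - 1:
                if left > col_rem[j]:
                    return
                cells[j] = left
                col_rem[: c] -= cells
                if (col_rem >= 0).all():
                    rec(i + 1, row_left, acc_lfact + lf + lgamma(left + 1))
                col_rem[: c] += cells
                cells[j] = 0
                return
            hi = min(left, col_rem[j])
            for v in range(hi + 1):
                cells[j] = v
                fill(j + 1, left - v, lf + lgamma(v + 1))
            cells[j] = 0

        fill(0, int(rows[i]), 0.0)

    rec(0, rows, 0.0)
    return min(1.0, float(total))


def _monte_carlo_pvalue(counts: np.ndarray, n_draws: int, seed: int) -> float:
    """Margin-conditional Monte-Carlo estimate of the two-sided p-value."""
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    rng = np.random.default_rng(seed)
    row_of_unit = np.repeat(np.arange(len(rows)), rows)
    col_of_unit = np.repeat(np.arange(len(cols)), cols)
    logp_obs = _log_table_prob(counts)
    cutoff = logp_obs + np.log1p(_REL_EPS)
    hits = 0
    r, c = counts.shape
    for _ in range(n_draws):
        perm = rng.permutation(col_of_unit)
        table = np.zeros((r, c), dtype=np.int64)
        np.add.at(table, (row_of_unit, perm), 1)
        if _log_table_prob(table) <= cutoff:
            hits += 1
    return (hits + 1) / (n_draws + 1)


def fisher_exact(table: ContingencyTable | np.ndarray,
                 method: Literal["auto", "exact", "mc"] = "auto",
                 n_mc: int = 200_000, seed: int = 0) -> float:
    """Two-sided Fisher exact test for an r x c table."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    counts = counts.astype(np.int64)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise InvalidConfigError("need at least 2 rows and 2 columns")
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise DegenerateTableError("table has a zero margin")
    if method == "auto":
        method = "exact" if counts.sum() <= 200 and counts.size <= 16 else "mc"
    if method == "exact":
        return _enumerate_pvalue(counts)
    if method == "mc":
        return _monte_carlo_pvalue(counts, n_mc, seed)
    raise InvalidConfigError(f"unknown method {method!r}")


def compact_letters(labels: Sequence[str],
                    significant: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display via greedy insert-and-absorb.

    Groups start as one all-inclusive set; every significantly different pair
    splits the groups containing both, and redundant subset groups are
    absorbed. Letters are assigned in label order.
    """
    labels = list(labels)
    groups: list[set[str]] = [set(labels)]
    for a, b in sorted(significant):
        new_groups: list[set[str]] = []
        for g in groups:
            if a in g and b in g:
                new_groups.append(g - {a})
                new_groups.append(g - {b})
            else:
                new_groups.append(g)
        # absorb groups contained in another
        groups = [
            g for g in new_groups
            if g and not any(g < h for h in new_groups)
        ]
        # deduplicate
        unique: list[set[str]] = []
        for g in groups:
            if g not in unique:
                unique.append(g)
        groups = unique
    groups.sort(key=lambda g: min(labels.index(x) for x in g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lab: "" for lab in labels}
    for i, g in enumerate(groups):
        for lab in g:
            letters[lab] += alphabet[i % len(alphabet)]
    return letters


@dataclass
class PairwiseFisherResult:
    p_matrix: pd.DataFrame
    letters: dict[str, str]
    adjusted: bool


def pairwise_fisher(table: ContingencyTable, alpha: float = 0.05,
                    adjust: Literal[None, "holm"] = None) -> PairwiseFisherResult:
    """2x2 (r x 2) Fisher tests for every column pair plus grouping letters.

    Raw p-values by default (Holm adjustment available); letters summarize
    which graft combinations differ at ``alpha``.
    """
    cols = list(table.col_labels)
    if len(cols) < 2:
        raise InvalidConfigError("pairwise comparison needs >=2 columns")
    k = len(cols)
    P = np.ones((k, k))
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    raw = []
    for i, j in pairs:
        sub = table.counts[:, [i, j]]
        raw.append(fisher_exact(ContingencyTable(
            sub, table.row_labels, (cols[i], cols[j]))))
    pvals = np.array(raw)
    if adjust == "holm":
        from statsmodels.stats.multitest import multipletests

        pvals = multipletests(pvals, method="holm")[1]
    elif adjust is not None:
        raise InvalidConfigError(f"unknown adjustment {adjust!r}")
    for (i, j), p in zip(pairs, pvals):
        P[i, j] = P[j, i] = p
    p_matrix = pd.DataFrame(P, index=cols, columns=cols)
    significant = {
        (cols[i], cols[j]) for (i, j), p in zip(pairs, pvals) if p < alpha
    }
    return PairwiseFisherResult(p_matrix, compact_letters(cols, significant),
                                adjust is not None)


def two_sample_t(a: Sequence[float], b: Sequence[float],
                 equal_var: bool = False) -> tuple[float, float]:
    """Thin two-sample t-test utility for continuous morphometrics."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                          equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def load_breakage_counts() -> ContingencyTable:
    """Junction bend-test counts reconstructed from the published breakage
    percentages (0%, 6%, 75%, 92%) and group sizes for the four graft
    combinations; see datasets/junction_break_counts.csv."""
    ref = importlib_resources.files("graftgrn") / "datasets" / "junction_break_counts.csv"
    with importlib_resources.as_file(ref) as path:
        return ContingencyTable.from_csv(path)
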