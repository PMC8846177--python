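"""Modified-Shannon-entropy (MSE) selection of sample-specific outlier genes.

A two-stage selector for genes whose expression is concentrated in a few
samples. Stage one computes the Shannon entropy (bits) of each gene's
normalized expression profile, p_i = x_i / sum(x); genes with entropy below a
fraction (default 30%) of the maximum log2(m) are kept — low entropy means
high profile variation. Stage two enumerates every outlier/nonoutlier
assignment of the gene's m values and picks the one minimizing

    U = n * ln(sigma) + 2 * s * ln(n!) / n

where s and n count outlier and nonoutlier candidates and sigma is the sample
standard deviation (n - 1 denominator) of the nonoutlier values. Assignments
need n >= 2 and sigma > 0 to be valid. By default only high-side assignments
are considered (every outlier value at least as large as every nonoutlier
value — an outlier flag marks a sample where the gene is upregulated);
``direction="both"`` enumerates all 2^m assignments. Selected genes can then
be filtered by a user-chosen outlier/nonoutlier pattern over named samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, MissingSampleError, NoValidPartitionError

MAX_EXHAUSTIVE_SAMPLES = 20

__all__ = [
    "MSEResult",
    "entropy_score",
    "select_low_entropy",
    "best_outlier_assignment",
    "mse_analysis",
    "select_by_pattern",
]


@dataclass
class MSEResult:
    gene_id: str
    entropy: float
    selected: bool
    partition: tuple[int, ...] | None  # 1 = outlier, 0 = nonoutlier
    s: int | None
    n: int | None
    sigma: float | None
    u: float | None


def entropy_score(values: Sequence[float]) -> float:
    """Shannon entropy (bits) of the value profile; 0*log0 := 0."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise InvalidConfigError("entropy requires nonnegative values")
    total = arr.sum()
    if total == 0:
        raise InvalidConfigError("entropy undefined for an all-zero profile")
    p = arr / total
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def select_low_entropy(entropies: Mapping[str, float], n_samples: int,
                       fraction: float = 0.30) -> list[str]:
    """Genes with entropy strictly below ``fraction`` of the maximum log2(m)."""
    if n_samples < 2:
        raise InvalidConfigError("need at least 2 samples")
    cutoff = fraction * np.log2(n_samples)
    return sorted(g for g, h in entropies.items() if h < cutoff)


def _assignment_stats(values: np.ndarray, masks: np.ndarray):
    """Vectorized (s, n, sigma, U) for a boolean outlier-mask matrix."""
    m = values.size
    s = masks.sum(axis=1)
    n = m - s
    keep = ~masks
    centered = values - values.mean()  # sigma is translation-invariant
    sums = keep @ centered
    sumsq = keep @ (centered**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (sumsq - sums**2 / np.maximum(n, 1)) / np.maximum(n - 1, 1)
    var = np.maximum(var, 0.0)
    sigma = np.sqrt(var)
    lognf = np.array([lgamma(k + 1) for k in range(m + 1)])
    with np.errstate(divide="ignore", invalid="ignore"):
        u = n * np.log(sigma) + 2.0 * s * lognf[n] / np.maximum(n, 1)
    valid = (n >= 2) & (sigma > 0)
    return s, n, sigma, np.where(valid, u, np.inf), valid


def best_outlier_assignment(
    values: Sequence[float],
    direction: Literal["high", "both"] = "high",
    max_samples: int = MAX_EXHAUSTIVE_SAMPLES,
) -> tuple[tuple[int, ...], float]:
    """Exhaustively minimize U over outlier/nonoutlier assignments.

    Returns (partition, U) where partition[i] = 1 flags sample i as an
    outlier. Ties break toward fewer outliers, then lexicographically smaller
    partitions. Raises when no assignment has n >= 2 nonoutliers with
    positive spread.
    """
    arr = np.asarray(values, dtype=float)
    m = arr.size
    if m < 2:
        raise InvalidConfigError("need at least 2 samples")
    if m > max_samples:
        raise InvalidConfigError(
            f"exhaustive search capped at {max_samples} samples (got {m})"
        )
    codes = np.arange(2**m, dtype=np.int64)
    masks = ((codes[:, None] >> np.arange(m)) & 1).astype(bool)
    if direction == "high":
        # outliers must sit at or above every nonoutlier value
        allowed = np.where(masks, arr, np.inf).min(axis=1) >= np.where(
            ~masks, arr, -np.inf
        ).max(axis=1)
        allowed |= masks.sum(axis=1) == 0
        masks = masks[allowed]
    elif direction != "both":
        raise InvalidConfigError(f"unknown direction {direction!r}")
    s, n, sigma, u, valid = _assignment_stats(arr, masks)
    if not valid.any():
        raise NoValidPartitionError(
            "no assignment has >=2 nonoutliers with positive spread"
        )
    # the single-pass spread estimate can lose ~1e-8 of precision when the
    # nonoutliers nearly coincide; re-evaluate the near-minimal assignments
    # with an exact two-pass computation before the final tie-break
    u_min = u[valid].min()
    near = np.flatnonzero(valid & (u <= u_min + 1e-6))
    lognf = [lgamma(k + 1) for k in range(m + 1)]

    def exact_u(i: int) -> float:
        non = arr[~masks[i]]
        sig = float(np.std(non, ddof=1))
        return non.size * np.log(sig) + 2.0 * s[i] * lognf[non.size] / non.size

    best = min(near, key=lambda i: (exact_u(i), s[i], tuple(masks[i].astype(int))))
    return tuple(int(x) for x in masks[best]), float(exact_u(best))


def mse_analysis(values: pd.DataFrame, fraction: float = 0.30,
                 direction: Literal["high", "both"] = "high") -> pd.DataFrame:
    """Entropy gate + exhaustive assignment for every gene in a gene x sample
    table (typically reference-normalized expression).

    Returns one row per gene: entropy, selection flag, per-sample 0/1 outlier
    flags (empty string for unselected genes), s, n, sigma, U.
    """
    m = values.shape[1]
    rows = []
    for gene, row in values.iterrows():
        arr = row.to_numpy(dtype=float)
        if arr.sum() == 0:
            continue
        h = entropy_score(arr)
        selected = h < fraction * np.log2(m)
        rec = {"gene": gene, "entropy": h, "selected": selected,
               "partition": "", "s": np.nan, "n": np.nan,
               "sigma": np.nan, "u": np.nan}
        if selected:
            try:
                partition, u = best_outlier_assignment(arr, direction=direction)
            except NoValidPartitionError:
                rec["selected"] = False
            else:
                s = sum(partition)
                non = arr[np.array(partition) == 0]
                rec.update(
                    partition="".join(str(b) for b in partition),
                    s=s, n=m - s,
                    sigma=float(np.std(non, ddof=1)),
                    u=u,
                )
        rows.append(rec)
    return pd.DataFrame(rows).set_index("gene")


def select_by_pattern(results: pd.DataFrame, sample_ids: Sequence[str],
                      required_outlier_samples: Iterable[str] = (),
                      required_nonoutlier_samples: Iterable[str] = ()) -> list[str]:
    """Genes whose best partition is 1 at every required outlier sample and 0
    at every required nonoutlier sample. Empty requirements return all genes
    with a computed partition."""
    sample_ids = list(sample_ids)
    pos = {s: i for i, s in enumerate(sample_ids)}
    req_out = list(required_outlier_samples)
    req_non = list(required_nonoutlier_samples)
    for s in req_out + req_non:
        if s not in pos:
            raise MissingSampleError(f"unknown sample ID {s!r}")
    hits = []
    for gene, row in results.iterrows():
        part = row["partition"]
        if not isinstance(part, str) or len(part) != len(sample_ids):
            continue
        if all(part[pos[s]] == "1" for s in req_out) and all(
            part[pos[s]] == "0" for s in req_non
        ):
            hits.append(gene)
    return hits
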