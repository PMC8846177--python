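"""Expression-level processing for the graft time course.

This module holds the FPKM-scale expression container and the stages that act
directly on it: reference normalization, min-max scaling, PCA-based quality
control, pairwise differential-expression testing between days after grafting
(DAG), threshold-based DEG selection with timepoint assignment, and k-means
clustering of scaled DEG profiles.

The differential-expression test is a Welch two-sample test on log2(FPKM + 1)
per gene with Benjamini-Hochberg adjustment within each pairwise comparison.
A gene is called a DEG when any comparison passes both the FDR and the |log2
fold change| thresholds, and it is assigned to every timepoint at which it is
the upregulated side of a passing comparison (set semantics; a gene may belong
to several timepoints).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, InvalidConfigError, MissingSampleError

PSEUDOCOUNT = 1.0
REFERENCE_FLOOR = 0.01

__all__ = [
    "ExpressionMatrix",
    "NormalizedExpression",
    "PCAResult",
    "read_expression",
    "write_expression",
    "normalize_to_reference",
    "minmax_scale",
    "pca_qc",
    "pairwise_de",
    "select_degs",
    "shared_deg_fraction",
    "cluster_deg_profiles",
]


@dataclass
class ExpressionMatrix:
    """Nonnegative gene x sample expression values plus per-sample design.

    ``values`` is a genes-as-rows DataFrame whose columns are sample IDs of
    the form ``<combination>_<timepoint>d_r<replicate>``; ``sample_meta`` is
    indexed by those IDs with columns ``combination``, ``timepoint``,
    ``replicate``. Gene species (tomato-like vs pepper-like) is carried by the
    gene ID prefix (``Sl``/``Ca``).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise InvalidConfigError("gene IDs must be unique")
        if (self.values.to_numpy() < 0).any():
            raise InvalidConfigError("expression values must be nonnegative")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise InvalidConfigError(f"samples lack metadata: {sorted(missing)}")
        for col in ("combination", "timepoint", "replicate"):
            if col not in self.sample_meta.columns:
                raise InvalidConfigError(f"sample_meta missing column {col!r}")
            if self.sample_meta.loc[list(self.values.columns), col].isna().any():
                raise InvalidConfigError(f"sample_meta column {col!r} has missing entries")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def gene_species(self) -> pd.Series:
        """Species-of-gene inferred from the ID prefix before the underscore."""
        return pd.Series(
            [g.split("_", 1)[0] for g in self.values.index], index=self.values.index
        )

    def samples_where(self, **criteria) -> list[str]:
        """Sample IDs whose metadata match all keyword criteria."""
        meta = self.sample_meta.loc[list(self.values.columns)]
        mask = np.ones(len(meta), dtype=bool)
        for key, val in criteria.items():
            mask &= (meta[key] == val).to_numpy()
        return list(meta.index[mask])

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.sample_meta)

    def replicate_means(self, condition: str | None = None) -> pd.DataFrame:
        """Per-gene mean profile over timepoints (columns ordered by DAG)."""
        meta = self.sample_meta.loc[list(self.values.columns)]
        if condition is not None:
            cols = meta.index[meta["combination"] == condition]
        else:
            cols = meta.index
        grouped = self.values[list(cols)].T.groupby(
            meta.loc[cols, "timepoint"].to_numpy()
        )
        return grouped.mean().T.sort_index(axis=1)


@dataclass
class NormalizedExpression:
    """Reference-normalized matrix plus genes whose reference value hit the floor."""

    matrix: ExpressionMatrix
    flagged_genes: tuple[str, ...]


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    variance_fractions: np.ndarray


def write_expression(matrix: ExpressionMatrix, expr_path: str | Path,
                     design_path: str | Path | None = None) -> None:
    expr_path = Path(expr_path)
    matrix.values.to_csv(expr_path, sep="\t", index_label="gene", float_format="%.10g")
    if design_path is None:
        design_path = expr_path.with_name(expr_path.stem + ".design.tsv")
    meta = matrix.sample_meta.loc[list(matrix.values.columns)]
    meta.to_csv(design_path, sep="\t", index_label="sample")


def read_expression(expr_path: str | Path,
                    design_path: str | Path | None = None) -> ExpressionMatrix:
    expr_path = Path(expr_path)
    values = pd.read_csv(expr_path, sep="\t", index_col="gene", comment="#")
    values.index.name = None
    if design_path is None:
        design_path = expr_path.with_name(expr_path.stem + ".design.tsv")
    meta = pd.read_csv(design_path, sep="\t", index_col="sample", comment="#")
    return ExpressionMatrix(values, meta)


def normalize_to_reference(matrix: ExpressionMatrix, reference_sample_id: str,
                           floor: float = REFERENCE_FLOOR) -> NormalizedExpression:
    """Divide every gene by its value in the reference sample.

    Genes whose reference value is at or below ``floor`` are divided by the
    floor instead and reported as flagged, so that ratios stay finite.
    """
    if reference_sample_id not in matrix.values.columns:
        raise MissingSampleError(f"reference sample {reference_sample_id!r} not found")
    ref = matrix.values[reference_sample_id].to_numpy(dtype=float)
    flagged = ref <= floor
    denom = np.where(flagged, floor, ref)
    normalized = matrix.values.div(pd.Series(denom, index=matrix.values.index), axis=0)
    out = ExpressionMatrix(normalized, matrix.sample_meta)
    return NormalizedExpression(out, tuple(matrix.values.index[flagged]))


def minmax_scale(values):
    """Map values linearly onto [0, 1]; constant vectors map to all zeros.

    Accepts a 1-D array/Series or a DataFrame (scaled per row / per gene).
    """
    if isinstance(values, pd.DataFrame):
        arr = values.to_numpy(dtype=float)
        lo = arr.min(axis=1, keepdims=True)
        span = arr.max(axis=1, keepdims=True) - lo
        out = np.where(span > 0, (arr - lo) / np.where(span == 0, 1.0, span), 0.0)
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    arr = np.asarray(values, dtype=float)
    if arr.size == 0 or not np.isfinite(arr).any():
        raise InsufficientDataError("min-max scaling needs at least one finite value")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def pca_qc(matrix: ExpressionMatrix) -> PCAResult:
    """Centered SVD-based PCA of samples for replicate/grouping QC."""
    X = matrix.values.to_numpy(dtype=float).T  # samples x genes
    if X.shape[0] < 2:
        raise InsufficientDataError("PCA requires at least 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    fractions = var / total if total > 0 else np.zeros_like(var)
    scores = pd.DataFrame(
        U * s,
        index=matrix.values.columns,
        columns=[f"PC{i + 1}" for i in range(len(s))],
    )
    return PCAResult(scores, fractions)


def _welch_log2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized Welch test p-values on log2(x + 1); rows are genes."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(b, a, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    # Zero variance in both groups: p=1 when means agree, else a certain call.
    nan = ~np.isfinite(p)
    if nan.any():
        same = np.isclose(a[nan].mean(axis=1), b[nan].mean(axis=1))
        p[nan] = np.where(same, 1.0, 0.0)
    return p


def pairwise_de(matrix: ExpressionMatrix, t_a: int, t_b: int, condition: str,
                pseudocount: float = PSEUDOCOUNT) -> pd.DataFrame:
    """Differential expression between two DAG timepoints within a condition.

    Returns one row per gene with columns (gene, comparison, log2fc, p, fdr,
    direction, up_timepoint). ``log2fc`` is t_b relative to t_a on replicate
    means with a pseudocount; ``up_timepoint`` is the timepoint with the
    higher mean, i.e. the side the gene would be assigned to if it passes.
    """
    cols_a = matrix.samples_where(combination=condition, timepoint=t_a)
    cols_b = matrix.samples_where(combination=condition, timepoint=t_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise InsufficientDataError(
            f"pairwise DE needs >=2 replicates per timepoint in {condition!r} "
            f"(got {len(cols_a)} at {t_a} DAG, {len(cols_b)} at {t_b} DAG)"
        )
    A = matrix.values[cols_a].to_numpy(dtype=float)
    B = matrix.values[cols_b].to_numpy(dtype=float)
    log2fc = np.log2(B.mean(axis=1) + pseudocount) - np.log2(A.mean(axis=1) + pseudocount)
    p = _welch_log2(np.log2(A + pseudocount), np.log2(B + pseudocount))
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": matrix.gene_ids,
            "comparison": f"{t_a}v{t_b}",
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "direction": np.where(log2fc >= 0, "up", "down"),
            "up_timepoint": np.where(log2fc >= 0, t_b, t_a),
        }
    )


def select_degs(records: pd.DataFrame, fdr_max: float = 0.05,
                abs_log2fc_min: float = 2.0) -> dict[int, set[str]]:
    """Per-timepoint DEG sets from the pooled pairwise comparisons.

    A comparison passes when fdr < ``fdr_max`` and |log2fc| > ``abs_log2fc_min``
    (both strict, matching the published thresholds FDR <0.05 and log2 FC >2 or
    <-2). A passing gene is assigned to the upregulated timepoint of every
    passing comparison.
    """
    passing = records[(records["fdr"] < fdr_max) & (records["log2fc"].abs() > abs_log2fc_min)]
    sets: dict[int, set[str]] = {}
    for t, sub in passing.groupby("up_timepoint"):
        sets[int(t)] = set(sub["gene"])
    return sets


def shared_deg_fraction(deg_sets: Mapping[int, set[str]] | Sequence[set[str]]) -> float:
    """Percentage of DEGs (union) present in at least two timepoint sets."""
    sets = list(deg_sets.values()) if isinstance(deg_sets, Mapping) else list(deg_sets)
    if len(sets) < 2:
        raise InsufficientDataError("shared fraction needs at least 2 DEG sets")
    union: set[str] = set().union(*sets)
    if not union:
        warnings.warn("all DEG sets are empty; shared fraction reported as 0")
        return 0.0
    counts: dict[str, int] = {}
    for s in sets:
        for g in s:
            counts[g] = counts.get(g, 0) + 1
    shared = sum(1 for c in counts.values() if c >= 2)
    return 100.0 * shared / len(union)


def cluster_deg_profiles(profiles: pd.DataFrame, k: int = 9, seed: int = 0) -> pd.Series:
    """K-means labels (1..k) for min-max scaled DEG mean profiles."""
    if k < 2:
        raise InvalidConfigError("k must be >= 2")
    if k > len(profiles):
        raise InvalidConfigError(f"k={k} exceeds the number of genes ({len(profiles)})")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(profiles.to_numpy(dtype=float))
    return pd.Series(labels + 1, index=profiles.index, name="cluster")
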