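"""Per-timepoint regulatory network inference from TFs to selected genes.

Two engines share one interface contract (TF-only sources, per-timepoint
target sets, full time-course expression, correlation-based edge signs):

* a dynamic-Bayesian-network-style scorer: expression is discretized into a
  small number of states by one-dimensional k-means, candidate regulators are
  scored by mutual information (MI) against the target's states across samples
  aligned with a configurable time lapse (0 = contemporaneous), and edges are
  kept when the score exceeds the (1 - alpha) quantile of a seeded permutation
  null, up to a per-target parent limit;

* a tree-ensemble importance scorer (GENIE3-style): each target is regressed
  on all TFs with a random forest, importances are averaged over seeded
  iterations, and edges are kept by a mean + 1 SD rule on the target's
  importance vector.

Edge signs come from the Pearson correlation of the pair's replicate-mean
time profiles; weights are the engine scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestRegressor

from .errors import InvalidConfigError

__all__ = [
    "InferenceConfig",
    "NetworkEdge",
    "RegulatoryNetwork",
    "discretize_expression",
    "dbn_score_matrix",
    "rf_importance_matrix",
    "infer_dbn_network",
    "infer_rf_network",
    "union_networks",
    "write_sif",
    "read_sif",
]


@dataclass(frozen=True)
class InferenceConfig:
    time_lapse: int = 0
    discretization_levels: int = 3
    permutations: int = 100
    alpha: float = 0.05
    max_parents: int = 2
    # candidates examined in the greedy conditional stage (top scorers among
    # those passing the marginal permutation gate)
    candidate_pool: int = 10
    rf_iterations: int = 10
    rf_trees: int = 50
    edge_keep_rule: Literal["mean_plus_sd"] = "mean_plus_sd"
    seed: int = 0

    def validate(self) -> None:
        if self.permutations < 1:
            raise InvalidConfigError("permutations must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise InvalidConfigError("alpha must be in (0, 1)")
        if self.discretization_levels < 2:
            raise InvalidConfigError("discretization_levels must be >= 2")
        if self.time_lapse < 0:
            raise InvalidConfigError("time_lapse must be >= 0")


@dataclass(frozen=True)
class NetworkEdge:
    source: str
    target: str
    timepoints: frozenset[int]
    sign: int
    weight: float

    @property
    def label(self) -> str:
        return " and ".join(str(t) for t in sorted(self.timepoints)) + " DAG"


@dataclass
class RegulatoryNetwork:
    """Directed signed TF -> target edges with timepoint labels."""

    edges: tuple[NetworkEdge, ...]
    tf_ids: frozenset[str]
    family_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, frozenset[int]]] = set()
        for e in self.edges:
            if e.source == e.target:
                raise InvalidConfigError("self-edges are not allowed")
            if e.source not in self.tf_ids:
                raise InvalidConfigError(f"source {e.source!r} is not a TF")
            key = (e.source, e.target, e.timepoints)
            if key in seen:
                raise InvalidConfigError(f"duplicate edge {key}")
            seen.add(key)

    def outdegree(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.edges:
            out[e.source] = out.get(e.source, 0) + 1
        return out

    def nodes(self) -> set[str]:
        return {e.source for e in self.edges} | {e.target for e in self.edges}

    def targets_of(self, tf: str) -> set[str]:
        return {e.target for e in self.edges if e.source == tf}


def discretize_expression(values: Sequence[float], levels: int = 3,
                          seed: int = 0) -> np.ndarray:
    """1-D k-means states in {0..levels-1}, ordered by cluster center."""
    arr = np.asarray(values, dtype=float)
    distinct = np.unique(arr)
    if distinct.size == 1:
        return np.zeros(arr.shape, dtype=int)
    k = min(levels, distinct.size)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(arr.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[km.labels_]


def _states_matrix(matrix, genes: Sequence[str], samples: Sequence[str],
                   levels: int, seed: int) -> np.ndarray:
    vals = matrix.values.loc[list(genes), list(samples)].to_numpy(dtype=float)
    logv = np.log2(vals + 1.0)
    return np.vstack([discretize_expression(row, levels, seed) for row in logv])


def _mi_vs_all(tf_states: np.ndarray, y: np.ndarray, levels: int,
               y_levels: int | None = None) -> np.ndarray:
    """Plugin mutual information (nats) between each TF state row and y."""
    if y_levels is None:
        y_levels = levels
    m, n = tf_states.shape
    joint_idx = tf_states * y_levels + y  # (m, n)
    offs = np.arange(m)[:, None] * levels * y_levels
    counts = np.bincount((joint_idx + offs).ravel(), minlength=m * levels * y_levels)
    counts = counts.reshape(m, levels, y_levels).astype(float)
    p = counts / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * (np.log(p) - np.log(px) - np.log(py))
    return np.where(counts > 0, terms, 0.0).sum(axis=(1, 2))


def _cmi_vs_rows(y_rows: np.ndarray, x: np.ndarray, cells: np.ndarray,
                 levels: int, n_cells: int) -> np.ndarray:
    """I(x; y | cells) for each row of ``y_rows`` (chain rule, vectorized):
    I(x; y | c) = I((x, c); y) - I(c; y)."""
    xc = cells * levels + x
    return (_mi_vs_all(y_rows, xc, levels, n_cells * levels)
            - _mi_vs_all(y_rows, cells, levels, n_cells))


def _profile_signs(matrix, sources: Sequence[str], targets: Sequence[str]) -> pd.DataFrame:
    """Sign of the Pearson correlation between replicate-mean time profiles."""
    prof = matrix.replicate_means()
    P = prof.loc[list(dict.fromkeys(list(sources) + list(targets)))]
    X = P.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((Xc**2).sum(axis=1))
    norm[norm == 0] = 1.0
    Xn = Xc / norm[:, None]
    corr = pd.DataFrame(Xn @ Xn.T, index=P.index, columns=P.index)
    signs = np.where(corr.loc[list(sources), list(targets)].to_numpy() >= 0, 1, -1)
    return pd.DataFrame(signs, index=list(sources), columns=list(targets))


def _sample_correlations(matrix, sources: Sequence[str], targets: Sequence[str],
                         src_samples: Sequence[str], tgt_samples: Sequence[str]
                         ) -> np.ndarray:
    """|Pearson| between log-expression sample vectors (TFs x targets)."""
    A = np.log2(matrix.values.loc[list(sources), list(src_samples)]
                .to_numpy(dtype=float) + 1.0)
    B = np.log2(matrix.values.loc[list(targets), list(tgt_samples)]
                .to_numpy(dtype=float) + 1.0)
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    return np.abs((A / na[:, None]) @ (B / nb[:, None]).T)


def _lagged_samples(matrix, lag: int) -> tuple[list[str], list[str]]:
    """Source/target sample alignments for a given time lapse.

    With lag 0 both lists are all samples in time order. With lag L, source
    samples at timepoint index i pair with target samples at index i + L
    (matched by replicate); boundary timepoints are dropped.
    """
    meta = matrix.sample_meta.loc[list(matrix.values.columns)]
    tps = sorted(meta["timepoint"].unique())
    by_tr = {
        (t, r): s
        for s, t, r in zip(meta.index, meta["timepoint"], meta["replicate"])
    }
    src, tgt = [], []
    for i, t in enumerate(tps):
        j = i + lag
        if j >= len(tps):
            break
        for r in sorted(meta.loc[meta["timepoint"] == t, "replicate"]):
            key_t = (tps[j], r)
            if key_t in by_tr:
                src.append(by_tr[(t, r)])
                tgt.append(by_tr[key_t])
    return src, tgt


def dbn_score_matrix(matrix, targets: Sequence[str], tf_sources: Sequence[str],
                     config: InferenceConfig = InferenceConfig()) -> pd.DataFrame:
    """MI scores (rows = TFs, columns = targets) on discretized states."""
    config.validate()
    src_samples, tgt_samples = _lagged_samples(matrix, config.time_lapse)
    levels = config.discretization_levels
    S = _states_matrix(matrix, tf_sources, src_samples, levels, config.seed)
    T = _states_matrix(matrix, targets, tgt_samples, levels, config.seed)
    scores = np.empty((len(tf_sources), len(targets)))
    for j in range(len(targets)):
        scores[:, j] = _mi_vs_all(S, T[j], levels)
    return pd.DataFrame(scores, index=list(tf_sources), columns=list(targets))


def infer_dbn_network(matrix, targets: Sequence[str], tf_sources: Sequence[str],
                      timepoint: int,
                      config: InferenceConfig = InferenceConfig()) -> RegulatoryNetwork:
    """DBN-style network for one timepoint's target set.

    For each target, every candidate TF is scored by MI on discretized states
    across the lag-aligned samples of the full time course. TFs whose score
    exceeds the (1 - alpha) quantile of a permutation null (target states
    permuted, pooled over candidate TFs) are admitted greedily in score order
    (ties broken by the |Pearson| correlation of the log sample vectors): the
    first parent on its marginal MI, each further parent only when its
    conditional MI given the already-accepted parents' states also beats a
    within-cell permutation null, up to ``max_parents`` per target. The
    conditional step keeps a redundant TF from re-entering through signal
    already explained by an accepted parent.
    """
    config.validate()
    targets = list(targets)
    tf_sources = list(tf_sources)
    if not targets or not tf_sources or matrix.values.shape[1] == 0:
        import warnings

        warnings.warn(f"no data to infer a network at {timepoint} DAG")
        return RegulatoryNetwork((), frozenset(tf_sources))
    src_samples, tgt_samples = _lagged_samples(matrix, config.time_lapse)
    levels = config.discretization_levels
    S = _states_matrix(matrix, tf_sources, src_samples, levels, config.seed)
    T = _states_matrix(matrix, targets, tgt_samples, levels, config.seed)
    signs = _profile_signs(matrix, tf_sources, targets)
    rho = _sample_correlations(matrix, tf_sources, targets, src_samples, tgt_samples)
    tf_index = {tf: i for i, tf in enumerate(tf_sources)}
    edges: list[NetworkEdge] = []
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11, timepoint]))
    n = S.shape[1]
    for j, tgt in enumerate(targets):
        cand = [i for tf, i in tf_index.items() if tf != tgt]
        if not cand:
            continue
        Sc = S[cand]
        y = T[j]
        obs = _mi_vs_all(Sc, y, levels)
        null = np.empty((config.permutations, len(cand)))
        for b in range(config.permutations):
            null[b] = _mi_vs_all(Sc, y[rng.permutation(n)], levels)
        threshold = np.quantile(null.ravel(), 1.0 - config.alpha)
        passing = [k for k in range(len(cand)) if obs[k] > threshold]
        passing.sort(key=lambda k: (-obs[k], -rho[cand[k], j], tf_sources[cand[k]]))
        passing = passing[: config.candidate_pool]
        parents: list[int] = []
        for k in passing:
            if len(parents) >= config.max_parents:
                break
            if not parents:
                parents.append(k)
                continue
            cells = np.zeros(n, dtype=np.int64)
            for p in parents:
                cells = cells * levels + Sc[p]
            # compact cell labels so cardinalities stay small
            _, cells = np.unique(cells, return_inverse=True)
            n_cells = int(cells.max()) + 1
            cmi_obs = _cmi_vs_rows(y[None, :], Sc[k], cells, levels, n_cells)[0]
            # null: y permuted within conditioning cells, all draws at once
            yp = np.tile(y, (config.permutations, 1))
            for c in range(n_cells):
                sel = np.flatnonzero(cells == c)
                if sel.size > 1:
                    block = rng.permuted(
                        np.tile(sel, (config.permutations, 1)), axis=1
                    )
                    yp[:, sel] = y[block]
            cmi_null = _cmi_vs_rows(yp, Sc[k], cells, levels, n_cells)
            if cmi_obs > np.quantile(cmi_null, 1.0 - config.alpha):
                parents.append(k)
        for k in parents:
            tf = tf_sources[cand[k]]
            edges.append(
                NetworkEdge(
                    source=tf,
                    target=tgt,
                    timepoints=frozenset([timepoint]),
                    sign=int(signs.loc[tf, tgt]),
                    weight=float(obs[k]),
                )
            )
    return RegulatoryNetwork(tuple(edges), frozenset(tf_sources))


def rf_importance_matrix(matrix, targets: Sequence[str], tf_sources: Sequence[str],
                         config: InferenceConfig = InferenceConfig()) -> pd.DataFrame:
    """Random-forest importances (rows = TFs, columns = targets), averaged
    over ``rf_iterations`` seeded forests per target."""
    config.validate()
    samples = list(matrix.values.columns)
    logv = np.log2(matrix.values.loc[list(tf_sources) + list(targets), samples]
                   .to_numpy(dtype=float) + 1.0)
    X_all = logv[: len(tf_sources)].T  # samples x TFs
    imp = np.zeros((len(tf_sources), len(targets)))
    tf_pos = {tf: i for i, tf in enumerate(tf_sources)}
    for j, tgt in enumerate(targets):
        y = logv[len(tf_sources) + j]
        self_i = tf_pos.get(tgt)
        cols = [i for i in range(len(tf_sources)) if i != self_i]
        X = X_all[:, cols]
        acc = np.zeros(len(cols))
        for it in range(config.rf_iterations):
            rf = RandomForestRegressor(
                n_estimators=config.rf_trees,
                max_features="sqrt",
                random_state=config.seed * 10007 + it * 101 + j,
            )
            rf.fit(X, y)
            acc += rf.feature_importances_
        imp[cols, j] = acc / config.rf_iterations
    return pd.DataFrame(imp, index=list(tf_sources), columns=list(targets))


def infer_rf_network(matrix, targets: Sequence[str], tf_sources: Sequence[str],
                     timepoint: int,
                     config: InferenceConfig = InferenceConfig()) -> RegulatoryNetwork:
    """Tree-ensemble network for one timepoint's target set.

    Importances use the expression of all replicates; edges are kept when a
    TF's importance exceeds the mean + 1 SD of that target's importance
    vector; signs come from replicate-mean profiles.
    """
    config.validate()
    targets = list(targets)
    tf_sources = list(tf_sources)
    if not targets or not tf_sources or matrix.values.shape[1] == 0:
        import warnings

        warnings.warn(f"no data to infer a network at {timepoint} DAG")
        return RegulatoryNetwork((), frozenset(tf_sources))
    imp = rf_importance_matrix(matrix, targets, tf_sources, config)
    signs = _profile_signs(matrix, tf_sources, targets)
    edges: list[NetworkEdge] = []
    for tgt in targets:
        col = imp[tgt]
        col = col[col.index != tgt]
        cutoff = col.mean() + col.std(ddof=1)
        for tf, val in col[col > cutoff].items():
            edges.append(
                NetworkEdge(
                    source=tf,
                    target=tgt,
                    timepoints=frozenset([timepoint]),
                    sign=int(signs.loc[tf, tgt]),
                    weight=float(val),
                )
            )
    return RegulatoryNetwork(tuple(edges), frozenset(tf_sources))


def union_networks(*networks: RegulatoryNetwork) -> RegulatoryNetwork:
    """Union of per-timepoint networks; repeated (source, target) pairs merge
    into a single edge with the combined timepoint label (e.g. "3 and 5 DAG")
    and the maximum weight."""
    merged: dict[tuple[str, str], NetworkEdge] = {}
    tf_ids: set[str] = set()
    family: dict[str, str] = {}
    for net in networks:
        tf_ids |= net.tf_ids
        family.update(net.family_map)
        for e in net.edges:
            key = (e.source, e.target)
            prev = merged.get(key)
            if prev is None:
                merged[key] = e
            else:
                best = e if e.weight >= prev.weight else prev
                merged[key] = NetworkEdge(
                    source=e.source,
                    target=e.target,
                    timepoints=prev.timepoints | e.timepoints,
                    sign=best.sign,
                    weight=max(prev.weight, e.weight),
                )
    edges = tuple(sorted(merged.values(), key=lambda e: (e.source, e.target)))
    return RegulatoryNetwork(edges, frozenset(tf_ids), family)


def write_sif(network: RegulatoryNetwork, path: str | Path,
              config_hash: str | None = None) -> None:
    """Cytoscape-compatible TSV edge list."""
    path = Path(path)
    rows = [
        {
            "source": e.source,
            "interaction": f"regulates({'+' if e.sign > 0 else '-'})",
            "target": e.target,
            "timepoints": ",".join(str(t) for t in sorted(e.timepoints)),
            "weight": e.weight,
        }
        for e in sorted(network.edges, key=lambda e: (e.source, e.target, min(e.timepoints)))
    ]
    with open(path, "w") as fh:
        if config_hash is not None:
            fh.write(f"# config_hash={config_hash}\n")
        pd.DataFrame(rows, columns=["source", "interaction", "target", "timepoints", "weight"]
                     ).to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_sif(path: str | Path, family_map: Mapping[str, str] | None = None
             ) -> RegulatoryNetwork:
    df = pd.read_csv(path, sep="\t", comment="#")
    edges = tuple(
        NetworkEdge(
            source=row.source,
            target=row.target,
            timepoints=frozenset(int(t) for t in str(row.timepoints).split(",")),
            sign=1 if "+" in row.interaction else -1,
            weight=float(row.weight),
        )
        for row in df.itertuples()
    )
    tf_ids = frozenset(e.source for e in edges)
    return RegulatoryNetwork(edges, tf_ids, dict(family_map or {}))
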