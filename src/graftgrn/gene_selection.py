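"""GO-based gene filtering and semantic clustering of graft-related terms.

Network inference inputs are restricted to DEGs annotated to at least one
curated graft-related GO term plus all differentially expressed TFs. The
curated terms themselves are grouped into functional clusters by k-means on a
Wang graph-based semantic-similarity matrix: S-values propagate from a term to
its ancestors with contribution factor 0.8 for ``is_a`` and 0.6 for
``part_of`` edges, and the similarity of two terms is the sum of their shared
ancestors' S-values divided by the sum of their total semantic values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import InvalidConfigError, UnknownTermError

WANG_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}

__all__ = [
    "GOResources",
    "NetworkGeneSet",
    "GOClusterResult",
    "select_network_genes",
    "term_semantic_similarity",
    "similarity_matrix",
    "cluster_go_terms",
    "read_go_resources",
    "write_go_resources",
]


@dataclass
class GOResources:
    """Gene->terms annotation, typed term graph, curated graft-related subset.

    ``dag`` maps each term to its set of (parent, relation) pairs; roots map
    to an empty set. ``clusters``, when present, partitions ``graft_terms``.
    """

    annotation: dict[str, frozenset[str]]
    dag: dict[str, frozenset[tuple[str, str]]]
    graft_terms: frozenset[str]
    clusters: dict[str, int] | None = None

    def __post_init__(self) -> None:
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise InvalidConfigError("GO term graph contains a cycle")
        if self.clusters is not None:
            if set(self.clusters) != set(self.graft_terms):
                raise InvalidConfigError("clusters must partition exactly graft_terms")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.dag)
        for child, parents in self.dag.items():
            for parent, rel in parents:
                g.add_edge(child, parent, relation=rel)
        return g

    def roots(self) -> set[str]:
        return {t for t, parents in self.dag.items() if not parents}


@dataclass
class NetworkGeneSet:
    """Genes admitted to network inference, with provenance.

    ``provenance`` maps each gene to ``go_deg`` (DEG with a graft-related
    annotation), ``detf`` (differentially expressed TF), or ``both``.
    """

    genes: tuple[str, ...]
    tf_flags: dict[str, bool]
    provenance: dict[str, str]


@dataclass
class GOClusterResult:
    clusters: dict[str, int]  # term -> 1..k
    wss: dict[int, float]  # sweep k -> within-cluster sum of squares


def select_network_genes(
    deg_sets: Mapping[int, set[str]] | Sequence[set[str]],
    annotation: Mapping[str, frozenset[str]],
    graft_terms: frozenset[str] | set[str],
    tf_list: Iterable[str],
) -> NetworkGeneSet:
    """(DEGs annotated to >=1 graft term) union (DEGs that are TFs)."""
    sets = list(deg_sets.values()) if isinstance(deg_sets, Mapping) else list(deg_sets)
    degs: set[str] = set().union(*sets) if sets else set()
    if not degs:
        import warnings

        warnings.warn("no DEGs supplied; the network gene set is empty")
    tfs = set(tf_list)
    graft = set(graft_terms)
    genes: list[str] = []
    provenance: dict[str, str] = {}
    for g in sorted(degs):
        is_go = bool(annotation.get(g, frozenset()) & graft)
        is_tf = g in tfs
        if is_go and is_tf:
            provenance[g] = "both"
        elif is_go:
            provenance[g] = "go_deg"
        elif is_tf:
            provenance[g] = "detf"
        else:
            continue
        genes.append(g)
    return NetworkGeneSet(tuple(genes), {g: g in tfs for g in genes}, provenance)


def _s_values(dag: Mapping[str, frozenset[tuple[str, str]]], term: str,
              weights: Mapping[str, float]) -> dict[str, float]:
    """Wang S-values: max over paths of the product of edge contribution factors."""
    if term not in dag:
        raise UnknownTermError(f"term {term!r} not in the GO graph")
    s = {term: 1.0}
    stack = [term]
    while stack:
        node = stack.pop()
        for parent, rel in dag[node]:
            w = weights.get(rel)
            if w is None:
                raise InvalidConfigError(f"unknown relation {rel!r}")
            cand = w * s[node]
            if cand > s.get(parent, 0.0):
                s[parent] = cand
                stack.append(parent)
    return s


def term_semantic_similarity(
    dag: Mapping[str, frozenset[tuple[str, str]]],
    term_a: str,
    term_b: str,
    weights: Mapping[str, float] = WANG_WEIGHTS,
) -> float:
    """Wang graph-based semantic similarity in [0, 1]."""
    sa = _s_values(dag, term_a, weights)
    sb = _s_values(dag, term_b, weights)
    shared = set(sa) & set(sb)
    if not shared:
        return 0.0
    num = sum(sa[t] + sb[t] for t in shared)
    return num / (sum(sa.values()) + sum(sb.values()))


def similarity_matrix(
    dag: Mapping[str, frozenset[tuple[str, str]]],
    terms: Sequence[str],
    weights: Mapping[str, float] = WANG_WEIGHTS,
) -> pd.DataFrame:
    terms = list(terms)
    svals = {t: _s_values(dag, t, weights) for t in terms}
    totals = {t: sum(svals[t].values()) for t in terms}
    n = len(terms)
    mat = np.eye(n)
    for i in range(n):
        si = svals[terms[i]]
        for j in range(i + 1, n):
            sj = svals[terms[j]]
            shared = set(si) & set(sj)
            if shared:
                mat[i, j] = mat[j, i] = (
                    sum(si[t] + sj[t] for t in shared) / (totals[terms[i]] + totals[terms[j]])
                )
    return pd.DataFrame(mat, index=terms, columns=terms)


def cluster_go_terms(similarity: pd.DataFrame, k: int = 10, seed: int = 0,
                     sweep: Iterable[int] | None = None,
                     n_restarts: int = 10) -> GOClusterResult:
    """K-means over rows of the similarity matrix, with a WSS elbow sweep.

    Each sweep solution beyond the smallest k also considers an init derived
    from the previous solution's centers plus the worst-fit row, which makes
    the reported WSS curve nonincreasing in k.
    """
    terms = list(similarity.index)
    if k > len(terms):
        raise InvalidConfigError(f"k={k} exceeds the number of terms ({len(terms)})")
    X = similarity.to_numpy(dtype=float)
    if sweep is None:
        sweep = range(2, min(15, len(terms) - 1) + 1)
    sweep = sorted(set(list(sweep) + [k]))
    wss: dict[int, float] = {}
    solutions: dict[int, np.ndarray] = {}
    prev_centers: np.ndarray | None = None
    for kk in sweep:
        if kk > len(terms):
            continue
        km = KMeans(n_clusters=kk, n_init=n_restarts, random_state=seed).fit(X)
        best_inertia, best_labels, best_centers = km.inertia_, km.labels_, km.cluster_centers_
        if prev_centers is not None and prev_centers.shape[0] == kk - 1:
            d = ((X[:, None, :] - prev_centers[None]) ** 2).sum(-1).min(1)
            init = np.vstack([prev_centers, X[int(np.argmax(d))]])
            km2 = KMeans(n_clusters=kk, n_init=1, init=init).fit(X)
            if km2.inertia_ < best_inertia:
                best_inertia, best_labels, best_centers = (
                    km2.inertia_, km2.labels_, km2.cluster_centers_,
                )
        wss[kk] = float(best_inertia)
        solutions[kk] = best_labels
        prev_centers = best_centers
    clusters = {t: int(lbl) + 1 for t, lbl in zip(terms, solutions[k])}
    return GOClusterResult(clusters, wss)


# -- TSV dialect -------------------------------------------------------------

def write_go_resources(resources: GOResources, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ann_path = out_dir / "go_annotation.tsv"
    rows = [(g, t) for g in sorted(resources.annotation)
            for t in sorted(resources.annotation[g])]
    pd.DataFrame(rows, columns=["gene", "term"]).to_csv(ann_path, sep="\t", index=False)
    dag_path = out_dir / "go_dag.tsv"
    rows = [(c, p, r) for c in sorted(resources.dag)
            for p, r in sorted(resources.dag[c])]
    pd.DataFrame(rows, columns=["child", "parent", "relation"]).to_csv(
        dag_path, sep="\t", index=False
    )
    graft_path = out_dir / "graft_terms.txt"
    graft_path.write_text("".join(f"{t}\n" for t in sorted(resources.graft_terms)))
    paths = {"go_annotation": ann_path, "go_dag": dag_path, "graft_terms": graft_path}
    if resources.clusters is not None:
        cl_path = out_dir / "go_clusters.tsv"
        pd.DataFrame(
            sorted(resources.clusters.items()), columns=["term", "cluster"]
        ).to_csv(cl_path, sep="\t", index=False)
        paths["go_clusters"] = cl_path
    return paths


def read_go_resources(dir_or_paths: str | Path | Mapping[str, Path]) -> GOResources:
    if isinstance(dir_or_paths, (str, Path)):
        d = Path(dir_or_paths)
        paths = {
            "go_annotation": d / "go_annotation.tsv",
            "go_dag": d / "go_dag.tsv",
            "graft_terms": d / "graft_terms.txt",
            "go_clusters": d / "go_clusters.tsv",
        }
    else:
        paths = dict(dir_or_paths)
    ann_df = pd.read_csv(paths["go_annotation"], sep="\t", comment="#")
    annotation: dict[str, frozenset[str]] = {
        g: frozenset(sub["term"]) for g, sub in ann_df.groupby("gene")
    }
    dag_df = pd.read_csv(paths["go_dag"], sep="\t", comment="#")
    dag: dict[str, frozenset[tuple[str, str]]] = {}
    all_terms = set(dag_df["child"]) | set(dag_df["parent"])
    for t in all_terms:
        dag[t] = frozenset()
    for child, sub in dag_df.groupby("child"):
        dag[child] = frozenset(zip(sub["parent"], sub["relation"]))
    graft_terms = frozenset(
        line.strip() for line in Path(paths["graft_terms"]).read_text().splitlines()
        if line.strip()
    )
    clusters = None
    cl_path = paths.get("go_clusters")
    if cl_path is not None and Path(cl_path).exists():
        cl_df = pd.read_csv(cl_path, sep="\t", comment="#")
        clusters = dict(zip(cl_df["term"], cl_df["cluster"].astype(int)))
    return GOResources(annotation, dag, graft_terms, clusters)
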