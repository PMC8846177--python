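"""Cross-condition network comparison and summary layers.

Covers the rewiring readout (per-node outdegree variation between a reference
and an alternate network, the quantity mapped to node color when contrasting
heterograft networks with self-graft networks), hub selection by outdegree,
the layered Sankey summary (species -> TF family -> hub TF -> timepoint -> GO
cluster, links weighted by downstream target counts), and per-timepoint GO
cluster composition with Fisher enrichment flags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _fisher_2x2

from .errors import AnnotationError
from .inference import RegulatoryNetwork

__all__ = [
    "SankeyGraph",
    "outdegree_variation",
    "select_hubs",
    "build_sankey",
    "go_cluster_composition",
    "write_sankey_json",
]


@dataclass
class SankeyGraph:
    """Layered flow graph; nodes are (node id, layer tag) and links carry the
    number of downstream target-gene contributions."""

    nodes: list[tuple[str, str]]
    links: list[tuple[str, str, int]]

    def inflow(self, node: str) -> int:
        return sum(w for _, dst, w in self.links if dst == node)

    def outflow(self, node: str) -> int:
        return sum(w for src, _, w in self.links if src == node)


def outdegree_variation(reference: RegulatoryNetwork,
                        alternate: RegulatoryNetwork,
                        degree_corrected: bool = False) -> pd.DataFrame:
    """Per-node outdegree delta (alternate - reference) over the shared node
    universe; nodes absent from one network count as outdegree 0.

    With ``degree_corrected`` the delta is divided by max(1, reference
    outdegree), a DyNet-like rescaling that prevents large hubs from
    dominating the color map.
    """
    out_ref = reference.outdegree()
    out_alt = alternate.outdegree()
    nodes = sorted(reference.nodes() | alternate.nodes() | set(out_ref) | set(out_alt))
    rows = []
    for n in nodes:
        a, b = out_ref.get(n, 0), out_alt.get(n, 0)
        delta = b - a
        if degree_corrected:
            delta = delta / max(1, a)
        rows.append({"node": n, "outdeg_ref": a, "outdeg_alt": b,
                     "delta": delta, "abs_delta": abs(delta)})
    return pd.DataFrame(rows).set_index("node")


def select_hubs(network: RegulatoryNetwork, min_targets: int = 25
                ) -> tuple[list[str], float]:
    """TFs with outdegree strictly greater than ``min_targets``, plus the
    fraction of all edges covered by those hubs."""
    out = network.outdegree()
    hubs = sorted(tf for tf, k in out.items() if k > min_targets)
    total = len(network.edges)
    coverage = sum(out[h] for h in hubs) / total if total else 0.0
    return hubs, coverage


def build_sankey(network: RegulatoryNetwork,
                 family_map: Mapping[str, str],
                 go_clusters: Mapping[str, int],
                 annotation: Mapping[str, frozenset[str]],
                 species_of=None) -> SankeyGraph:
    """Layered Sankey of hub regulation flows.

    Every edge contributes one flow unit per (timepoint label, target GO
    cluster) combination; a target annotated to terms in several clusters
    contributes to each. Targets with no clustered graft-term annotation flow
    into an explicit ``unclustered`` sink so that flow is conserved at every
    interior layer.
    """
    if species_of is None:
        species_of = lambda g: g.split("_", 1)[0]
    term_cluster = dict(go_clusters)
    flows: dict[tuple[str, str, str, str, str], int] = {}
    for e in network.edges:
        if e.source not in family_map:
            raise AnnotationError(f"hub {e.source!r} has no TF family")
        sp = f"species:{species_of(e.source)}"
        fam = f"family:{family_map[e.source]}"
        tf = f"tf:{e.source}"
        clusters = sorted(
            {term_cluster[t] for t in annotation.get(e.target, frozenset())
             if t in term_cluster}
        )
        cl_nodes = [f"cluster:{c}" for c in clusters] or ["cluster:unclustered"]
        for t in sorted(e.timepoints):
            tp = f"timepoint:{t} DAG"
            for cl in cl_nodes:
                key = (sp, fam, tf, tp, cl)
                flows[key] = flows.get(key, 0) + 1
    links: dict[tuple[str, str], int] = {}
    nodes: dict[str, str] = {}
    for (sp, fam, tf, tp, cl), w in flows.items():
        for a, b in ((sp, fam), (fam, tf), (tf, tp), (tp, cl)):
            links[(a, b)] = links.get((a, b), 0) + w
        for node in (sp, fam, tf, tp, cl):
            nodes[node] = node.split(":", 1)[0]
    return SankeyGraph(
        nodes=sorted(nodes.items()),
        links=sorted((a, b, w) for (a, b), w in links.items()),
    )


def write_sankey_json(graph: SankeyGraph, path: str | Path,
                      config_hash: str | None = None) -> None:
    payload = {
        "nodes": [{"id": n, "layer": layer} for n, layer in graph.nodes],
        "links": [{"source": a, "target": b, "value": w} for a, b, w in graph.links],
    }
    if config_hash is not None:
        payload["config_hash"] = config_hash
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def go_cluster_composition(targets_by_timepoint: Mapping[int, set[str]],
                           go_clusters: Mapping[str, int],
                           annotation: Mapping[str, frozenset[str]],
                           alpha: float = 0.05) -> pd.DataFrame:
    """Per-cluster percentage of each timepoint's target genes, with a 2x2
    Fisher enrichment flag per (cluster, timepoint).

    The contrast is membership at the given timepoint versus membership pooled
    over all other timepoints. Percentages are per cluster independently, so
    multi-cluster genes can push the per-timepoint total above 100.
    """
    term_cluster = dict(go_clusters)
    cluster_ids = sorted(set(term_cluster.values()))

    def clusters_of(gene: str) -> set[int]:
        return {term_cluster[t] for t in annotation.get(gene, frozenset())
                if t in term_cluster}

    tps = sorted(targets_by_timepoint)
    member: dict[tuple[int, int], int] = {}
    totals: dict[int, int] = {}
    for t in tps:
        genes = targets_by_timepoint[t]
        totals[t] = len(genes)
        for c in cluster_ids:
            member[(t, c)] = sum(1 for g in genes if c in clusters_of(g))
    rows = []
    for t in tps:
        for c in cluster_ids:
            a = member[(t, c)]
            b = totals[t] - a
            other_in = sum(member[(u, c)] for u in tps if u != t)
            other_out = sum(totals[u] for u in tps if u != t) - other_in
            if totals[t] == 0:
                pct, p = 0.0, 1.0
            else:
                pct = 100.0 * a / totals[t]
                table = np.array([[a, b], [other_in, other_out]])
                if table.sum() == 0:
                    p = 1.0
                else:
                    p = float(_fisher_2x2(table)[1])
            rows.append({"timepoint": t, "cluster": c, "n_genes": a,
                         "percent": pct, "p": p, "enriched": p < alpha})
    return pd.DataFrame(rows)
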