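"""Workflow orchestration for the two headline analyses.

``run_selfgraft_workflow`` wires: reference normalization -> pairwise DE ->
DEG selection -> GO/TF gene filtering -> per-timepoint DBN inference -> union
-> hub selection -> Sankey -> GO-cluster composition, for each self-graft
combination. ``run_heterograft_comparison`` then re-infers the self-graft gene
sets on heterograft expression, maps per-node outdegree variation against the
self-graft union networks, builds the tree-ensemble heterograft networks for
the hub Sankey, and runs the modified-Shannon-entropy outlier scan on
reference-normalized heterograft expression.

Runs are plain sequential stages. Every run copies its configuration verbatim
into the output directory; every tabular artifact carries the configuration
hash in a leading comment line, and a structured log records per-stage timing
and row counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import pandas as pd
import yaml

from . import expression as xp
from . import gene_selection as gs
from . import inference as gi
from . import mse as ms
from . import network_analysis as na
from . import synthetic_data as sd
from .errors import DependencyError, GraftGRNError

SELF_COMBOS = {"TT": "Sl", "PP": "Ca"}
HETERO_COMBOS = ("PT", "TP")

__all__ = ["PipelineConfig", "run_selfgraft_workflow", "run_heterograft_comparison"]


@dataclass(frozen=True)
class PipelineConfig:
    synthetic: sd.SyntheticConfig = field(default_factory=sd.SyntheticConfig)
    inference: gi.InferenceConfig = field(default_factory=gi.InferenceConfig)
    input_dir: str | None = None  # read a written study instead of generating
    fdr_max: float = 0.05
    abs_log2fc_min: float = 2.0
    n_go_terms: int = 80
    go_dag_depth: int = 4
    graft_term_fraction: float = 0.5
    go_k: int = 10
    profile_k: int = 9
    hub_min_targets_self: int = 0
    hub_min_targets_hetero: int = 25
    entropy_fraction: float = 0.30
    self_engine: str = "dbn"
    hetero_engine: str = "dbn"  # used for the outdegree comparison
    hetero_sankey_engine: str = "rf"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        data = dict(data)
        syn = data.pop("synthetic", {})
        for key in ("timepoints", "active_timepoint_range"):
            if isinstance(syn.get(key), list):
                syn[key] = tuple(syn[key])
        inf = data.pop("inference", {})
        return cls(synthetic=sd.SyntheticConfig(**syn),
                   inference=gi.InferenceConfig(**inf), **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def stage(self, name: str, seconds: float, **counts) -> None:
        extras = "\t".join(f"{k}={v}" for k, v in counts.items())
        self.lines.append(f"{name}\t{seconds:.2f}s\t{extras}")

    def flush(self) -> None:
        self.path.write_text("".join(line + "\n" for line in self.lines))


def _run_stage(log: _RunLog, name: str, fingerprint: str, fn: Callable, **counts):
    t0 = time.time()
    try:
        result = fn()
    except Exception as exc:  # abort with the stage name and input fingerprint
        log.stage(name, time.time() - t0, status="failed")
        log.flush()
        raise GraftGRNError(
            f"stage {name!r} failed on input {fingerprint}: {exc}"
        ) from exc
    log.stage(name, time.time() - t0, **counts)
    return result


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str, **kwargs) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", float_format="%.10g", **kwargs)


def _load_inputs(config: PipelineConfig, out_dir: Path):
    """Generate (or read) the study expression, TF list and GO resources."""
    if config.input_dir is None:
        input_dir = out_dir / "inputs"
        sd.write_study(
            config.synthetic, input_dir,
            go_kwargs={
                "n_terms": config.n_go_terms,
                "dag_depth": config.go_dag_depth,
                "graft_related_fraction": config.graft_term_fraction,
            },
        )
    else:
        input_dir = Path(config.input_dir)
    study = {}
    for combo in list(SELF_COMBOS) + list(HETERO_COMBOS):
        p = input_dir / f"expression_{combo}.tsv"
        if not p.exists():
            raise DependencyError(f"missing input {p}")
        study[combo] = xp.read_expression(p)
    tf_path = input_dir / "tfs.tsv"
    if not tf_path.exists():
        raise DependencyError(f"missing input {tf_path}")
    tf_df = pd.read_csv(tf_path, sep="\t", comment="#")
    tf_list = list(tf_df["tf"])
    family_map = dict(zip(tf_df["tf"], tf_df["family"]))
    for name in ("go_annotation.tsv", "go_dag.tsv", "graft_terms.txt"):
        if not (input_dir / name).exists():
            raise DependencyError(
                f"missing GO input {input_dir / name}; regenerate the study inputs"
            )
    go = gs.read_go_resources(input_dir)
    return study, tf_list, family_map, go


def _infer_timepoint_networks(matrix, targets_by_tp, tf_sources, engine, config):
    nets = {}
    for t in sorted(targets_by_tp):
        targets = sorted(targets_by_tp[t])
        if engine == "dbn":
            nets[t] = gi.infer_dbn_network(matrix, targets, tf_sources, t, config)
        elif engine == "rf":
            nets[t] = gi.infer_rf_network(matrix, targets, tf_sources, t, config)
        else:
            raise GraftGRNError(f"unknown inference engine {engine!r}")
    return nets


def run_selfgraft_workflow(config: PipelineConfig, out_dir: str | Path) -> dict[str, Path]:
    """Self-graft networks, hubs, Sankey and GO composition; returns artifact paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    config.to_yaml(out_dir / "config.yaml")
    log = _RunLog(out_dir / "run_self.log")
    artifacts: dict[str, Path] = {"config": out_dir / "config.yaml"}

    study, tf_list, family_map, go = _run_stage(
        log, "load_inputs", "study", lambda: _load_inputs(config, out_dir)
    )

    sim = _run_stage(
        log, "go_similarity", f"{len(go.graft_terms)} graft terms",
        lambda: gs.similarity_matrix(go.dag, sorted(go.graft_terms)),
    )
    go_clusters = _run_stage(
        log, "cluster_go_terms", f"{sim.shape[0]} terms",
        lambda: gs.cluster_go_terms(sim, k=config.go_k, seed=config.seed),
    )
    cl_df = pd.DataFrame(sorted(go_clusters.clusters.items()), columns=["term", "cluster"])
    _write_tsv(cl_df, out_dir / "go_clusters.tsv", chash, index=False)
    artifacts["go_clusters"] = out_dir / "go_clusters.tsv"

    for combo in SELF_COMBOS:
        matrix = study[combo]
        ref_sample = f"{combo}_{min(m for m in matrix.sample_meta['timepoint'])}d_r1"
        _run_stage(
            log, f"normalize_{combo}", ref_sample,
            lambda m=matrix, r=ref_sample: xp.normalize_to_reference(m, r),
        )
        tps = sorted(matrix.sample_meta["timepoint"].unique())
        comparisons = [(tps[i], tps[j]) for i in range(len(tps))
                       for j in range(i + 1, len(tps))]
        records = _run_stage(
            log, f"pairwise_de_{combo}", f"{matrix.values.shape}",
            lambda m=matrix, c=combo: pd.concat(
                [xp.pairwise_de(m, a, b, c) for a, b in comparisons],
                ignore_index=True,
            ),
            comparisons=len(comparisons),
        )
        deg_sets = xp.select_degs(records, config.fdr_max, config.abs_log2fc_min)
        deg_rows = [
            {"gene": g, "timepoint": t}
            for t in sorted(deg_sets) for g in sorted(deg_sets[t])
        ]
        _write_tsv(pd.DataFrame(deg_rows, columns=["gene", "timepoint"]),
                   out_dir / f"degs_{combo}.tsv", chash, index=False)
        artifacts[f"degs_{combo}"] = out_dir / f"degs_{combo}.tsv"

        geneset = _run_stage(
            log, f"select_genes_{combo}", f"{sum(len(s) for s in deg_sets.values())} DEGs",
            lambda d=deg_sets: gs.select_network_genes(
                d, go.annotation, go.graft_terms, tf_list
            ),
            genes=0,
        )
        gset_df = pd.DataFrame(
            {"gene": geneset.genes,
             "is_tf": [geneset.tf_flags[g] for g in geneset.genes],
             "provenance": [geneset.provenance[g] for g in geneset.genes]}
        )
        _write_tsv(gset_df, out_dir / f"geneset_{combo}.tsv", chash, index=False)
        artifacts[f"geneset_{combo}"] = out_dir / f"geneset_{combo}.tsv"

        tf_sources = [g for g in geneset.genes if geneset.tf_flags[g]]
        targets_by_tp = {
            t: (deg_sets[t] & set(geneset.genes)) for t in sorted(deg_sets)
        }
        nets = _run_stage(
            log, f"infer_{combo}", f"{len(geneset.genes)} genes",
            lambda m=matrix, tb=targets_by_tp, s=tf_sources: _infer_timepoint_networks(
                m, tb, s, config.self_engine, config.inference
            ),
        )
        for t, net in nets.items():
            p = out_dir / f"network_{combo}_{t}dag.sif"
            gi.write_sif(net, p, chash)
            artifacts[f"network_{combo}_{t}dag"] = p
        union = gi.union_networks(*nets.values())
        union.family_map.update(family_map)
        p = out_dir / f"network_{combo}_union.sif"
        gi.write_sif(union, p, chash)
        artifacts[f"network_{combo}_union"] = p

        hubs, coverage = na.select_hubs(union, config.hub_min_targets_self)
        hub_net = gi.RegulatoryNetwork(
            tuple(e for e in union.edges if e.source in set(hubs)),
            union.tf_ids, union.family_map,
        )
        sankey = _run_stage(
            log, f"sankey_{combo}", f"{len(hubs)} hubs",
            lambda n=hub_net: na.build_sankey(
                n, family_map, go_clusters.clusters, go.annotation
            ),
            coverage=round(coverage, 3),
        )
        p = out_dir / f"sankey_{combo}.json"
        na.write_sankey_json(sankey, p, chash)
        artifacts[f"sankey_{combo}"] = p

        targets_per_tp = {
            t: {e.target for e in nets[t].edges} for t in nets
        }
        comp = na.go_cluster_composition(targets_per_tp, go_clusters.clusters,
                                         go.annotation)
        p = out_dir / f"composition_{combo}.tsv"
        _write_tsv(comp, p, chash, index=False)
        artifacts[f"composition_{combo}"] = p

    log.flush()
    artifacts["log"] = log.path
    return artifacts


def run_heterograft_comparison(config: PipelineConfig, out_dir: str | Path
                               ) -> dict[str, Path]:
    """Heterograft re-inference, outdegree variation, Sankey inputs and MSE.

    Requires the artifacts of :func:`run_selfgraft_workflow` in ``out_dir``.
    """
    out_dir = Path(out_dir)
    chash = config.hash()
    log = _RunLog(out_dir / "run_compare.log")
    artifacts: dict[str, Path] = {}

    for combo in SELF_COMBOS:
        for name in (f"degs_{combo}.tsv", f"geneset_{combo}.tsv",
                     f"network_{combo}_union.sif"):
            if not (out_dir / name).exists():
                raise DependencyError(
                    f"missing self-graft artifact {out_dir / name}; "
                    "run the self-graft workflow first"
                )
    if not (out_dir / "go_clusters.tsv").exists():
        raise DependencyError("missing go_clusters.tsv from the self-graft run")

    study, tf_list, family_map, go = _load_inputs(config, out_dir)
    go_clusters = dict(
        pd.read_csv(out_dir / "go_clusters.tsv", sep="\t", comment="#")
        .set_index("term")["cluster"].astype(int)
    )

    self_artifacts: dict[str, dict] = {}
    for combo in SELF_COMBOS:
        degs = pd.read_csv(out_dir / f"degs_{combo}.tsv", sep="\t", comment="#")
        deg_sets = {int(t): set(sub["gene"]) for t, sub in degs.groupby("timepoint")}
        gset = pd.read_csv(out_dir / f"geneset_{combo}.tsv", sep="\t", comment="#")
        union = gi.read_sif(out_dir / f"network_{combo}_union.sif", family_map)
        self_artifacts[combo] = {
            "deg_sets": deg_sets,
            "genes": list(gset["gene"]),
            "tf_sources": list(gset.loc[gset["is_tf"], "gene"]),
            "union": union,
        }

    # Reference vector for normalization: self-graft earliest-DAG replicate 1.
    ref_series = {}
    for combo in SELF_COMBOS:
        m = study[combo]
        ref = f"{combo}_{min(m.sample_meta['timepoint'])}d_r1"
        ref_series.update(m.values[ref].to_dict())

    for hetero in HETERO_COMBOS:
        hmatrix = study[hetero]
        for combo in SELF_COMBOS:
            base = self_artifacts[combo]
            genes = [g for g in base["genes"] if g in hmatrix.values.index]
            targets_by_tp = {
                t: (base["deg_sets"][t] & set(genes))
                for t in sorted(base["deg_sets"])
            }
            tf_sources = [g for g in base["tf_sources"] if g in hmatrix.values.index]
            nets = _run_stage(
                log, f"infer_{hetero}_on_{combo}", f"{len(genes)} genes",
                lambda m=hmatrix, tb=targets_by_tp, s=tf_sources: _infer_timepoint_networks(
                    m, tb, s, config.hetero_engine, config.inference
                ),
            )
            union = gi.union_networks(*nets.values()) if nets else gi.RegulatoryNetwork(
                (), frozenset(tf_sources))
            p = out_dir / f"network_{hetero}_on_{combo}_union.sif"
            gi.write_sif(union, p, chash)
            artifacts[f"network_{hetero}_on_{combo}_union"] = p

            report = na.outdegree_variation(base["union"], union)
            p = out_dir / f"outdegree_{hetero}_vs_{combo}.tsv"
            _write_tsv(report, p, chash)
            artifacts[f"outdegree_{hetero}_vs_{combo}"] = p

            sankey_nets = _run_stage(
                log, f"sankey_infer_{hetero}_on_{combo}", f"{len(genes)} genes",
                lambda m=hmatrix, tb=targets_by_tp, s=tf_sources: _infer_timepoint_networks(
                    m, tb, s, config.hetero_sankey_engine, config.inference
                ),
            )
            s_union = gi.union_networks(*sankey_nets.values())
            hubs, coverage = na.select_hubs(s_union, config.hub_min_targets_hetero)
            hub_net = gi.RegulatoryNetwork(
                tuple(e for e in s_union.edges if e.source in set(hubs)),
                s_union.tf_ids, family_map,
            )
            sankey = na.build_sankey(hub_net, family_map, go_clusters, go.annotation)
            p = out_dir / f"sankey_{hetero}_on_{combo}.json"
            na.write_sankey_json(sankey, p, chash)
            artifacts[f"sankey_{hetero}_on_{combo}"] = p

        # MSE on reference-normalized heterograft expression
        ref = pd.Series({g: ref_series.get(g, 0.0) for g in hmatrix.values.index})
        denom = ref.where(ref > xp.REFERENCE_FLOOR, xp.REFERENCE_FLOOR)
        normalized = hmatrix.values.div(denom, axis=0)
        results = _run_stage(
            log, f"mse_{hetero}", f"{normalized.shape[0]} genes",
            lambda v=normalized: ms.mse_analysis(v, config.entropy_fraction),
        )
        p = out_dir / f"mse_{hetero}.tsv"
        _write_tsv(results, p, chash)
        artifacts[f"mse_{hetero}"] = p

    log.flush()
    artifacts["log"] = log.path
    return artifacts
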