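"""Synthetic grafting study generator.

Emulates the design of the tomato/pepper grafting time course: two genomes
(tomato-like ``Sl`` and pepper-like ``Ca``), four graft combinations (two
self-grafts, two reciprocal heterografts), three sampling days after grafting
(1, 3, 5 DAG) with four replicates, FPKM-like nonnegative expression, and
heterografts expressed over the concatenated two-genome gene space.

The generator plants a known regulatory network per genome. Transcription
factor (TF) log-expression follows a smooth random trajectory over the
timepoints; each target's log-mean at an active timepoint is a signed linear
combination of its parents' realized per-sample log values (so replicate noise
propagates regulator -> target) plus an intercept. Heterografts rewire a
configurable fraction of edges and delay pepper regulator activity at 1 DAG,
emulating the delayed pepper wound response. Every generator is a pure
function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .expression import ExpressionMatrix, write_expression

TF_FAMILIES = ("AP2/ERF", "bHLH", "LBD", "NAC", "C3H", "HD-ZIP", "MYB", "WRKY", "other")
SPECIES = ("Sl", "Ca")

__all__ = [
    "SyntheticConfig",
    "PlantedEdge",
    "PlantedNetwork",
    "generate_planted_network",
    "simulate_timecourse",
    "generate_study",
    "generate_go_resources",
    "generate_phenotype_counts",
    "write_study",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters; defaults are the conditions used throughout.

    Counts are per genome. ``noise_sd`` is the log-scale replicate standard
    deviation; ``disruption_fraction`` is the fraction of planted edges
    rewired in the heterograft regime.
    """

    n_tfs: int = 60
    n_targets: int = 300
    n_flat_genes: int = 100
    parents_per_target: int = 2
    timepoints: tuple[int, ...] = (1, 3, 5)
    replicates: int = 4
    noise_sd: float = 0.2
    disruption_fraction: float = 0.5
    seed: int = 0
    # Expression-scale parameters (natural-log space). Baselines emulate the
    # FPKM range of moderately expressed genes; curve_sd sets the dynamic
    # range of TF trajectories; edge weights the regulatory effect size.
    baseline_log_mean: float = 4.6
    baseline_log_sd: float = 1.0
    curve_sd: float = 1.0
    weight_low: float = 0.6
    weight_high: float = 1.2
    # min/max number of timepoints an edge is active at (inclusive)
    active_timepoint_range: tuple[int, int] = (1, 3)
    pepper_delay: bool = True

    def validate(self) -> None:
        if min(self.n_tfs, self.n_targets, self.n_flat_genes) < 0:
            raise InvalidConfigError("gene counts must be >= 0")
        if self.replicates < 2:
            raise InvalidConfigError("replicates must be >= 2")
        if not 0.0 <= self.disruption_fraction <= 1.0:
            raise InvalidConfigError("disruption_fraction must be in [0, 1]")
        if self.parents_per_target > self.n_tfs:
            raise InvalidConfigError("parents_per_target cannot exceed n_tfs")
        if self.parents_per_target < 0:
            raise InvalidConfigError("parents_per_target must be >= 0")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        if len(self.timepoints) < 2:
            raise InvalidConfigError("need at least 2 timepoints")
        lo, hi = self.active_timepoint_range
        if not 1 <= lo <= hi <= len(self.timepoints):
            raise InvalidConfigError("active_timepoint_range must be within 1..len(timepoints)")


@dataclass(frozen=True)
class PlantedEdge:
    regulator: str
    target: str
    sign: int  # +1 or -1
    timepoints: frozenset[int]
    weight: float


@dataclass(frozen=True)
class PlantedNetwork:
    edges: tuple[PlantedEdge, ...]
    tf_ids: frozenset[str]
    family_map: dict[str, str]

    def __post_init__(self) -> None:
        for e in self.edges:
            if e.regulator == e.target:
                raise InvalidConfigError("planted networks contain no self-edges")
            if e.regulator not in self.tf_ids:
                raise InvalidConfigError("all regulators must be TFs")

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(e.regulator, e.target) for e in self.edges}


def _gene_ids(config: SyntheticConfig) -> dict[str, list[str]]:
    ids: dict[str, list[str]] = {}
    for sp in SPECIES:
        ids[f"{sp}_tfs"] = [f"{sp}_TF{i:03d}" for i in range(1, config.n_tfs + 1)]
        ids[f"{sp}_targets"] = [f"{sp}_G{i:04d}" for i in range(1, config.n_targets + 1)]
        ids[f"{sp}_flat"] = [f"{sp}_F{i:04d}" for i in range(1, config.n_flat_genes + 1)]
    return ids


def generate_planted_network(config: SyntheticConfig) -> PlantedNetwork:
    """Plant a two-genome regulatory network.

    Each target gets exactly ``parents_per_target`` distinct within-genome TF
    parents, a random sign, a nonempty active-timepoint set, and an effect
    size drawn from [weight_low, weight_high]. TF families come from a fixed
    nine-label palette.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ids = _gene_ids(config)
    edges: list[PlantedEdge] = []
    tf_ids: list[str] = []
    family_map: dict[str, str] = {}
    tps = list(config.timepoints)
    for sp in SPECIES:
        tfs = ids[f"{sp}_tfs"]
        tf_ids.extend(tfs)
        for tf in tfs:
            family_map[tf] = TF_FAMILIES[rng.integers(len(TF_FAMILIES))]
        for tgt in ids[f"{sp}_targets"]:
            if config.parents_per_target == 0:
                continue
            parents = rng.choice(tfs, size=config.parents_per_target, replace=False)
            lo, hi = config.active_timepoint_range
            for par in parents:
                n_active = int(rng.integers(lo, hi + 1))
                active = frozenset(
                    int(t) for t in rng.choice(tps, size=n_active, replace=False)
                )
                edges.append(
                    PlantedEdge(
                        regulator=str(par),
                        target=tgt,
                        sign=int(rng.choice([-1, 1])),
                        timepoints=active,
                        weight=float(rng.uniform(config.weight_low, config.weight_high)),
                    )
                )
    return PlantedNetwork(tuple(edges), frozenset(tf_ids), family_map)


def _disrupt_network(network: PlantedNetwork, config: SyntheticConfig,
                     stream: int) -> PlantedNetwork:
    """Rewire a fraction of edges to a different within-genome regulator."""
    if config.disruption_fraction == 0:
        return network
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, stream]))
    n_rewire = int(round(config.disruption_fraction * len(network.edges)))
    idx = set(rng.choice(len(network.edges), size=n_rewire, replace=False).tolist())
    by_species: dict[str, list[str]] = {}
    for tf in sorted(network.tf_ids):
        by_species.setdefault(tf.split("_", 1)[0], []).append(tf)
    new_edges = []
    for i, e in enumerate(network.edges):
        if i in idx:
            pool = [t for t in by_species[e.regulator.split("_", 1)[0]]
                    if t != e.regulator and t != e.target]
            new_reg = str(rng.choice(pool))
            e = replace(e, regulator=new_reg, sign=int(rng.choice([-1, 1])))
        new_edges.append(e)
    return PlantedNetwork(tuple(new_edges), network.tf_ids, network.family_map)


def _tf_curves(network: PlantedNetwork, config: SyntheticConfig) -> dict[str, np.ndarray]:
    """Smooth random log-trajectories per TF, shared across regimes."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    n_t = len(config.timepoints)
    curves: dict[str, np.ndarray] = {}
    for tf in sorted(network.tf_ids):
        base = rng.normal(config.baseline_log_mean, config.baseline_log_sd)
        steps = rng.normal(0.0, config.curve_sd, size=n_t - 1)
        curves[tf] = base + np.concatenate([[0.0], np.cumsum(steps)])
    return curves


def _flat_levels(config: SyntheticConfig) -> dict[str, float]:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    ids = _gene_ids(config)
    flat = {}
    for sp in SPECIES:
        for g in ids[f"{sp}_flat"]:
            flat[g] = rng.normal(config.baseline_log_mean, config.baseline_log_sd)
    return flat


def simulate_timecourse(
    network: PlantedNetwork,
    config: SyntheticConfig,
    regime: Literal["selfgraft", "heterograft"] = "selfgraft",
    combination: str | None = None,
    noise_stream: int = 0,
) -> ExpressionMatrix:
    """Simulate one condition over the concatenated two-genome gene space.

    The heterograft regime rewires ``disruption_fraction`` of the planted
    edges (seeded, per ``noise_stream``) and, when ``pepper_delay`` is set,
    delays pepper TF trajectories by one timepoint to emulate the delayed
    pepper wound response at 1 DAG.
    """
    config.validate()
    if regime not in ("selfgraft", "heterograft"):
        raise InvalidConfigError(f"unknown regime {regime!r}")
    label = combination or ("self" if regime == "selfgraft" else "hetero")
    net = network
    curves = _tf_curves(network, config)
    if regime == "heterograft":
        net = _disrupt_network(network, config, stream=noise_stream)
        if config.pepper_delay:
            curves = {
                tf: (np.concatenate([[c[0]], c[:-1]]) if tf.startswith("Ca") else c)
                for tf, c in curves.items()
            }
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 5, noise_stream, 0 if regime == "selfgraft" else 1])
    )
    ids = _gene_ids(config)
    tfs = sorted(net.tf_ids)
    targets = [g for sp in SPECIES for g in ids[f"{sp}_targets"]]
    flat = _flat_levels(config)
    tps = list(config.timepoints)
    n_t, n_r = len(tps), config.replicates
    samples = [f"{label}_{t}d_r{r}" for t in tps for r in range(1, n_r + 1)]
    t_of_sample = np.repeat(np.arange(n_t), n_r)

    # TF realized log values: curve value at the sample's timepoint + noise.
    tf_log = np.empty((len(tfs), len(samples)))
    for i, tf in enumerate(tfs):
        tf_log[i] = curves[tf][t_of_sample] + rng.normal(0, config.noise_sd, len(samples))
    tf_index = {tf: i for i, tf in enumerate(tfs)}
    tf_time_mean = np.array([curves[tf].mean() for tf in tfs])

    # Target intercepts (deterministic per target from the shared curve seed).
    rng_b = np.random.default_rng(np.random.SeedSequence([config.seed, 6]))
    intercepts = {g: rng_b.normal(config.baseline_log_mean, config.baseline_log_sd)
                  for g in targets}

    edges_by_target: dict[str, list[PlantedEdge]] = {}
    for e in net.edges:
        edges_by_target.setdefault(e.target, []).append(e)

    tgt_log = np.empty((len(targets), len(samples)))
    active_mask = np.empty((n_t,), dtype=bool)
    for j, g in enumerate(targets):
        mean_log = np.full(len(samples), intercepts[g])
        for e in edges_by_target.get(g, []):
            for k, t in enumerate(tps):
                active_mask[k] = t in e.timepoints
            contrib = e.sign * e.weight * (
                tf_log[tf_index[e.regulator]] - tf_time_mean[tf_index[e.regulator]]
            )
            mean_log += np.where(active_mask[t_of_sample], contrib, 0.0)
        tgt_log[j] = mean_log + rng.normal(0, config.noise_sd, len(samples))

    flat_ids = [g for sp in SPECIES for g in ids[f"{sp}_flat"]]
    flat_log = np.empty((len(flat_ids), len(samples)))
    for j, g in enumerate(flat_ids):
        flat_log[j] = flat[g] + rng.normal(0, config.noise_sd, len(samples))

    genes = tfs + targets + flat_ids
    values = np.maximum(np.exp(np.vstack([tf_log, tgt_log, flat_log])), 0.0)
    df = pd.DataFrame(values, index=genes, columns=samples)
    meta = pd.DataFrame(
        {
            "combination": label,
            "timepoint": [tps[t] for t in t_of_sample],
            "replicate": [r for _ in tps for r in range(1, n_r + 1)],
        },
        index=samples,
    )
    return ExpressionMatrix(df, meta)


def generate_study(config: SyntheticConfig) -> dict[str, ExpressionMatrix]:
    """The four graft combinations of the study design.

    ``TT``/``PP`` are the self-grafts restricted to their own genome's genes;
    ``PT``/``TP`` are reciprocal heterografts over the concatenated gene space
    with independently drawn disruptions.
    """
    network = generate_planted_network(config)
    self_all = simulate_timecourse(network, config, "selfgraft", combination="self")
    out: dict[str, ExpressionMatrix] = {}
    species_of = self_all.gene_species()
    for combo, sp in (("TT", "Sl"), ("PP", "Ca")):
        genes = [g for g in self_all.gene_ids if species_of[g] == sp]
        sub = self_all.values.loc[genes].copy()
        sub.columns = [c.replace("self_", f"{combo}_") for c in sub.columns]
        meta = self_all.sample_meta.copy()
        meta.index = [c.replace("self_", f"{combo}_") for c in meta.index]
        meta["combination"] = combo
        out[combo] = ExpressionMatrix(sub, meta)
    for stream, combo in ((1, "PT"), (2, "TP")):
        out[combo] = simulate_timecourse(
            network, config, "heterograft", combination=combo, noise_stream=stream
        )
    return out


def generate_go_resources(network: PlantedNetwork, n_terms: int = 80,
                          dag_depth: int = 4, graft_related_fraction: float = 0.5,
                          seed: int = 0, annotation_coverage: float = 1.0):
    """Random GO-like resources: a rooted acyclic term graph, gene annotation
    covering every dynamic gene, and a curated graft-related term subset.

    Returns a :class:`~graftgrn.gene_selection.GOResources`.
    """
    from .gene_selection import GOResources  # local import avoids a cycle

    if n_terms < 1 or dag_depth < 1:
        raise InvalidConfigError("n_terms and dag_depth must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    root = "GO:0000001"
    terms = [f"GO:{i + 2:07d}" for i in range(n_terms)]
    levels = {root: 0}
    dag: dict[str, frozenset[tuple[str, str]]] = {root: frozenset()}
    by_level: dict[int, list[str]] = {0: [root]}
    for term in terms:
        lvl = int(rng.integers(1, dag_depth + 1))
        # parents come from strictly shallower levels -> acyclic by construction
        candidates = [t for l in range(lvl) for t in by_level.get(l, [])]
        n_par = min(len(candidates), int(rng.integers(1, 3)))
        parents = rng.choice(candidates, size=n_par, replace=False)
        rels = rng.choice(["is_a", "part_of"], size=n_par, p=[0.8, 0.2])
        dag[term] = frozenset(zip(map(str, parents), map(str, rels)))
        levels[term] = lvl
        by_level.setdefault(lvl, []).append(term)

    dynamic_genes = sorted({e.target for e in network.edges} | set(network.tf_ids))
    annotation: dict[str, frozenset[str]] = {}
    for g in dynamic_genes:
        if rng.random() <= annotation_coverage:
            n_ann = int(rng.integers(1, 4))
            annotation[g] = frozenset(
                str(t) for t in rng.choice(terms, size=min(n_ann, len(terms)), replace=False)
            )
    n_graft = max(1, int(round(graft_related_fraction * n_terms)))
    graft_terms = frozenset(str(t) for t in rng.choice(terms, size=n_graft, replace=False))
    return GOResources(annotation=annotation, dag=dag, graft_terms=graft_terms)


def generate_phenotype_counts(groups: tuple[str, ...], probs: tuple[float, ...],
                              n_per_group: int, seed: int = 0):
    """Binomial event counts per group as a 2 x k (event, non-event) table."""
    from .phenotype import ContingencyTable

    if len(groups) != len(probs):
        raise InvalidConfigError("groups and probs must have equal length")
    if any(not 0.0 <= p <= 1.0 for p in probs):
        raise InvalidConfigError("probs must be in [0, 1]")
    if n_per_group < 1:
        raise InvalidConfigError("n_per_group must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 8]))
    events = np.array([rng.binomial(n_per_group, p) for p in probs])
    counts = np.vstack([events, n_per_group - events])
    return ContingencyTable(counts, ("event", "non_event"), tuple(groups))


def write_study(config: SyntheticConfig, out_dir: str | Path,
                go_kwargs: Mapping | None = None) -> dict[str, Path]:
    """Write the full synthetic study (expression, TFs, GO, planted edges)."""
    from .gene_selection import write_go_resources

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    network = generate_planted_network(config)
    study = generate_study(config)
    paths: dict[str, Path] = {}
    for combo, matrix in study.items():
        p = out_dir / f"expression_{combo}.tsv"
        write_expression(matrix, p)
        paths[f"expression_{combo}"] = p
    tf_path = out_dir / "tfs.tsv"
    pd.DataFrame(
        {"tf": sorted(network.tf_ids),
         "family": [network.family_map[t] for t in sorted(network.tf_ids)]}
    ).to_csv(tf_path, sep="\t", index=False)
    paths["tfs"] = tf_path
    edges_path = out_dir / "planted_edges.tsv"
    pd.DataFrame(
        [
            {
                "regulator": e.regulator,
                "target": e.target,
                "sign": "+" if e.sign > 0 else "-",
                "timepoints": ",".join(str(t) for t in sorted(e.timepoints)),
                "weight": e.weight,
            }
            for e in network.edges
        ]
    ).to_csv(edges_path, sep="\t", index=False, float_format="%.10g")
    paths["planted_edges"] = edges_path
    resources = generate_go_resources(network, seed=config.seed, **(go_kwargs or {}))
    paths.update(write_go_resources(resources, out_dir))
    return paths
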