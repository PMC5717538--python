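"""Synthetic multi-disease compendia with planted ground truth.

Every stage of the pipeline is testable without downloads: this module
generates (i) one expression study per disease, where diseases in the same
planted cluster share a signed mean shift on that cluster's effect genes,
(ii) a weighted planted-partition interaction network whose modules align
with the effect-gene programs, (iii) disease-gene lists with controlled
intra-cluster overlap, curated-style functional gene sets, and a drug
target table with approval flags.  The planted truth (cluster partition,
effect genes, modules, druggable targets) is returned alongside, so
recovery can be scored with the adjusted Rand index or exact set tests.

All generators are pure functions of (config, seed): the same
configuration always yields byte-identical outputs.

The noise model is an independent unit-variance normal per gene per
sample before additive per-batch offsets (normal with sd 0.5) — the
downstream z-transformation makes the marginal scale irrelevant, so a
richer covariance model would not change what the tests exercise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .preprocessing import ARM_CONTROL, ARM_DISEASE, ExpressionStudy


@dataclass
class SyntheticConfig:
    """Study-design knobs for the synthetic compendium.

    Defaults describe a small but fully recoverable design: 6 diseases in
    two planted clusters of 3, 500 genes, 50 effect genes per cluster with
    a standardized shift of 2 z-units, 10 samples per arm, and a 3-module
    planted-partition network aligned to the effect programs.
    """

    n_diseases: int = 6
    cluster_partition: tuple = ((0, 1, 2), (3, 4, 5))
    n_genes: int = 500
    samples_per_arm: int = 10
    n_batches_per_disease: int = 1
    effect_size: float = 2.0
    effect_genes_per_cluster: int = 50
    noise_sd: float = 1.0
    batch_sd: float = 0.5
    network_n_nodes: int = 60
    network_module_sizes: tuple = (10, 10, 10)
    p_within: float = 0.9
    p_between: float = 0.05
    edge_score_range: tuple = (0.86, 1.0)
    align_modules_to_effects: bool = True
    disease_genes_per_disease: int = 30
    disease_gene_overlap: float = 0.8
    n_functional_modules: int = 23
    functional_module_size: int = 15
    n_drugs: int = 20
    targets_per_drug: int = 3
    drug_module_fraction: float = 0.5
    approved_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_diseases": self.n_diseases,
            "n_genes": self.n_genes,
            "samples_per_arm": self.samples_per_arm,
            "n_batches_per_disease": self.n_batches_per_disease,
            "effect_genes_per_cluster": self.effect_genes_per_cluster,
            "network_n_nodes": self.network_n_nodes,
            "n_drugs": self.n_drugs,
            "targets_per_drug": self.targets_per_drug,
        }
        for name, v in counts.items():
            if v < 1 or v != int(v):
                raise ValueError(f"{name} must be a positive integer, got {v}")
        seen = set()
        for block in self.cluster_partition:
            for d in block:
                if d in seen:
                    raise ValueError("cluster_partition blocks must be disjoint")
                if not 0 <= d < self.n_diseases:
                    raise ValueError(f"disease index {d} out of range")
                seen.add(d)
        if self.effect_genes_per_cluster > self.n_genes:
            raise ValueError("effect_genes_per_cluster exceeds n_genes")
        for p in (self.p_within, self.p_between):
            if not 0.0 <= p <= 1.0:
                raise ValueError("edge probabilities must be in [0, 1]")
        lo, hi = self.edge_score_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError("edge_score_range must satisfy 0 < low <= high <= 1")
        if not 0.0 <= self.disease_gene_overlap <= 1.0:
            raise ValueError("disease_gene_overlap must be in [0, 1]")
        if sum(self.network_module_sizes) > self.network_n_nodes:
            raise ValueError("network module sizes exceed node count")

    @property
    def disease_ids(self) -> list:
        return [f"D{k:02d}" for k in range(self.n_diseases)]


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators."""

    cluster_labels: dict  # disease id -> cluster id (None = unclustered)
    effect_gene_sets: dict  # program key -> {gene: +1/-1}
    planted_modules: list = field(default_factory=list)  # list of node-id sets
    druggable_genes: set = field(default_factory=set)
    drug_targets: dict = field(default_factory=dict)  # drug -> set of genes

    def partition_labels(self, disease_ids=None) -> list:
        """Integer labels for ARI scoring: each unclustered disease is its
        own singleton class."""
        if disease_ids is None:
            disease_ids = sorted(self.cluster_labels)
        labels, next_single = [], 10_000
        for d in disease_ids:
            c = self.cluster_labels[d]
            if c is None:
                labels.append(next_single)
                next_single += 1
            else:
                labels.append(int(c))
        return labels

    def module_labels(self, nodes) -> list:
        """Planted-module label per node (singletons for background nodes)."""
        lookup = {}
        for k, mod in enumerate(self.planted_modules):
            for g in mod:
                lookup[g] = k
        labels, nxt = [], 10_000
        for nd in nodes:
            if nd in lookup:
                labels.append(lookup[nd])
            else:
                labels.append(nxt)
                nxt += 1
        return labels


def _gene_ids(n: int) -> list:
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def _plant_programs(config: SyntheticConfig, rng: np.random.Generator):
    """Disjoint signed effect-gene programs: one per cluster, one per
    unclustered disease (true-negative pairs need independent programs)."""
    genes = _gene_ids(config.n_genes)
    clustered = {d for block in config.cluster_partition for d in block}
    singles = [d for d in range(config.n_diseases) if d not in clustered]
    n_programs = len(config.cluster_partition) + len(singles)
    need = n_programs * config.effect_genes_per_cluster
    if need > config.n_genes:
        raise ValueError(
            f"{n_programs} programs x {config.effect_genes_per_cluster} effect "
            f"genes need {need} genes but only {config.n_genes} exist"
        )
    pool = rng.permutation(config.n_genes)
    programs, labels = {}, {}
    pos = 0
    for c, block in enumerate(config.cluster_partition):
        sign = int(rng.choice([-1, 1]))
        chosen = pool[pos : pos + config.effect_genes_per_cluster]
        programs[f"cluster{c}"] = {genes[i]: sign for i in chosen}
        pos += config.effect_genes_per_cluster
        for d in block:
            labels[f"D{d:02d}"] = c
    for d in singles:
        sign = int(rng.choice([-1, 1]))
        chosen = pool[pos : pos + config.effect_genes_per_cluster]
        programs[f"singleton:D{d:02d}"] = {genes[i]: sign for i in chosen}
        pos += config.effect_genes_per_cluster
        labels[f"D{d:02d}"] = None
    return genes, programs, labels


def _program_key(truth: PlantedTruth, disease_id: str) -> str:
    c = truth.cluster_labels[disease_id]
    return f"cluster{c}" if c is not None else f"singleton:{disease_id}"


def generate_compendium(config: SyntheticConfig) -> tuple[list, PlantedTruth]:
    """One :class:`ExpressionStudy` per disease plus the planted truth.

    Disease arms of clustered diseases share their cluster's signed mean
    shift (``effect_size`` z-units) on the cluster's effect genes; control
    arms are pure noise; per-batch per-gene offsets are added on top.
    """
    rng = np.random.default_rng(config.seed)
    genes, programs, labels = _plant_programs(config, rng)
    truth = PlantedTruth(cluster_labels=labels, effect_gene_sets=programs)
    gene_index = {g: i for i, g in enumerate(genes)}
    studies = []
    n_arm = config.samples_per_arm
    for d in range(config.n_diseases):
        did = f"D{d:02d}"
        n_samples = 2 * n_arm
        values = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
        arms = np.array([ARM_DISEASE] * n_arm + [ARM_CONTROL] * n_arm)
        shift = np.zeros(config.n_genes)
        for g, sign in programs[_program_key(truth, did)].items():
            shift[gene_index[g]] = sign * config.effect_size * config.noise_sd
        values[:, :n_arm] += shift[:, None]
        # balanced batch assignment within each arm, then additive offsets
        nb = config.n_batches_per_disease
        batches = np.array(
            [f"b{i % nb}" for i in range(n_arm)] + [f"b{i % nb}" for i in range(n_arm)]
        )
        for b in np.unique(batches):
            offset = rng.normal(0.0, config.batch_sd, size=config.n_genes)
            values[:, batches == b] += offset[:, None]
        studies.append(
            ExpressionStudy(
                disease_id=did,
                gene_ids=list(genes),
                values=values,
                sample_ids=[f"{did}_s{i:02d}" for i in range(n_samples)],
                arms=arms,
                batches=batches,
            )
        )
    return studies, truth


def generate_network(config: SyntheticConfig, truth: PlantedTruth) -> list:
    """Weighted planted-partition edge list aligned with the effect programs.

    Module k's nodes are drawn from cluster k's effect genes when
    ``align_modules_to_effects`` is set (and sizes permit), so dysregulated
    programs appear as network modules; remaining nodes come from the
    non-effect gene pool.  Within-module pairs get an edge with probability
    ``p_within``, all other pairs with ``p_between``; scores are uniform in
    ``edge_score_range``.  Fills ``truth.planted_modules`` and returns the
    edge list as (node1, node2, score) tuples.
    """
    rng = np.random.default_rng(config.seed + 1)
    sizes = list(config.network_module_sizes)
    if sum(sizes) > config.network_n_nodes:
        raise ValueError("module sizes exceed network size")
    genes = _gene_ids(config.n_genes)
    cluster_keys = [f"cluster{c}" for c in range(len(config.cluster_partition))]
    modules, used = [], set()
    for k, size in enumerate(sizes):
        aligned = (
            config.align_modules_to_effects
            and k < len(cluster_keys)
            and len(truth.effect_gene_sets.get(cluster_keys[k], {})) >= size
        )
        if aligned:
            members = sorted(truth.effect_gene_sets[cluster_keys[k]])[:size]
        else:
            free = [g for g in genes if g not in used and not _is_effect(truth, g)]
            if len(free) < size:
                raise ValueError("not enough free genes for network modules")
            members = [free[i] for i in rng.choice(len(free), size=size, replace=False)]
        modules.append(set(members))
        used |= set(members)
    n_bg = config.network_n_nodes - sum(sizes)
    free = [g for g in genes if g not in used and not _is_effect(truth, g)]
    if len(free) < n_bg:
        raise ValueError("not enough free genes for background nodes")
    background = [free[i] for i in rng.choice(len(free), size=n_bg, replace=False)]
    truth.planted_modules = [set(m) for m in modules]
    nodes = sorted(used | set(background))
    module_of = {}
    for k, m in enumerate(modules):
        for g in m:
            module_of[g] = k
    lo, hi = config.edge_score_range
    edges = []
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            same = a in module_of and b in module_of and module_of[a] == module_of[b]
            p = config.p_within if same else config.p_between
            if p >= 1.0 or (p > 0.0 and rng.random() < p):
                edges.append((a, b, float(rng.uniform(lo, hi))))
    return edges


def _is_effect(truth: PlantedTruth, gene: str) -> bool:
    return any(gene in s for s in truth.effect_gene_sets.values())


def generate_annotations(
    config: SyntheticConfig, truth: PlantedTruth
) -> tuple[dict, dict, list]:
    """Disease-gene lists, functional-module gene sets, and a drug table.

    Diseases of one planted cluster share a fraction
    ``disease_gene_overlap`` of their lists (a common core drawn from the
    cluster's effect genes, topped up per disease with private genes);
    lists of different clusters are disjoint.  Functional sets mirror the
    curated-module idea: the first sets copy the planted effect programs,
    the rest are random gene sets.  Each drug targets ``targets_per_drug``
    genes — a fraction of drugs aims inside the planted network modules —
    and carries an approval flag.  Fills ``truth.drug_targets`` and
    ``truth.druggable_genes``.
    """
    rng = np.random.default_rng(config.seed + 2)
    genes = _gene_ids(config.n_genes)
    size = config.disease_genes_per_disease
    n_core = int(round(config.disease_gene_overlap * size))
    free_pool = [g for g in genes if not _is_effect(truth, g)]
    rng.shuffle(free_pool)
    disease_lists: dict = {}
    for key, program in truth.effect_gene_sets.items():
        members = [d for d, c in truth.cluster_labels.items() if _matches(key, d, c)]
        program_genes = sorted(program)
        core = program_genes[:n_core]
        if len(core) < n_core:
            # effect program smaller than the requested shared core: top up
            # with cluster-specific genes from the free pool so the overlap
            # fraction holds and lists stay disjoint across clusters
            extra, free_pool = (
                free_pool[: n_core - len(core)],
                free_pool[n_core - len(core):],
            )
            if len(core) + len(extra) < n_core:
                raise ValueError("gene pool exhausted while building disease lists")
            core = core + extra
        for d in members:
            n_priv = size - n_core
            private, free_pool = free_pool[:n_priv], free_pool[n_priv:]
            if len(private) < n_priv:
                raise ValueError("gene pool exhausted while building disease lists")
            disease_lists[d] = set(core) | set(private)
    fms: dict = {}
    keys = sorted(truth.effect_gene_sets)
    for i in range(config.n_functional_modules):
        name = f"FM{i + 1}"
        if i < len(keys):
            fms[name] = set(sorted(truth.effect_gene_sets[keys[i]])[: config.functional_module_size])
        else:
            idx = rng.choice(config.n_genes, size=config.functional_module_size, replace=False)
            fms[name] = {genes[j] for j in idx}
    module_genes = sorted(set().union(*truth.planted_modules)) if truth.planted_modules else []
    drugs = []
    for k in range(config.n_drugs):
        drug = f"drug{k:03d}"
        in_module = module_genes and rng.random() < config.drug_module_fraction
        pool = module_genes if in_module else genes
        idx = rng.choice(len(pool), size=min(config.targets_per_drug, len(pool)), replace=False)
        targets = {pool[j] for j in idx}
        approved = bool(rng.random() < config.approved_fraction)
        drugs.append((drug, targets, approved))
        truth.drug_targets[drug] = set(targets)
    truth.druggable_genes = set().union(*(t for _, t, _ in drugs)) if drugs else set()
    return disease_lists, fms, drugs


def _matches(program_key: str, disease_id: str, cluster: int | None) -> bool:
    if program_key.startswith("singleton:"):
        return program_key == f"singleton:{disease_id}"
    return cluster is not None and program_key == f"cluster{cluster}"


# ---------------------------------------------------------------------------
# Writers (plain-text dialects consumed by the preprocessing/network readers)

def write_study(study: ExpressionStudy, expr_path, sheet_path) -> None:
    import pandas as pd

    pd.DataFrame(study.values, index=study.gene_ids, columns=study.sample_ids).to_csv(
        expr_path, sep="\t", float_format="%.12g"
    )
    pd.DataFrame(
        {
            "sample_id": study.sample_ids,
            "disease": study.disease_id,
            "arm": study.arms,
            "batch": study.batches,
        }
    ).to_csv(sheet_path, sep="\t", index=False)


def write_edge_list(edges: list, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b, s in edges:
            fh.write(f"{a}\t{b}\t{s:.6f}\n")


def write_gmt_sets(sets: dict, path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name in sets:
            fh.write("\t".join([name, description, *sorted(sets[name])]) + "\n")


def write_disease_gene_lists(lists: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("disease\tgene\n")
        for d in sorted(lists):
            for g in sorted(lists[d]):
                fh.write(f"{d}\t{g}\n")


def write_drug_table(drugs: list, path) -> None:
    with open(path, "w") as fh:
        fh.write("drug_id\tgene\tapproved\n")
        for drug, targets, approved in drugs:
            for g in sorted(targets):
                fh.write(f"{drug}\t{g}\t{int(approved)}\n")


def write_truth(truth: PlantedTruth, path) -> None:
    payload = {
        "cluster_labels": truth.cluster_labels,
        "effect_gene_sets": {k: dict(v) for k, v in truth.effect_gene_sets.items()},
        "planted_modules": [sorted(m) for m in truth.planted_modules],
        "druggable_genes": sorted(truth.druggable_genes),
        "drug_targets": {d: sorted(t) for d, t in truth.drug_targets.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
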