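"""Recovery and calibration experiments against planted synthetic truth.

These are the package's self-checks: how well does the end-to-end pipeline
recover a planted disease partition, how well does MCL recover planted
network modules, how often is a planted dysregulated module detected, and
are permutation p-values uniform when nothing is planted.  Partition
agreement is scored with the adjusted Rand index (ARI; 1 = identical
partitions, 0 = chance).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .dga import RegTParams, dga_matrix
from .network import MCLParams, ModuleSet, ProteinNetwork, mcl_cluster, module_activity
from .preprocessing import intersect_genes, merge_batches, ztransform
from .similarity import (
    STAT_MODULE,
    STAT_PCOR,
    cluster_diseases,
    pair_pvalues,
    partial_correlation,
    permutation_null,
)
from .synthetic import SyntheticConfig, generate_compendium, generate_network


def _ari(labels_a, labels_b) -> float:
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(labels_a, labels_b))


def _prepare(studies):
    merged = [ztransform(merge_batches([s])) for s in studies]
    _, merged = intersect_genes(merged)
    return merged


def cluster_recovery_ari(
    n_seeds: int = 20,
    base_seed: int = 0,
    n_perm: int = 100,
    alpha: float = 0.05,
    config: SyntheticConfig | None = None,
    params: RegTParams | None = None,
) -> list:
    """Per-seed ARI of recovered vs. planted disease clusters.

    Default study conditions: 6 diseases in 2 planted clusters of 3,
    500 genes, 50 effect genes per cluster, effect size 2.0, 10 samples
    per arm, label-shuffling null with 100 permutations.
    """
    if config is None:
        config = SyntheticConfig()
    if params is None:
        params = RegTParams()
    out = []
    for k in range(n_seeds):
        cfg = dataclasses.replace(config, seed=base_seed + k)
        studies, truth = generate_compendium(cfg)
        merged = _prepare(studies)
        dga = dga_matrix(merged, params)
        null = permutation_null(merged, params, n_perm, base_seed + k, STAT_PCOR)
        pcor = partial_correlation(dga.scores)
        _, labels, _ = cluster_diseases(pcor, null, alpha)
        disease_ids = [s.disease_id for s in merged]
        predicted = [labels[i] if labels[i] != 0 else -(i + 1) for i in range(len(merged))]
        out.append(_ari(truth.partition_labels(disease_ids), predicted))
    return out


def mcl_recovery_ari(
    n_seeds: int = 20,
    base_seed: int = 0,
    module_sizes: tuple = (10, 10, 10),
    p_within: float = 0.9,
    p_between: float = 0.05,
    mcl_params: MCLParams | None = None,
) -> list:
    """Per-seed ARI of MCL modules vs. the planted network partition."""
    if mcl_params is None:
        mcl_params = MCLParams()
    out = []
    for k in range(n_seeds):
        cfg = SyntheticConfig(
            seed=base_seed + k,
            network_n_nodes=sum(module_sizes),
            network_module_sizes=tuple(module_sizes),
            p_within=p_within,
            p_between=p_between,
            align_modules_to_effects=False,
        )
        _, truth = generate_compendium(cfg)
        edges = generate_network(cfg, truth)
        nodes = sorted({n for a, b, _ in edges for n in (a, b)})
        net = _network(edges)
        modules = mcl_cluster(net, mcl_params)
        label_of = {}
        for m, genes in enumerate(modules.modules.values()):
            for g in genes:
                label_of[g] = m
        predicted = [label_of.get(n, -1) for n in nodes]
        out.append(_ari(truth.module_labels(nodes), predicted))
    return out


def _network(edges) -> ProteinNetwork:
    best = {}
    for a, b, s in edges:
        key = (a, b) if a < b else (b, a)
        best[key] = max(best.get(key, 0.0), s)
    kept = [(a, b, s) for (a, b), s in sorted(best.items())]
    nodes = sorted({n for a, b, _ in kept for n in (a, b)})
    return ProteinNetwork(nodes=nodes, edges=kept)


def module_detection_power(
    n_seeds: int = 50,
    base_seed: int = 0,
    n_perm: int = 99,
    alpha: float = 0.05,
    config: SyntheticConfig | None = None,
    params: RegTParams | None = None,
) -> float:
    """Fraction of planted (module, disease) cells detected at p < alpha.

    The planted network modules are aligned with the cluster effect
    programs, so each module is truly dysregulated exactly in its
    cluster's diseases; power is measured over those cells only.
    """
    if config is None:
        config = SyntheticConfig(n_genes=200, effect_genes_per_cluster=20)
    if params is None:
        params = RegTParams(window=51)
    hits = total = 0
    for k in range(n_seeds):
        cfg = dataclasses.replace(config, seed=base_seed + k)
        studies, truth = generate_compendium(cfg)
        generate_network(cfg, truth)
        merged = _prepare(studies)
        modules = ModuleSet(
            modules={f"P{i}": m for i, m in enumerate(truth.planted_modules)},
            provenance="mcl",
        )
        null = permutation_null(
            merged, params, n_perm, base_seed + k, STAT_MODULE, modules=modules
        )
        dga = dga_matrix(merged, params)
        act = module_activity(modules, dga, null)
        for i, mid in enumerate(act.module_ids):
            cluster = int(mid[1:])
            if cluster >= len(cfg.cluster_partition):
                continue  # background module: no planted signal
            for d in cfg.cluster_partition[cluster]:
                col = act.disease_ids.index(f"D{d:02d}")
                total += 1
                hits += act.pvals[i, col] < alpha
    return hits / total


def null_pair_pvalue_ks(
    n_diseases: int = 20,
    n_genes: int = 1000,
    n_perm: int = 100,
    seed: int = 0,
    params: RegTParams | None = None,
) -> tuple[float, np.ndarray]:
    """KS test of pair p-values against uniform under a pure-noise design.

    With effect size 0 nothing distinguishes the diseases, so the
    permutation p-values of all D*(D-1)/2 pairs should be approximately
    uniform.  Returns (KS p-value, the pair p-values).
    """
    from scipy import stats as sps

    if params is None:
        params = RegTParams()
    cfg = SyntheticConfig(
        n_diseases=n_diseases,
        cluster_partition=(),
        n_genes=n_genes,
        effect_size=0.0,
        effect_genes_per_cluster=5,
        seed=seed,
    )
    studies, _ = generate_compendium(cfg)
    merged = _prepare(studies)
    dga = dga_matrix(merged, params)
    null = permutation_null(merged, params, n_perm, seed + 1, STAT_PCOR)
    pcor = partial_correlation(dga.scores)
    pvals = pair_pvalues(pcor, null)
    iu = np.triu_indices(n_diseases, k=1)
    flat = pvals[iu]
    ks = sps.kstest(flat, "uniform")
    return float(ks.pvalue), flat
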