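"""Drug-target integration: druggable-target over-representation in the
signature modules, cluster-unique module sets, and per-cluster candidate
drug lists for repurposing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import ActivityMatrix, ModuleSet
from .stats import hypergeom_overlap


@dataclass
class DrugGeneMap:
    """Drug -> target-gene sets with approval flags.

    ``druggable_genes`` defaults to the union of all targets but may be an
    expert-curated druggable-category gene set.
    """

    targets: dict  # drug id -> set of gene ids
    approved: dict  # drug id -> bool
    druggable_genes: set = field(default_factory=set)

    def __post_init__(self):
        self.targets = {d: set(g) for d, g in self.targets.items()}
        for d, genes in self.targets.items():
            if not genes:
                raise ValueError(f"drug {d!r} has an empty target set")
            if d not in self.approved:
                raise ValueError(f"drug {d!r} has no approval flag")
        if not self.druggable_genes:
            self.druggable_genes = set().union(*self.targets.values()) if self.targets else set()


def read_drug_table(path) -> DrugGeneMap:
    """Read a drug-gene TSV with columns drug_id, gene, approved (0/1)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "gene": str})
    missing = {"drug_id", "gene", "approved"} - set(df.columns)
    if missing:
        raise ValueError(f"drug table missing columns {sorted(missing)}")
    targets, approved = {}, {}
    for row in df.itertuples():
        targets.setdefault(row.drug_id, set()).add(row.gene)
        approved[row.drug_id] = bool(int(row.approved))
    return DrugGeneMap(targets=targets, approved=approved)


def druggable_overrep(signature_genes, druggable_genes, universe) -> tuple[int, float]:
    """Hypergeometric over-representation of druggable genes in a signature.

    Shares the exact code path of the disease-gene overlap test, so the two
    agree bit-for-bit on identical inputs.
    """
    signature_genes = set(signature_genes)
    if not signature_genes:
        raise ValueError("empty signature gene set")
    return hypergeom_overlap(signature_genes, set(druggable_genes), universe)


def cluster_associated_modules(
    activity: ActivityMatrix,
    cluster_members: dict,
    alpha: float = 0.05,
    require_all: bool = True,
) -> dict:
    """Modules associated with each disease cluster (2-step rule).

    A module is associated with a cluster when it is significant
    (p < alpha) in every member disease (or a strict majority, with
    ``require_all=False``) and its mean absolute activity over the
    cluster's diseases reaches the median of that summary among the
    modules passing the significance step.  This is the signature
    extraction restricted to the cluster's diseases.
    """
    if activity.pvals is None:
        raise ValueError("needs permutation p-values")
    out = {}
    for cid, members in cluster_members.items():
        cols = [activity.disease_ids.index(d) for d in members]
        sig = activity.pvals[:, cols] < alpha
        if require_all:
            stage1 = sig.all(axis=1)
        else:
            stage1 = sig.sum(axis=1) > len(cols) / 2.0
        if not stage1.any():
            out[cid] = set()
            continue
        summaries = np.abs(activity.activity[:, cols]).mean(axis=1)
        threshold = float(np.median(summaries[stage1]))
        keep = stage1 & (summaries >= threshold)
        out[cid] = {m for m, k in zip(activity.module_ids, keep) if k}
    return out


def cluster_unique_modules(cluster_to_modules: dict) -> tuple[dict, set]:
    """Per-cluster unique module sets and the modules shared by all clusters.

    unique(c) = modules(c) minus the union of every other cluster's
    modules; shared_all = the intersection over clusters.  Unique sets are
    pairwise disjoint and disjoint from shared_all.
    """
    if len(cluster_to_modules) < 2:
        raise ValueError("need at least 2 clusters")
    clusters = {c: set(m) for c, m in cluster_to_modules.items()}
    unique = {}
    for c, mods in clusters.items():
        others = set().union(*(m for k, m in clusters.items() if k != c))
        unique[c] = mods - others
    shared_all = set.intersection(*clusters.values())
    return unique, shared_all


def drugs_for_modules(
    modules: ModuleSet, drugs: DrugGeneMap, approved_only: bool = True
) -> dict:
    """Drugs with at least one target inside the given modules' gene union.

    Returns ``{drug_id: sorted hit genes}`` in drug-id order; unapproved
    drugs are excluded when ``approved_only`` is set.  Monotone: adding a
    module never removes a drug.
    """
    pool = set(modules.all_genes())
    out = {}
    for drug in sorted(drugs.targets):
        if approved_only and not drugs.approved[drug]:
            continue
        hits = sorted(drugs.targets[drug] & pool)
        if hits:
            out[drug] = hits
    return out
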