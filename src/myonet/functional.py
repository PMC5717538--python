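"""Functional-module activity (FMA) for curated muscle gene sets.

A functional module (FM) is a curated set of biomarker genes representing
one unit of skeletal-muscle physiology (neuromuscular junction, calcium
homeostasis, sarcomeric filaments, mitochondrial metabolism, ...), grouped
into families.  The FMA score of module i in disease k is the mean DGA
score of its genes — the same statistic as protein-module activity, and it
deliberately runs through the same code path.  Negative FMA means the
module's genes are down-regulated in disease relative to controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .network import ActivityMatrix, ModuleSet, module_activity


@dataclass
class FunctionalModuleSet:
    """Curated gene sets keyed by FM name, with an optional family label."""

    modules: dict  # fm id -> frozenset of genes
    families: dict  # fm id -> family / description

    def __post_init__(self):
        self.modules = {k: frozenset(v) for k, v in self.modules.items()}

    def __len__(self) -> int:
        return len(self.modules)

    def as_module_set(self) -> ModuleSet:
        return ModuleSet(modules=dict(self.modules), provenance="gmt")


def load_gene_sets(path) -> FunctionalModuleSet:
    """Parse a GMT file: ``name TAB description TAB gene [TAB gene ...]``.

    Member genes may be tab- or space-separated after the description
    field.  Duplicate genes within a set are counted once; empty sets and
    duplicate set names are rejected with the offending line number.
    """
    modules, families = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno}: {line!r}")
            name, desc = parts[0].strip(), parts[1].strip()
            genes = set()
            for fieldv in parts[2:]:
                genes.update(g for g in fieldv.split() if g)
            if not name:
                raise ValueError(f"{path}: empty set name at line {lineno}")
            if name in modules:
                raise ValueError(f"{path}: duplicate set name {name!r} at line {lineno}")
            if not genes:
                raise ValueError(f"{path}: empty gene set {name!r} at line {lineno}")
            modules[name] = frozenset(genes)
            families[name] = desc
    if not modules:
        raise ValueError(f"{path}: no gene sets found")
    return FunctionalModuleSet(modules=modules, families=families)


def fma_scores(fms: FunctionalModuleSet, dga, null_store=None) -> ActivityMatrix:
    """FMA matrix: mean DGA per FM per disease, permutation p-values attached.

    FMs are intersected with the DGA gene universe first; empty
    intersections are dropped with a warning (error if none survive).
    Identical computation to protein-module activity.
    """
    universe = set(dga.gene_ids)
    kept, dropped = {}, []
    for fm, genes in fms.modules.items():
        inter = genes & universe
        if inter:
            kept[fm] = inter
        else:
            dropped.append(fm)
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} FMs with no genes in the universe: {dropped}",
            stacklevel=2,
        )
    if not kept:
        raise ValueError("no functional module overlaps the gene universe")
    return module_activity(ModuleSet(modules=kept, provenance="gmt"), dga, null_store)


def shared_fms(pair: tuple, activity: ActivityMatrix, alpha: float = 0.05) -> dict:
    """FMs significant (p < alpha) in both diseases of an unordered pair.

    Returns ``{fm_id: "concordant" | "discordant"}`` according to whether
    the FMA signs agree — a module can be shared yet dysregulated in
    opposite directions in the two diseases.  Symmetric in the pair and
    monotone in alpha.
    """
    if activity.pvals is None:
        raise ValueError("shared-FM analysis needs permutation p-values")
    a, b = pair
    for d in (a, b):
        if d not in activity.disease_ids:
            raise KeyError(f"unknown disease {d!r}")
    ia, ib = activity.disease_ids.index(a), activity.disease_ids.index(b)
    out = {}
    for m, fm in enumerate(activity.module_ids):
        if activity.pvals[m, ia] < alpha and activity.pvals[m, ib] < alpha:
            same = activity.activity[m, ia] * activity.activity[m, ib] >= 0
            out[fm] = "concordant" if same else "discordant"
    return out
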