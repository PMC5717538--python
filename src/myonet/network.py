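"""Protein-interaction modules: edge loading, Markov clustering, module
activity (PMA) and cross-disease signature extraction.

The interaction network is a weighted undirected graph (e.g. a STRING edge
list kept above a combined-score cutoff of 0.85).  It is decomposed into
modules with the Markov Cluster algorithm (MCL): the column-stochastic
adjacency matrix is alternately *expanded* (matrix power, spreading flow)
and *inflated* (entrywise power followed by column re-normalization,
sharpening flow) until convergence; clusters are read from the attractors
of the limit matrix.  A module's activity in a disease (PMA) is the mean
DGA score of its member genes, with significance from the matched
permutation null.  "Signature" modules are those significantly active in a
strict majority of diseases and above the median absolute activity among
such modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ProteinNetwork:
    """Simple undirected weighted graph; edges stored with node1 < node2."""

    nodes: list
    edges: list  # (node1, node2, score)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class MCLParams:
    """MCL tuning: expansion power, inflation exponent, pruning, stopping."""

    expansion: int = 2
    inflation: float = 2.0
    prune_threshold: float = 1e-5
    tol: float = 1e-6
    max_iter: int = 200
    self_loop_weight: float = 1.0

    def __post_init__(self):
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class ModuleSet:
    """Gene-set modules, from MCL (a partition) or from a GMT file."""

    modules: dict  # module id -> frozenset of gene ids
    provenance: str = "mcl"
    report: dict | None = None

    def __post_init__(self):
        self.modules = {k: frozenset(v) for k, v in self.modules.items()}

    def __len__(self) -> int:
        return len(self.modules)

    def sizes(self) -> dict:
        return {k: len(v) for k, v in self.modules.items()}

    def all_genes(self) -> frozenset:
        out = frozenset()
        for v in self.modules.values():
            out |= v
        return out


@dataclass
class ActivityMatrix:
    """Module x disease activity scores (mean DGA) with permutation p-values."""

    module_ids: list
    disease_ids: list
    activity: np.ndarray
    pvals: np.ndarray | None = None

    def __post_init__(self):
        self.activity = np.asarray(self.activity, dtype=float)
        shape = (len(self.module_ids), len(self.disease_ids))
        if self.activity.shape != shape:
            raise ValueError("activity shape does not match labels")
        if self.pvals is not None:
            self.pvals = np.asarray(self.pvals, dtype=float)
            if self.pvals.shape != shape:
                raise ValueError("pvals shape does not match labels")

    def to_frame(self, which: str = "activity"):
        import pandas as pd

        data = self.activity if which == "activity" else self.pvals
        return pd.DataFrame(data, index=self.module_ids, columns=self.disease_ids)


def load_edges(path, threshold: float = 0.85) -> ProteinNetwork:
    """Load a STRING-style edge list, keeping scores strictly above threshold.

    Rows are whitespace/tab separated ``node1 node2 score``; a header row is
    skipped when its score field is not numeric.  Scores on a 0-1000 scale
    (any value > 1) are divided by 1000.  Duplicate undirected edges keep
    the maximum score; self-loops are dropped.
    """
    raw = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace("\t", " ").split()
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}")
            try:
                score = float(parts[2])
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise ValueError(
                    f"{path}: non-numeric score at line {lineno}: {parts[2]!r}"
                ) from None
            raw.append((parts[0], parts[1], score))
    if not raw:
        raise ValueError(f"{path}: no edges found")
    if any(s > 1.0 for _, _, s in raw):
        raw = [(a, b, s / 1000.0) for a, b, s in raw]
    best: dict = {}
    for a, b, s in raw:
        if a == b:
            continue
        if s <= threshold:
            continue
        key = (a, b) if a < b else (b, a)
        if s > best.get(key, -1.0):
            best[key] = s
    if not best:
        raise ValueError(f"{path}: no edge passes the score threshold {threshold}")
    edges = [(a, b, s) for (a, b), s in sorted(best.items())]
    nodes = sorted({n for a, b, _ in edges for n in (a, b)})
    return ProteinNetwork(nodes=nodes, edges=edges)


def _mcl_iterate(M: np.ndarray, params: MCLParams) -> tuple[np.ndarray, bool]:
    converged = False
    for _ in range(params.max_iter):
        new = np.linalg.matrix_power(M, params.expansion)
        new = new**params.inflation
        new[new < params.prune_threshold] = 0.0
        colsum = new.sum(axis=0)
        dead = colsum == 0.0
        if np.any(dead):  # fully pruned column: park flow on the diagonal
            new[np.where(dead)[0], np.where(dead)[0]] = 1.0
            colsum = new.sum(axis=0)
        new /= colsum
        if np.max(np.abs(new - M)) < params.tol:
            M = new
            converged = True
            break
        M = new
    return M, converged


def mcl_cluster(network: ProteinNetwork, params: MCLParams | None = None) -> ModuleSet:
    """Markov clustering of the weighted network into disjoint modules.

    Clusters are read from the converged flow matrix: attractor rows
    (positive diagonal) define candidate modules via their nonzero
    supports; overlapping attractors are merged, and a node covered by
    several modules is assigned to the one with the largest converged
    weight, ties to the lowest module id.  The output is a partition of the
    node set.
    """
    if params is None:
        params = MCLParams()
    if network.n_nodes == 0:
        raise ValueError("empty network")
    nodes = list(network.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for a, b, s in network.edges:
        i, j = index[a], index[b]
        A[i, j] = A[j, i] = s
    A[np.diag_indices(n)] += params.self_loop_weight
    M = A / A.sum(axis=0)
    M, converged = _mcl_iterate(M, params)
    if not converged:
        warnings.warn(
            f"MCL did not converge within {params.max_iter} iterations; "
            "returning clusters from the last iterate",
            stacklevel=2,
        )
    # attractors and their supports
    attractors = [i for i in range(n) if M[i, i] > 0.0]
    if not attractors:
        attractors = list(range(n))
    parent = {a: a for a in attractors}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    covered_by = {}  # node -> list of attractors whose support covers it
    for a in attractors:
        for j in np.where(M[a] > 0.0)[0]:
            covered_by.setdefault(int(j), []).append(a)
    for attrs in covered_by.values():
        for other in attrs[1:]:
            ra, rb = find(attrs[0]), find(other)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    groups = {}
    for a in attractors:
        groups.setdefault(find(a), []).append(a)
    roots = sorted(groups)  # deterministic module order: lowest attractor node
    assignment = {}
    for j, attrs in covered_by.items():
        weights = {}
        for a in attrs:
            weights.setdefault(find(a), 0.0)
            weights[find(a)] += M[a, j]
        assignment[j] = min(weights, key=lambda r: (-weights[r], roots.index(r)))
    clusters = {r: set() for r in roots}
    for j, r in assignment.items():
        clusters[r].add(nodes[j])
    uncovered = [j for j in range(n) if j not in assignment]
    modules, width = {}, len(str(n))
    mid = 0
    for r in roots:
        if clusters[r]:
            mid += 1
            modules[f"M{mid:0{width}d}"] = frozenset(clusters[r])
    for j in uncovered:
        mid += 1
        modules[f"M{mid:0{width}d}"] = frozenset([nodes[j]])
    return ModuleSet(modules=modules, provenance="mcl")


def filter_modules(modules: ModuleSet, min_size: int = 3, universe=None) -> ModuleSet:
    """Keep modules with >= min_size genes after restriction to the universe."""
    universe = None if universe is None else set(universe)
    kept = {}
    for mid, genes in modules.modules.items():
        g = genes if universe is None else genes & universe
        if len(g) >= min_size:
            kept[mid] = g
    report = {"original": len(modules), "surviving": len(kept), "min_size": min_size}
    return ModuleSet(modules=kept, provenance=modules.provenance, report=report)


def module_activity(modules: ModuleSet, dga, null_store=None) -> ActivityMatrix:
    """Per-module per-disease activity: mean DGA of the module's genes.

    When a permutation null store (statistic ``module-activity``, built for
    the same ModuleSet) is supplied, two-sided p-values are attached:
    ``p_ik = (1 + #{|null_ik| >= |obs_ik|}) / (N + 1)``, matched per module
    and disease because the null spread of a mean depends on module size.
    """
    from .similarity import _activity, _module_indices

    module_ids, rows = _module_indices(modules, dga.gene_ids)
    act = _activity(dga.scores, rows)
    pvals = None
    if null_store is not None:
        if null_store.statistic != "module-activity":
            raise ValueError("null store was not built for module activity")
        if null_store.module_ids != module_ids:
            raise ValueError("null store modules do not match the given ModuleSet")
        null_abs = np.abs(null_store.values)  # (n_perm, M, D)
        ge = (null_abs >= np.abs(act)[None, :, :]).sum(axis=0)
        pvals = (1.0 + ge) / (null_store.n_perm + 1.0)
        pvals[act == 0.0] = 1.0
    return ActivityMatrix(
        module_ids=module_ids,
        disease_ids=list(dga.disease_ids),
        activity=act,
        pvals=pvals,
    )


def signature_modules(
    activity: ActivityMatrix, alpha: float = 0.05, summary_over: str = "all"
) -> tuple[list, list, float]:
    """Two-step extraction of the cross-disease signature modules.

    Stage 1 keeps modules significant (p < alpha) in strictly more than
    half the diseases.  Each stage-1 module is summarized by its mean
    absolute activity — over all diseases by default, or over its
    significant diseases only (``summary_over="significant"``).  The
    expression threshold is the median of those summaries, and the
    signature is the stage-1 modules at or above it.

    Returns (stage1 ids, signature ids, expression_threshold).
    """
    if activity.pvals is None:
        raise ValueError("signature extraction needs permutation p-values")
    if summary_over not in ("all", "significant"):
        raise ValueError(f"unknown summary_over {summary_over!r}")
    D = len(activity.disease_ids)
    sig = activity.pvals < alpha
    stage1_mask = sig.sum(axis=1) > D / 2.0
    stage1 = [m for m, keep in zip(activity.module_ids, stage1_mask) if keep]
    if not stage1:
        warnings.warn("no module is significant in a majority of diseases", stacklevel=2)
        return [], [], float("nan")
    absact = np.abs(activity.activity)
    if summary_over == "all":
        summaries = absact.mean(axis=1)
    else:
        with np.errstate(invalid="ignore"):
            summaries = np.where(
                sig.any(axis=1), (absact * sig).sum(axis=1) / sig.sum(axis=1), 0.0
            )
    s1 = summaries[stage1_mask]
    threshold = float(np.median(s1))
    signature = [m for m, s in zip(stage1, s1) if s >= threshold]
    return stage1, signature, threshold


def write_gmt(modules: ModuleSet, path, description: str = "mcl_module") -> None:
    with open(path, "w") as fh:
        for mid, genes in modules.modules.items():
            fh.write("\t".join([mid, description, *sorted(genes)]) + "\n")
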