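"""Disease similarity: partial correlations of DGA profiles, permutation
nulls, and complete-linkage clustering with a significance-mapped tree cut.

Two diseases are similar when their gene-wise DGA profiles correlate after
controlling for every other disease in the compendium; the partial
correlation is read off the inverse of the disease-by-disease correlation
matrix.  Significance comes from a label-shuffling permutation scheme:
disease/control labels are shuffled within each study, DGA scores are
recomputed, and the pairwise partial correlations of the shuffled data form
one pooled background distribution for all pairs.  The dendrogram cut that
defines disease clusters is the height corresponding to the chosen
significance level on that background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .dga import DGAMatrix, RegTParams, dga_matrix

STAT_PCOR = "pairwise-pcor"
STAT_MODULE = "module-activity"


def partial_correlation(X) -> np.ndarray:
    """All pairwise partial correlations of the columns of ``X``.

    ``X`` is an observations x variables matrix (here genes x diseases).
    With correlation matrix R and precision matrix Omega = R^-1,

        pcor_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj)

    i.e. the correlation of columns i and j controlling for all others.
    Raises a singularity error naming the offending columns when R cannot
    be inverted (e.g. a duplicated column).
    """
    X = np.asarray(X, dtype=float)
    n_obs, n_var = X.shape
    if n_obs <= n_var:
        raise ValueError(f"need more observations ({n_obs}) than variables ({n_var})")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = list(np.where(sds == 0)[0])
        raise ValueError(f"constant columns {bad} have undefined correlations")
    R = np.corrcoef(X, rowvar=False)
    if np.linalg.cond(R) > 1e12:
        dup = [
            (i, j)
            for i in range(n_var)
            for j in range(i + 1, n_var)
            if abs(R[i, j]) > 1 - 1e-10
        ]
        raise np.linalg.LinAlgError(
            f"correlation matrix is singular; near-duplicate column pairs: {dup}"
        )
    omega = np.linalg.inv(R)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return np.clip((pcor + pcor.T) / 2.0, -1.0, 1.0)


@dataclass
class NullStore:
    """Permutation null samples for one statistic.

    ``values`` has shape (n_perm, n_pairs) for the pairwise partial
    correlation statistic (upper-triangle order) and
    (n_perm, n_modules, n_diseases) for module activity.
    """

    statistic: str
    values: np.ndarray
    disease_ids: list
    module_ids: list | None = None
    seed: int | None = None

    @property
    def n_perm(self) -> int:
        return self.values.shape[0]

    def pooled(self) -> np.ndarray:
        return self.values.ravel()


def _shuffle_arms(studies: list, rng: np.random.Generator) -> list:
    """Shuffle arm labels independently within each study (sizes preserved)."""
    return [replace(s, arms=rng.permutation(s.arms)) for s in studies]


def _module_indices(modules, gene_ids) -> tuple[list, list]:
    lookup = {g: i for i, g in enumerate(gene_ids)}
    ids, rows = [], []
    for mid, genes in modules.modules.items():
        idx = sorted(lookup[g] for g in genes if g in lookup)
        if not idx:
            raise ValueError(f"module {mid!r} has no genes in the universe; filter first")
        ids.append(mid)
        rows.append(np.array(idx))
    return ids, rows


def _activity(scores: np.ndarray, rows: list) -> np.ndarray:
    return np.vstack([scores[r].mean(axis=0) for r in rows])


def permutation_null(
    studies: list,
    params: RegTParams | None = None,
    n_perm: int = 100,
    seed: int = 0,
    statistic: str = STAT_PCOR,
    modules=None,
) -> NullStore:
    """Label-shuffling permutation null for a similarity statistic.

    For each of ``n_perm`` permutations the disease/control labels are
    shuffled independently within every study (arm sizes preserved), the
    DGA matrix is recomputed, and the requested statistic is evaluated:
    all pairwise partial correlations (pooled background) or the module
    activity matrix for ``modules``.  Reproducible from ``seed``.
    """
    if statistic not in (STAT_PCOR, STAT_MODULE):
        raise ValueError(f"unknown permutation statistic {statistic!r}")
    if statistic == STAT_MODULE and modules is None:
        raise ValueError("module-activity statistic needs a ModuleSet")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if params is None:
        params = RegTParams()
    rng = np.random.default_rng(seed)
    module_ids = rows = None
    if modules is not None:
        module_ids, rows = _module_indices(modules, studies[0].gene_ids)
    iu = None
    out = []
    for _ in range(n_perm):
        perm_dga = dga_matrix(_shuffle_arms(studies, rng), params)
        if statistic == STAT_PCOR:
            pc = partial_correlation(perm_dga.scores)
            if iu is None:
                iu = np.triu_indices(pc.shape[0], k=1)
            out.append(pc[iu])
        else:
            out.append(_activity(perm_dga.scores, rows))
    return NullStore(
        statistic=statistic,
        values=np.stack(out),
        disease_ids=[s.disease_id for s in studies],
        module_ids=module_ids,
        seed=seed,
    )


def pair_pvalues(pcor: np.ndarray, null_store: NullStore, smooth: bool = True) -> np.ndarray:
    """One-sided upper-tail permutation p-values against the pooled null.

    ``p_ij = (1 + #{null >= pcor_ij}) / (N + 1)`` with add-one smoothing
    (``smooth=False`` gives the raw-count ``#{null >= obs} / N`` variant,
    which can return 0).  Monotone decreasing in the observed correlation.
    """
    null = np.sort(null_store.pooled())
    if null.size == 0:
        raise ValueError("empty null store")
    n = null.size
    ge = n - np.searchsorted(null, np.asarray(pcor), side="left")
    if smooth:
        p = (1.0 + ge) / (n + 1.0)
    else:
        p = ge / float(n)
    return 0.5 * (p + p.T)


def complete_linkage(dist: np.ndarray) -> np.ndarray:
    """Complete-linkage agglomeration with a lexicographic tie-break.

    Returns a scipy-style linkage matrix (n-1) x 4.  At every step the pair
    of active clusters at minimal complete (maximum) distance is merged;
    exact ties go to the lexicographically smallest (id, id) pair.  Cluster
    ids follow the scipy convention: originals 0..n-1, merges n, n+1, ...
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    dmat = {}
    for i in range(n):
        for j in range(i + 1, n):
            dmat[(i, j)] = dist[i, j]
    active = {i: 1 for i in range(n)}  # id -> cluster size
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = min(dmat.items(), key=lambda kv: (kv[1], kv[0]))
        (a, b), h = best
        Z[step] = [a, b, h, active[a] + active[b]]
        size = active.pop(a) + active.pop(b)
        for k in active:
            da = dmat.pop((min(a, k), max(a, k)))
            db = dmat.pop((min(b, k), max(b, k)))
            dmat[(k, next_id)] = max(da, db)
        del dmat[(a, b)]
        active[next_id] = size
        next_id += 1
    return Z


def cut_tree(Z: np.ndarray, height: float, n: int) -> np.ndarray:
    """Flat clusters from merges at height <= ``height``.

    Returns integer labels; clusters of size >= 2 get ids 1, 2, ... in order
    of their smallest member, singletons get 0 ("unclustered").
    """
    parent = list(range(n + len(Z)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step, (a, b, h, _) in enumerate(Z):
        if h <= height:
            new = n + step
            parent[find(int(a))] = new
            parent[find(int(b))] = new
    roots = [find(i) for i in range(n)]
    members = {}
    for i, r in enumerate(roots):
        members.setdefault(r, []).append(i)
    labels = np.zeros(n, dtype=int)
    next_label = 1
    for r in sorted(members, key=lambda r: members[r][0]):
        if len(members[r]) >= 2:
            labels[members[r]] = next_label
            next_label += 1
    return labels


@dataclass
class SimilarityResult:
    """Pairwise disease similarity with significance and clustering."""

    disease_ids: list
    pcor: np.ndarray
    pvals: np.ndarray
    null_samples: np.ndarray
    linkage: np.ndarray
    clusters: dict
    cut_height: float
    alpha: float

    def significant_pairs(self, alpha: float | None = None) -> list:
        """Unordered disease pairs with permutation p below alpha."""
        alpha = self.alpha if alpha is None else alpha
        out = []
        d = self.disease_ids
        for i in range(len(d)):
            for j in range(i + 1, len(d)):
                if self.pvals[i, j] < alpha:
                    out.append((d[i], d[j], float(self.pcor[i, j]), float(self.pvals[i, j])))
        return out


def cluster_diseases(
    pcor: np.ndarray, null_store: NullStore, alpha: float = 0.05
) -> tuple[np.ndarray, dict, float]:
    """Complete-linkage clustering of 1 - pcor with a significance cut.

    The cut height is ``h* = 1 - q`` where ``q`` is the (1 - alpha) quantile
    of the pooled null correlations, so subtrees entirely below h* join
    diseases whose similarity exceeds what the permutation background
    produces at level alpha.  Singletons are reported as unclustered
    (label 0).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    pcor = np.asarray(pcor, dtype=float)
    n = pcor.shape[0]
    q = float(np.quantile(null_store.pooled(), 1.0 - alpha))
    height = 1.0 - q
    Z = complete_linkage(1.0 - pcor)
    labels = cut_tree(Z, height, n)
    return Z, {i: int(lab) for i, lab in enumerate(labels)}, height


def similarity_analysis(
    studies: list,
    params: RegTParams | None = None,
    n_perm: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    dga: DGAMatrix | None = None,
    null_store: NullStore | None = None,
) -> SimilarityResult:
    """End-to-end similarity stage: DGA -> pcor -> p-values -> clusters."""
    if params is None:
        params = RegTParams()
    if dga is None:
        dga = dga_matrix(studies, params)
    if null_store is None:
        null_store = permutation_null(studies, params, n_perm, seed, STAT_PCOR)
    pcor = partial_correlation(dga.scores)
    pvals = pair_pvalues(pcor, null_store)
    Z, labels, height = cluster_diseases(pcor, null_store, alpha)
    clusters = {dga.disease_ids[i]: lab for i, lab in labels.items()}
    if all(v == 0 for v in clusters.values()):
        warnings.warn("no disease cluster below the significance cut", stacklevel=2)
    return SimilarityResult(
        disease_ids=list(dga.disease_ids),
        pcor=pcor,
        pvals=pvals,
        null_samples=null_store.pooled(),
        linkage=Z,
        clusters=clusters,
        cut_height=height,
        alpha=alpha,
    )
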