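"""Set-overlap statistics: hypergeometric disease-gene overlap per disease
pair and a one-sided Fisher exact test of concordance between two notions
of disease similarity (expression-based vs. shared disease genes).

The overlap null is that each disease's gene list is drawn uniformly at
random from the gene universe; the p-value is the exact upper tail
P(X >= observed overlap) of the hypergeometric distribution.  The Fisher
concordance test asks whether disease pairs called similar by expression
are enriched among pairs sharing known disease genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from scipy import stats as sps


@dataclass
class DiseaseGeneLists:
    """Curated gene lists per disease plus the sampling universe."""

    lists: dict  # disease -> set of genes
    universe: set

    def __post_init__(self):
        self.universe = set(self.universe)
        self.lists = {d: set(g) for d, g in self.lists.items()}
        for d, genes in self.lists.items():
            extra = genes - self.universe
            if extra:
                raise ValueError(
                    f"disease {d!r} lists {len(extra)} genes outside the universe"
                )


@dataclass(frozen=True)
class ConcordanceTable:
    """2x2 cross-classification of disease pairs by two significance calls.

    a: significant under both criteria; b: gene-criterion only;
    c: expression-criterion only; d: neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"count {name}={v} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def hypergeom_overlap(setA, setB, universe) -> tuple[int, float]:
    """Exact upper-tail overlap p-value: P(X >= |A∩B|).

    X is hypergeometric with population N=|universe|, K=|A| marked items
    and n=|B| draws.  Both sets must be subsets of the universe.
    """
    universe = set(universe)
    setA, setB = set(setA), set(setB)
    if not setA <= universe or not setB <= universe:
        raise ValueError("both sets must be subsets of the universe")
    k = len(setA & setB)
    p = float(sps.hypergeom.sf(k - 1, len(universe), len(setA), len(setB)))
    return k, min(p, 1.0)


def pairwise_overlap_table(lists: DiseaseGeneLists, alpha: float = 0.05):
    """Hypergeometric overlap for every unordered disease pair.

    Returns a DataFrame (disease_a, disease_b, overlap, p) covering all
    D*(D-1)/2 pairs and the set of pairs with raw p < alpha.  No multiple
    testing correction is applied: the significant-pair count is reported
    against raw p-values.
    """
    import pandas as pd

    diseases = sorted(lists.lists)
    if len(diseases) < 2:
        raise ValueError("need at least 2 diseases")
    rows = []
    for a, b in combinations(diseases, 2):
        k, p = hypergeom_overlap(lists.lists[a], lists.lists[b], lists.universe)
        rows.append((a, b, k, p))
    table = pd.DataFrame(rows, columns=["disease_a", "disease_b", "overlap", "p"])
    significant = {(r.disease_a, r.disease_b) for r in table.itertuples() if r.p < alpha}
    return table, significant


def fisher_concordance(table: ConcordanceTable) -> float:
    """One-sided (enrichment) Fisher exact p-value for a 2x2 table.

    P(X >= a) with X hypergeometric(N=a+b+c+d, K=a+b, n=a+c) — the exact
    probability, under fixed margins, of seeing at least the observed
    number of doubly-significant pairs.
    """
    p = float(sps.hypergeom.sf(table.a - 1, table.total, table.a + table.b, table.a + table.c))
    return min(p, 1.0)


def concordance_from_pairs(all_pairs, gene_significant, expr_significant) -> ConcordanceTable:
    """Build the 2x2 concordance table from pair sets (unordered keys)."""

    def norm(pairs):
        return {tuple(sorted(p)) for p in pairs}

    allp, gs, es = norm(all_pairs), norm(gene_significant), norm(expr_significant)
    if not gs <= allp or not es <= allp:
        raise ValueError("significant pairs must be a subset of all evaluated pairs")
    a = len(gs & es)
    b = len(gs - es)
    c = len(es - gs)
    d = len(allp - gs - es)
    return ConcordanceTable(a=a, b=b, c=c, d=d)
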