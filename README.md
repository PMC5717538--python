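# myonet

Quantifying similarity among diseases from case/control expression
studies, with module-level activity scoring on a protein-interaction
network and drug–target integration. The package was designed around
compendia of skeletal-muscle diseases (dystrophies, myopathies,
mitochondrial and inflammatory disorders profiled against controls on a
shared microarray platform), but nothing in it is muscle-specific.

## Who this is for

Computational biologists who have several case/control expression studies
— one per disease — and want to ask: *which diseases look alike at the
transcriptome level, do those similarities agree with known disease
genes, which protein and functional modules carry the shared signal, and
which approved drugs already target them?*

## The method

1. **Differential gene activity (DGA).** For each gene *g* in disease
   *k*, a variance-regularized two-sample t-statistic contrasts the
   disease arm with the control arm of z-transformed expression:

   σ̃² = (v₀·σ²_bg + (n−1)·s²) / (v₀ + n − 1),
   t = (m_d − m_c) / √(σ̃²_d/n_d + σ̃²_c/n_c)

   where σ²_bg is a background variance estimated from genes of similar
   mean expression and v₀ = max(c − n, 0) is the prior weight. With
   v₀ = 0 this is exactly Welch's t.

2. **Disease similarity.** The partial Pearson correlation of DGA
   columns, pcor_ij = −Ω_ij/√(Ω_ii Ω_jj) with Ω the inverse correlation
   matrix, measures the similarity of diseases *i* and *j* controlling
   for all others. Significance comes from shuffling disease/control
   labels within each study, recomputing DGA, and pooling the permuted
   pairwise correlations into one background distribution (100
   permutations by default). Diseases are clustered by complete linkage
   on 1 − pcor; the tree is cut at the height corresponding to the
   α = 0.05 quantile of the background.

3. **Module activity (PMA / FMA).** The interaction network (e.g. a
   STRING edge list at combined score > 0.85) is decomposed with the
   Markov Cluster algorithm (expansion/inflation on the column-stochastic
   adjacency matrix); modules with ≥ 3 genes in the measured universe are
   scored per disease as the mean DGA of their genes, with matched
   permutation p-values. Curated functional gene sets (GMT files) are
   scored identically. "Signature" modules are significant in a strict
   majority of diseases and at or above the median absolute activity
   among such modules.

4. **Associations and drugs.** Disease-gene list overlap is tested with
   the exact hypergeometric upper tail; concordance between
   expression-based and gene-based similarity is a one-sided Fisher exact
   test; druggable-target over-representation in signature modules uses
   the same hypergeometric tail; cluster-unique modules map to candidate
   repurposable drugs.

Every stage can run on synthetic compendia with planted ground truth
(clusters, effect-gene programs, network modules, drug targets), so the
whole pipeline is testable without downloads.

## Worked example

```python
from myonet import PipelineConfig, SyntheticConfig, run_pipeline

config = PipelineConfig(
    synthetic=SyntheticConfig(n_genes=500, effect_genes_per_cluster=50,
                              samples_per_arm=10),
    n_perm=100, seed=1,
)
result = run_pipeline(config)

print("clusters:", result.similarity.clusters)
print("significant pairs:", [(a, b, round(r, 3))
                             for a, b, r, _ in result.similarity.significant_pairs()])
print("modules kept:", len(result.modules), "of", result.modules.report["original"])
print("cluster-unique modules:", result.unique_modules)
print("fisher concordance p:", round(result.fisher_p, 5))
```

Output:

```
clusters: {'D00': 1, 'D01': 1, 'D02': 1, 'D03': 2, 'D04': 2, 'D05': 2}
significant pairs: [('D00', 'D01', 0.367), ('D00', 'D02', 0.373), ('D01', 'D02', 0.39), ('D03', 'D04', 0.33), ('D03', 'D05', 0.413), ('D04', 'D05', 0.397)]
modules kept: 5 of 9
cluster-unique modules: {1: {'M02'}, 2: {'M03'}}
fisher concordance p: 0.0002
```

The synthetic design plants two 3-disease clusters sharing 50-gene effect
programs at a 2 z-unit shift. The pipeline recovers exactly that
partition; all six significant pairs are intra-cluster, with partial
correlations around 0.33–0.41 against a permutation background. Each
cluster's planted network module ends up in its unique module set, and
the Fisher test confirms that expression-based similarity concentrates on
pairs that also share disease genes.

The same pipeline runs from the shell:

```bash
myonet simulate --seed 1 --out data/
myonet run-all config.yaml --out results/
```

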