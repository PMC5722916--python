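# coexkit

Weighted gene co-expression modules, enrichment statistics and
protein–protein-interaction (PPI) bottleneck genes from bulk RNA-seq count
matrices.

`coexkit` is aimed at transcriptomics analysts who start from a gene-level
read-count matrix over several cell types or conditions and want the classic
systems-biology readout: which genes move together (co-expression modules),
which cell type each module tracks, whether interesting gene sets
(tissue-specific markers, ontology terms, up-regulated genes) are
over-represented in a module beyond chance, and which proteins sit at the
choke points of the modules' interaction network.

## The statistics at the core

**TPM normalization.** Counts are divided first by gene length in kb and
then by the per-sample total, scaled to 10⁶: TPMᵍₛ = 10⁶ · (cᵍₛ/ℓᵍ) /
Σᵢ(cᵢₛ/ℓᵢ). Every column sums to 10⁶ by construction. Analysis happens on
log₂(TPM+1), keeping genes with mean TPM > 1 and then the top quartile by
variance.

**Signed-hybrid weighted network.** The adjacency is aᵢⱼ = cor(xᵢ,xⱼ)^β for
positive correlations and 0 otherwise. β is the smallest candidate power
whose connectivity distribution fits a scale-free law: genes are binned by
connectivity kᵢ = Σⱼaᵢⱼ and log₁₀ p(k) is regressed on log₁₀ k; the fit must
reach R² ≥ 0.9 with negative slope. Genes are clustered by average linkage
on 1 − TOM, where the topological overlap TOMᵢⱼ = (ℓᵢⱼ + aᵢⱼ)/(min(kᵢ,kⱼ) +
1 − aᵢⱼ) rewards shared neighbourhoods. The dendrogram is cut at the
adaptive height that maximizes the number of clusters reaching the minimum
module size; modules whose eigengenes correlate above 0.75 are merged.

**Eigengenes and membership.** Each module is summarized by its eigengene —
the first principal component of the standardized member expression, sign-
oriented along the mean member profile. Module membership K_ME is the
correlation of a gene with a module eigengene; genes with K_ME > 0.75 join
the module's membership set (multi-membership allowed). Module–cell-type
association is the Pearson correlation of the eigengene with the binary
trait indicator, with p-values from t = r√(n−2)/√(1−r²) on n−2 df.

**Enrichment.** Over-representation uses the hypergeometric upper tail
P(X ≥ k) for k hits in n draws from a universe of N genes with K annotated,
evaluated in log space; Benjamini–Hochberg FDR across sets; a set passes at
FDR ≤ 0.05, fold enrichment (k/n)/(K/N) ≥ 1.5 and k ≥ 5. Up-regulated gene
sets use |fold-change| ≥ 2 and adjusted p ≤ 0.01 (inclusive). A
size-matched randomization test draws 10,000 random modules from the
universe and reports p = #{null > observed}/10,000.

**Bottlenecks.** PPI edges with combined confidence ≥ 0.7 among the module
genes form a simple graph; on its largest connected component each node's
unnormalized shortest-path betweenness is computed, and genes at or above
the 95th percentile (the top 5 %, ties included) are flagged as bottlenecks.

A synthetic-data generator (`coexkit.simulate`) plants all of this structure
— co-expression modules with cell-type-specific activity, tissue markers,
DE genes, and a two-community PPI graph joined by a known bridge — so every
stage is testable against exact ground truth.

## Worked example

```python
import coexkit as ck

cfg = ck.SimulationConfig(seed=42)                       # 6 cell types, 26 replicates
counts, annotation, traits, truth = ck.simulate_expression(cfg)
tpm = ck.compute_tpm(counts, annotation)
logtpm = ck.log_transform(tpm)
expressed = ck.filter_expressed(tpm)                     # mean TPM > 1
quartile = ck.select_top_quartile_variance(logtpm, expressed.selected_gene_ids)
net = ck.CoexpressionNetwork(logtpm.values.loc[list(quartile.selected_gene_ids)], traits)
res = net.fit()
print(res.summary())
```

prints (abridged):

```
expressed genes (mean TPM > 1): 6000
top-quartile by variance:      1500
Weighted co-expression network
  genes: 1500   samples: 26
  soft-threshold power: 12
  modules: 23   unassigned genes: 318

 module  size  kme_members top_trait     r            p
      1   131          116       ct3 0.312 1.210000e-01
      2    96           87       ct1 0.940 9.820000e-13
      5    60           50       ct4 0.872 6.420000e-09
      6    59           53       ct5 0.873 6.140000e-09
      7    56           53       ct3 0.885 1.900000e-09
      9    51           48       ct2 0.928 9.340000e-12
      ...
```

The five planted modules surface as the strongly trait-correlated clusters
(modules 2, 5, 6, 7 and 9 here, each tracking one cell type with r ≈ 0.87–
0.94 and p < 10⁻⁸); the remaining, weakly associated clusters come from the
generator's structured background. `res.labels`, `res.eigengenes`, `res.kme`
and `res.membership_sets` carry the full decomposition, and
`ck.gene_set_enrichment`, `ck.randomization_module_test` and
`ck.bottleneck_analysis` take it from there.

The same analysis runs end-to-end from the shell:

```sh
coexkit run-all --config config.yaml --out results/
```

writing every intermediate (TPM, selections, labels, eigengenes, K_ME,
module–trait tables, enrichment and bottleneck calls) as TSV plus a
`manifest.json` of checksums; identical config and seed give byte-identical
outputs.

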