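# Methods

This note records the models, parameter choices and numerical conventions
behind `coexkit`, and what the synthetic benchmarks do and do not show.

## Normalization and gene selection

TPM is computed per sample as count / gene-length(kb), renormalized so each
column sums to 10⁶; a sample with zero total counts or a gene without a
length annotation is an error, not a silent repair. Log transformation is
log₂(TPM+1). The expression filter keeps genes with **mean** TPM across all
samples strictly greater than 1; per-sample ("any"/"all") variants are
available via the `mode` flag, but the mean rule is the default because a
single per-gene number makes the filter reproducible as one gene count.
Top-quartile selection keeps the ⌊n/4⌋ genes of highest unbiased (n−1)
sample variance of log₂(TPM+1) — floor, not rounding, because 19,261 input
genes must reduce to exactly 4,815 — with ties at the cut broken by
lexicographic gene id so the selection is a pure function of the data.
Variance is computed on the log scale (standard practice for co-expression
work); a linear-scale variant was deliberately not implemented.

Sample PCA centers genes across samples and takes the SVD of the
samples × genes matrix. Component signs are fixed by making the
largest-magnitude gene loading positive; variance fractions are σᵢ²/Σσ²,
non-increasing and summing to 1.

## Co-expression network

* **Adjacency** is signed-hybrid: aᵢⱼ = max(cor, 0)^β with zero diagonal.
  Negative correlations are zeroed rather than folded in, so modules are
  groups of positively co-varying genes.
* **Power selection**: candidate powers 1–10 and 12–30 (even); for each, the
  connectivity vector is split into 10 equal-width bins, within-bin mean k
  and frequency are computed, and log₁₀ p(k) is regressed on log₁₀ mean-k
  over non-empty bins. The chosen β is the smallest whose R² ≥ 0.9 **with a
  negative slope** — a rising log-log fit is a degree distribution
  concentrating at high k, not a scale-free one, so positive-slope fits
  never qualify, including in the fallback (best negative-slope R², with a
  warning) when no candidate reaches the target.
* **TOM**: TOMᵢⱼ = (ℓᵢⱼ + aᵢⱼ)/(min(kᵢ,kⱼ) + 1 − aᵢⱼ), unit diagonal,
  clipped to [0,1]; clustering is average linkage on 1 − TOM with genes
  sorted lexicographically first so tie handling is reproducible.
* **Tree cut**: the dendrogram is cut at the merge height that maximizes the
  number of clusters reaching `min_module_size` (default 30); among heights
  achieving that count the highest (coarsest) wins. This adaptive rule finds
  however many well-separated blocks the tree contains at any problem size,
  whereas a fixed quantile-of-merge-heights cut bounds the cluster count by
  the quantile and fails below ~100·(1−q) clusters; the fixed-quantile
  variant remains available through `cut_height_quantile`. Clusters below
  the minimum size become label 0 (unassigned); ids are renumbered by
  decreasing size. A known limitation: on structureless data the root
  itself is a "cluster", so pure noise yields one module rather than none —
  downstream trait statistics are what separate it from a real module.
* **Merging**: eigengene correlation > 0.75 merges modules, most-correlated
  pair first, eigengenes recomputed after every merge; the module count
  strictly decreases, so termination is guaranteed.
* **Eigengene**: first right singular vector of the standardized member
  rows, unit norm, sign-oriented to correlate positively with the mean
  member profile. Zero-variance members are excluded with a warning.
* **Module–trait**: Pearson correlation of eigengenes with the binary
  cell-type indicator columns; two-sided p from the exact t transform.
  p-values are reported unadjusted (BH is available as a separate utility)
  since module×trait grids are small and readers typically inspect the full
  grid.

## Enrichment statistics

The hypergeometric upper tail is summed in log space (gammaln +
logsumexp), so p-values of 10⁻³⁰⁰ keep full relative precision. The
tissue-specificity scan takes the universe to be all annotated genes by
default (callers can pass the expressed-gene intersection instead); K for a
tissue counts genes of any specificity category (tissue enriched, group
enriched, tissue enhanced) naming that tissue. Fold enrichment is
(k/n)/(K/N).

The randomization test draws size-matched gene sets without replacement
(vectorized via per-row argpartition of random keys, chunked to bound
memory) and counts nulls **strictly greater** than the observed overlap, as
the procedure is defined; this is anti-conservative relative to the
standard add-one estimator, so a reported 0 is displayed as "< 1/n_random"
and the `greater_equal` convention is available as an option. Under the
null the strict rule makes P(p ≤ 0.05) fall slightly below 0.05 because of
the discreteness of the overlap count — the calibration band used in the
acceptance checks, [0.02, 0.09], reflects that.

Up-regulation filtering is inclusive at both boundaries (|log₂FC| ≥ 1 for a
2-fold change, adjusted p ≤ 0.01). Gene-set enrichment applies BH across
the collection and the FDR ≤ 0.05 / fold ≥ 1.5 / ≥ 5 hits filter.

## PPI bottlenecks

Edges at combined confidence ≥ 0.7 (inclusive) among the supplied genes
form a simple unweighted graph; scores arriving on the STRING 0–1000
integer scale are divided by 1000 at load time, duplicate undirected edges
keep the maximum score, and self-edges are dropped. The largest connected
component (ties to the component holding the lexicographically smallest
node) is analyzed with unnormalized Brandes betweenness — each unordered
pair counted once, fractional path counting. Bottlenecks are the genes in
the top 5 %: the threshold is the q-th largest score with q = max(1,
⌈0.05·n⌉), inclusive comparison, so ties at the threshold are all called
and the set can exceed 5 % of nodes. Because the percentile rule is
invariant to monotone rescaling, normalizing betweenness first would not
change the bottleneck set.

## Synthetic data generator

The generator emulates a six-cell-type bulk RNA-seq compendium with 26
biological replicates (5,5,4,4,4,4) and five planted 50-gene modules, one
active per cell type. For module m and sample s of cell type t the latent
activity is e = profile[m,t] + N(0,1); member gene g has latent
λ = a·e + √(1−a²)·noise, with loadings a drawn uniformly on [0.8, 1.0].
The mean pairwise latent correlation of members is exactly the 0.81 target
(E[a]² = 0.9²) while individual memberships span a realistic continuum —
real modules are not cliques of identical genes, and a loading continuum is
also what gives the soft-thresholded network its decaying degree
distribution. `within_module_cor` is calibrated conditional on cell type
(i.e., with flat activity profiles); with cell-type contrasts active, the
marginal correlation is higher because members also share the on/off
pattern.

Background genes are not i.i.d. noise: each gets its own mild cell-type
baseline, drawn with a heavy-tailed (lognormal, σ_log = 0.8, median 0.6
latent units) per-gene amplitude over a replicate noise floor of 0.5. Two
observations motivated this. Biologically, no real gene is perfectly flat
across cell types, and gene-level variability spans orders of magnitude.
Statistically, the smooth correlation continuum these baselines induce is
what makes the selected network's connectivity distribution scale-free —
with i.i.d. background the degree histogram is a two-point mixture
(background spike + module hump) that no power law fits. Module activity
amplitude defaults to 6 latent units (~3 log₂ units of expression after the
softplus link — conservative next to real cell-type markers).

Counts are Poisson around depth · length_kb · softplus(λ), renormalized per
sample, so TPM recovers softplus(λ) in expectation; an optional
negative-binomial dispersion adds over-dispersion for robustness checks.
Tissue-specific markers are background genes boosted by 2 latent units in
their tissue; DE genes (5 % of genes, |log₂FC| = 2, alternating signs) are
drawn from the remaining background pool so each planted feature has
unambiguous ground truth. The simulated PPI graph builds two Erdős–Rényi
communities (p_in = 0.9, scores in [0.7,1]) on the first two modules'
genes, joined only through one designated background "bridge" gene (the
true maximum-betweenness bottleneck), plus sub-threshold decoy edges
between the communities. Everything is a pure function of the mandatory
seed.

What passing these benchmarks does **not** show: the generator has no batch
effects, no library-composition bias beyond length × abundance, no doublet
or contamination structure, and its DE truth is injected rather than
estimated — so the benchmarks validate the statistical machinery, not
robustness to the full messiness of public RNA-seq archives.

## Pipeline determinism and problem sizes

`run_all` derives independent per-stage seeds from the single master seed
via `SeedSequence([seed, stage_index])`, so adding a stage never perturbs
earlier stages' random streams. The manifest records the config hash
(excluding the output directory), per-stage SHA-256 checksums of every
output file, and library versions; it contains no wall-clock information,
so identical config + seed give byte-identical manifests. Logging goes to
stderr with `[stage:...]` markers; a stage failure aborts with the stage
name and a nonzero exit code.

The default benchmark sizes — 6,000 genes simulated, 1,500 in the network,
20 seeds for recovery tallies, 10,000 draws per randomization test, 200
replicates for null calibration, 100 brute-force betweenness graphs of ≤ 12
nodes — were chosen so the complete suite and the acceptance script each
finish in about a minute on one CPU while keeping every statistical check
well-powered. The recovery ARI is computed over genes assigned in both the
recovered and the planted labelings: genes the network assigns that the
generator labels background are dominated by planted DE/tissue genes that
genuinely share a module's cell-type pattern, and counting them would score
the generator's labeling rather than the method.
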