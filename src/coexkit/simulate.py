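"""Synthetic RNA-seq datasets with planted structure for every pipeline stage.

The generator emulates the statistical shape of a multi-cell-type bulk
RNA-seq compendium: a handful of co-expression modules whose activity
differs between cell types, tissue-specific marker genes, differentially
expressed genes between a designated pair of cell types, Poisson (optionally
negative-binomial) sequencing counts, and a protein-interaction graph built
from two module communities joined by a single bridge node of known maximal
betweenness.  Everything is a pure function of the mandatory seed, so
downstream stages can be tested against exact ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneAnnotation,
    PPIEdgeList,
    TraitDesign,
    DEResultTable,
    GeneSetCollection,
    ValidationError,
    _canonical_edges,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_expression",
    "simulate_ppi",
    "de_table_from_truth",
    "gene_sets_from_truth",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study design.

    Defaults mirror a six-cell-type design with 26 biological replicates and
    five planted modules of 50 genes at a within-module Pearson correlation
    of 0.81; each module is active (latent mean ``activity_high``) in one
    cell type and silent elsewhere.
    """

    seed: int
    n_genes: int = 6000
    n_cell_types: int = 6
    replicates_per_type: Sequence[int] = (5, 5, 4, 4, 4, 4)
    module_sizes: Sequence[int] = (50, 50, 50, 50, 50)
    within_module_cor: float = 0.81
    loading_spread: float = 0.1
    activity_profiles: Optional[np.ndarray] = None  # modules x cell types latent means
    activity_high: float = 6.0
    noise_sd: float = 1.0
    background_sd: float = 0.5
    background_profile_sd: float = 0.6  # median per-gene cell-type spread for background
    background_profile_log_sd: float = 0.8  # lognormal spread of per-gene amplitudes
    de_fraction: float = 0.05
    de_log2fc: float = 2.0
    de_cell_types: Optional[tuple[str, str]] = None  # defaults to first two types
    n_tissue_specific: int = 25
    tissue_boost: float = 2.0
    sequencing_depth: float = 1.0e6
    gene_length_range: tuple[int, int] = (500, 5000)
    nb_dispersion: Optional[float] = None  # None = Poisson counts

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory")
        if not 0.0 < self.within_module_cor < 1.0:
            raise ValidationError("within_module_cor must lie in (0, 1)")
        if len(self.replicates_per_type) != self.n_cell_types:
            raise ValidationError("replicates_per_type must have n_cell_types entries")
        if any(r < 2 for r in self.replicates_per_type):
            raise ValidationError("each cell type needs >= 2 biological replicates")
        if sum(self.module_sizes) > self.n_genes:
            raise ValidationError("module sizes exceed the number of genes")
        if self.n_cell_types * self.n_tissue_specific > self.n_genes - sum(self.module_sizes):
            raise ValidationError("not enough background genes for tissue-specific labels")

    @property
    def cell_type_names(self) -> list[str]:
        return [f"ct{i + 1}" for i in range(self.n_cell_types)]

    @property
    def n_samples(self) -> int:
        return int(sum(self.replicates_per_type))


@dataclass
class SyntheticTruth:
    """Planted ground truth consistent with the emitted matrices."""

    module_labels: pd.Series  # gene -> module id (0 = background)
    activity_profiles: pd.DataFrame  # module x cell type latent means
    module_activity: pd.DataFrame  # module x sample realized latent activity
    de_genes: dict[str, float]  # gene -> signed planted log2 fold-change
    de_contrast: tuple[str, str]
    tissue_specific: dict[str, frozenset[str]]  # tissue -> genes
    bottlenecks: frozenset[str] = field(default_factory=frozenset)
    ppi_communities: tuple[frozenset[str], ...] = ()
    latent: Optional[pd.DataFrame] = None  # genes x samples latent signals (not serialized)

    def module_genes(self, module: int) -> list[str]:
        return sorted(self.module_labels.index[self.module_labels == module])

    def to_json(self, path) -> None:
        payload = {
            "module_labels": {g: int(m) for g, m in self.module_labels.items()},
            "activity_profiles": self.activity_profiles.to_dict(),
            "module_activity": self.module_activity.to_dict(),
            "de_genes": self.de_genes,
            "de_contrast": list(self.de_contrast),
            "tissue_specific": {t: sorted(s) for t, s in self.tissue_specific.items()},
            "bottlenecks": sorted(self.bottlenecks),
            "ppi_communities": [sorted(c) for c in self.ppi_communities],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def simulate_expression(config: SimulationConfig) -> tuple[
    ExpressionMatrix, GeneAnnotation, TraitDesign, SyntheticTruth
]:
    """Draw a count matrix, annotation, trait design and truth from the config.

    Member genes of module m load on a shared latent activity
    ``e[m, s] = profile[m, celltype(s)] + N(0, 1)`` with loading
    ``a = sqrt(within_module_cor)``, so at ``noise_sd = 1`` the expected
    pairwise Pearson correlation of member latent signals equals the target.
    Counts are Poisson around ``depth * length_kb * softplus(latent)``
    renormalized per sample, so TPM recovers ``softplus(latent)`` in
    expectation.
    """
    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_genes))
    genes = [f"g{i + 1:0{width}d}" for i in range(config.n_genes)]
    cell_types = config.cell_type_names
    sample_types: list[str] = []
    for ct, reps in zip(cell_types, config.replicates_per_type):
        sample_types.extend([ct] * reps)
    samples = [f"s{i + 1:02d}_{ct}" for i, ct in enumerate(sample_types)]
    n_samples = len(samples)

    indicator = pd.DataFrame(0, index=samples, columns=cell_types, dtype=np.int64)
    for s, ct in zip(samples, sample_types):
        indicator.loc[s, ct] = 1
    traits = TraitDesign(indicator)

    n_modules = len(config.module_sizes)
    labels = np.zeros(config.n_genes, dtype=np.int64)
    pos = 0
    for m, size in enumerate(config.module_sizes, start=1):
        labels[pos:pos + size] = m
        pos += size
    module_labels = pd.Series(labels, index=genes, name="module")

    if config.activity_profiles is not None:
        profiles = np.asarray(config.activity_profiles, dtype=float)
        if profiles.shape != (n_modules, config.n_cell_types):
            raise ValidationError("activity_profiles must be modules x cell types")
    else:
        profiles = np.zeros((n_modules, config.n_cell_types))
        for m in range(n_modules):
            profiles[m, m % config.n_cell_types] = config.activity_high
    profile_df = pd.DataFrame(profiles, index=range(1, n_modules + 1), columns=cell_types)

    type_idx = np.array([cell_types.index(ct) for ct in sample_types])
    # latent module activity per sample
    activity = profiles[:, type_idx] + rng.normal(0.0, 1.0, size=(n_modules, n_samples))
    activity_df = pd.DataFrame(activity, index=range(1, n_modules + 1), columns=samples)

    # member loadings: symmetric spread around sqrt(cor) keeps the expected
    # pairwise correlation E[a_g a_h] at the target while giving the module a
    # realistic continuum of membership strengths
    center = np.sqrt(config.within_module_cor)
    delta = min(config.loading_spread, 1.0 - center, center)
    loadings = rng.uniform(center - delta, center + delta, size=config.n_genes)
    latent = np.empty((config.n_genes, n_samples))
    noise = rng.normal(0.0, 1.0, size=(config.n_genes, n_samples))
    # every gene gets its own mild cell-type baseline (real compendia have no
    # perfectly flat genes); module membership adds the shared activity on top
    bg_amplitude = config.background_profile_sd * rng.lognormal(
        0.0, config.background_profile_log_sd, size=config.n_genes)
    bg_profiles = bg_amplitude[:, None] * rng.normal(
        0.0, 1.0, size=(config.n_genes, config.n_cell_types))
    for g in range(config.n_genes):
        m = labels[g]
        if m == 0:
            latent[g] = bg_profiles[g, type_idx] + config.background_sd * noise[g]
        else:
            a = loadings[g]
            latent[g] = a * activity[m - 1] + np.sqrt(1.0 - a * a) * config.noise_sd * noise[g]

    # tissue-specific marker genes, drawn from the background pool
    background = [g for g in range(config.n_genes) if labels[g] == 0]
    tissue_specific: dict[str, frozenset[str]] = {}
    spec_category = {}
    spec_tissues: dict[str, frozenset[str]] = {g: frozenset() for g in genes}
    cursor = 0
    bg_perm = rng.permutation(background)
    for t, ct in enumerate(cell_types):
        chosen = bg_perm[cursor:cursor + config.n_tissue_specific]
        cursor += config.n_tissue_specific
        tissue_specific[ct] = frozenset(genes[g] for g in chosen)
        for g in chosen:
            latent[g, type_idx == t] += config.tissue_boost
            spec_category[genes[g]] = "tissue_enriched"
            spec_tissues[genes[g]] = frozenset({ct})

    # expression on the count scale
    expression = _softplus(latent)

    # planted DE genes between the designated cell-type pair
    ct_a, ct_b = config.de_cell_types or (cell_types[0], cell_types[1])
    for ct in (ct_a, ct_b):
        if ct not in cell_types:
            raise ValidationError(f"unknown DE cell type {ct!r}")
    n_de = int(round(config.de_fraction * config.n_genes))
    # DE genes come from the background pool not already used as tissue
    # markers, keeping each planted feature's ground truth unambiguous
    free_bg = bg_perm[cursor:]
    pool = free_bg if len(free_bg) >= n_de else np.arange(config.n_genes)
    de_candidates = pool[rng.permutation(len(pool))[:n_de]]
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    de_genes: dict[str, float] = {}
    a_mask = np.array([ct == ct_a for ct in sample_types])
    for g, sign in zip(de_candidates, signs):
        lfc = sign * config.de_log2fc
        expression[g, a_mask] *= 2.0 ** lfc
        de_genes[genes[g]] = float(lfc)

    lengths = rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1,
                           size=config.n_genes)
    length_kb = lengths / 1000.0

    mean_frac = (length_kb[:, None] * expression)
    mean_frac = mean_frac / mean_frac.sum(axis=0, keepdims=True)
    rates = config.sequencing_depth * mean_frac
    if config.nb_dispersion is not None:
        shape = 1.0 / config.nb_dispersion
        rates = rng.gamma(shape, rates / shape)
    counts = rng.poisson(rates)

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=samples, dtype=np.int64), "raw_counts"
    )
    ann = GeneAnnotation(pd.DataFrame({
        "length_bp": lengths,
        "specificity_category": [spec_category.get(g, "none") for g in genes],
        "specific_tissues": [spec_tissues[g] for g in genes],
    }, index=pd.Index(genes, name="gene_id")))
    truth = SyntheticTruth(
        module_labels=module_labels,
        activity_profiles=profile_df,
        module_activity=activity_df,
        de_genes=de_genes,
        de_contrast=(ct_a, ct_b),
        tissue_specific=tissue_specific,
        latent=pd.DataFrame(latent, index=genes, columns=samples),
    )
    return matrix, ann, traits, truth


def simulate_ppi(truth: SyntheticTruth, *, p_in: float = 0.9,
                 community_size: Optional[int] = None, bridge_links: int = 3,
                 n_decoys: int = 20, seed: int = 0) -> tuple[PPIEdgeList, SyntheticTruth]:
    """Two dense module-derived communities joined by one bridge gene.

    Communities are Erdos-Renyi graphs (edge probability ``p_in``, scores
    uniform in [0.7, 1]) over the genes of the first two planted modules; a
    designated background gene bridges them with ``bridge_links`` edges into
    each community, and is recorded as the true maximum-betweenness
    bottleneck.  Cross-community decoy edges carry scores below the 0.7
    confidence threshold, so they vanish after thresholding.
    """
    modules = sorted(set(truth.module_labels) - {0})
    if len(modules) < 2:
        raise ValidationError("simulate_ppi needs at least two planted modules")
    rng = np.random.default_rng(seed)
    communities = []
    for m in modules[:2]:
        members = truth.module_genes(m)
        if community_size is not None:
            members = members[:community_size]
        if len(members) < 3:
            raise ValidationError("PPI community sizes must be >= 3")
        communities.append(members)

    background = sorted(truth.module_labels.index[truth.module_labels == 0])
    if not background:
        raise ValidationError("no background gene available for the bridge")
    bridge = background[0]

    rows: list[tuple[str, str, float]] = []
    for members in communities:
        k = len(members)
        for i in range(k):
            for j in range(i + 1, k):
                if rng.random() < p_in:
                    rows.append((members[i], members[j], float(rng.uniform(0.7, 1.0))))
    for members in communities:
        targets = list(rng.choice(len(members), size=min(bridge_links, len(members)),
                                  replace=False))
        for t in targets:
            rows.append((bridge, members[t], float(rng.uniform(0.8, 1.0))))
    # sub-threshold decoys between the communities
    for _ in range(n_decoys):
        u = communities[0][int(rng.integers(len(communities[0])))]
        v = communities[1][int(rng.integers(len(communities[1])))]
        rows.append((u, v, float(rng.uniform(0.2, 0.7 - 1e-9))))

    df = pd.DataFrame(rows, columns=["protein_a", "protein_b", "score"])
    edges = PPIEdgeList(_canonical_edges(df))
    truth.bottlenecks = frozenset({bridge})
    truth.ppi_communities = tuple(frozenset(c) for c in communities)
    return edges, truth


def de_table_from_truth(truth: SyntheticTruth, *, null_p: float = 1.0,
                        de_p: float = 1.0e-6) -> DEResultTable:
    """Differential-expression table carrying the planted effects.

    Stands in for an external negative-binomial DE fit: planted genes get
    their true signed log2 fold-change and a small adjusted p; all other
    genes get zero fold-change and p = 1.
    """
    genes = list(truth.module_labels.index)
    lfc = [truth.de_genes.get(g, 0.0) for g in genes]
    p = [de_p if g in truth.de_genes else null_p for g in genes]
    table = pd.DataFrame({
        "log2_fold_change": lfc,
        "p_value": p,
        "p_adjusted": p,
    }, index=pd.Index(genes, name="gene_id"))
    return DEResultTable(table)


def gene_sets_from_truth(truth: SyntheticTruth, *, n_random_sets: int = 10,
                         random_set_size: int = 40, seed: int = 0) -> GeneSetCollection:
    """Gene-set collection over all simulated genes: planted tissue marker
    sets plus size-matched random decoy sets."""
    rng = np.random.default_rng(seed)
    universe = frozenset(truth.module_labels.index)
    genes = sorted(universe)
    sets: dict[str, frozenset[str]] = {
        f"tissue_{t}": s for t, s in truth.tissue_specific.items()
    }
    for i in range(n_random_sets):
        members = rng.choice(len(genes), size=random_set_size, replace=False)
        sets[f"random_{i + 1:02d}"] = frozenset(genes[j] for j in members)
    return GeneSetCollection(universe, sets)
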