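"""Hypergeometric enrichment, DE filters, randomization null and BH-FDR.

The central statistic is the hypergeometric upper tail P(X >= k) for drawing
k annotated genes in n draws from a universe of N genes containing K
annotated ones, evaluated in log space so extreme tails keep full relative
precision.  On top of it sit the tissue-specificity scan, gene-set
enrichment with the FDR <= 0.05 / fold >= 1.5 / >= 5 genes filter, the
fold-change >= 2 & adjusted-p <= 0.01 up-regulation filter, and a
size-matched randomization test with a strictly-greater counting rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .io import DEResultTable, GeneAnnotation, GeneSetCollection, ValidationError


@dataclass
class EnrichmentResult:
    """One gene set's hypergeometric enrichment against a universe."""

    set_name: str
    population: int  # N
    successes: int  # K
    draws: int  # n
    observed: int  # k
    p_value: float
    fold_enrichment: float  # (k/n) / (K/N)
    fdr: float = float("nan")
    passes_filter: bool = False


@dataclass
class RandomizationResult:
    """Size-matched random-module null for an observed overlap count."""

    module_name: str
    observed: int
    n_random: int
    null_mean: float
    null_sd: float
    null_max: int
    p_value: float
    seed: int
    comparison: str = "greater"

    def formatted_p(self) -> str:
        return f"< {1.0 / self.n_random:g}" if self.p_value == 0.0 else f"{self.p_value:g}"


def _log_hyper_pmf(N: int, K: int, n: int, k: np.ndarray) -> np.ndarray:
    return (
        gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
        + gammaln(N - K + 1) - gammaln(n - k + 1) - gammaln(N - K - n + k + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), summed in log space."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"inconsistent counts N={N}, K={K}, n={n}")
    if not 0 <= k <= min(K, n):
        raise ValidationError(f"observed k={k} outside [0, min(K, n)={min(K, n)}]")
    if k == 0:
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    lo = max(0, n - (N - K))
    support = support[support >= lo]
    if len(support) == 0:
        return 0.0
    return float(min(1.0, np.exp(logsumexp(_log_hyper_pmf(N, K, n, support)))))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def tissue_specificity_scan(top_genes: Iterable[str], annotation: GeneAnnotation,
                            universe: Optional[Iterable[str]] = None) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each tissue's specific genes.

    For every tissue appearing in the annotation, K counts genes whose
    specific tissues include it (any of the tissue-enriched / group-enriched
    / tissue-enhanced categories), n is the query size and k the overlap.
    The universe defaults to all annotated genes; results are sorted by
    p-value with BH-FDR attached.
    """
    universe_set = set(universe) if universe is not None else set(annotation.gene_ids)
    if not universe_set:
        raise ValidationError("empty universe")
    query = set(top_genes) & universe_set
    N, n = len(universe_set), len(query)
    results = []
    for tissue in annotation.tissues():
        tissue_genes = annotation.tissue_gene_set(tissue) & universe_set
        K = len(tissue_genes)
        k = len(query & tissue_genes)
        p = hypergeom_upper_tail(N, K, n, k)
        fold = (k / n) / (K / N) if n > 0 and K > 0 else 0.0
        results.append(EnrichmentResult(tissue, N, K, n, k, p, fold))
    results.sort(key=lambda r: (r.p_value, r.set_name))
    fdr = bh_fdr([r.p_value for r in results])
    for r, q in zip(results, fdr):
        r.fdr = float(q)
        r.passes_filter = bool(q <= 0.05)
    return results


def upregulated_sets(de: DEResultTable, fc_threshold: float = 2.0,
                     padj_threshold: float = 0.01) -> tuple[frozenset[str], frozenset[str]]:
    """Split a DE table into up-in-A and up-in-B gene sets.

    A gene counts as up-regulated when |fold-change| >= ``fc_threshold``
    (i.e. |log2FC| >= log2(threshold)) and adjusted p <= ``padj_threshold``;
    both comparisons are inclusive.  The two sets are disjoint.
    """
    lfc_cut = float(np.log2(fc_threshold))
    t = de.table
    sig = t["p_adjusted"] <= padj_threshold
    up_a = frozenset(t.index[sig & (t["log2_fold_change"] >= lfc_cut)])
    up_b = frozenset(t.index[sig & (t["log2_fold_change"] <= -lfc_cut)])
    return up_a, up_b


def randomization_module_test(module_genes: Iterable[str], target_set: Iterable[str],
                              universe: Iterable[str], n_random: int = 10000,
                              seed: int = 0, comparison: str = "greater",
                              module_name: str = "module") -> RandomizationResult:
    """Size-matched random-module overlap null.

    Draws ``n_random`` uniform gene sets of the module's size from the
    universe (without replacement within each draw) and counts how many
    overlap the target set more than the module does.  With the default
    strictly-greater rule the p-value has resolution 1/n_random and a
    reported 0 means p < 1/n_random; ``comparison='greater_equal'`` gives
    the standard conservative convention.
    """
    universe_list = sorted(set(universe))
    module = set(module_genes)
    target = set(target_set)
    if not module <= set(universe_list):
        raise ValidationError("module is not a subset of the universe")
    if not target <= set(universe_list):
        raise ValidationError("target set is not a subset of the universe")
    m, N = len(module), len(universe_list)
    if m > N:
        raise ValidationError("module larger than universe")
    if comparison not in ("greater", "greater_equal"):
        raise ValidationError(f"unknown comparison {comparison!r}")
    observed = len(module & target)
    target_mask = np.array([g in target for g in universe_list])
    rng = np.random.default_rng(seed)
    null = np.empty(n_random, dtype=np.int64)
    chunk = max(1, min(n_random, int(2e7) // max(N, 1)))
    done = 0
    while done < n_random:
        size = min(chunk, n_random - done)
        keys = rng.random((size, N))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        null[done:done + size] = target_mask[idx].sum(axis=1)
        done += size
    exceed = int((null > observed).sum() if comparison == "greater"
                 else (null >= observed).sum())
    return RandomizationResult(
        module_name=module_name, observed=observed, n_random=n_random,
        null_mean=float(null.mean()), null_sd=float(null.std(ddof=1)),
        null_max=int(null.max()), p_value=exceed / n_random, seed=seed,
        comparison=comparison,
    )


def gene_set_enrichment(query_genes: Iterable[str], collection: GeneSetCollection,
                        min_genes: int = 5, fdr_max: float = 0.05,
                        fold_min: float = 1.5) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of a query against every set in a collection.

    Sets pass the filter when FDR <= ``fdr_max``, fold enrichment
    (k/n)/(K/N) >= ``fold_min`` and at least ``min_genes`` query genes hit
    the set.  Results are sorted by p-value.
    """
    if not len(collection):
        raise ValidationError("empty gene-set collection")
    query = set(query_genes)
    extra = query - collection.universe
    if extra:
        raise ValidationError(
            f"query genes outside the collection universe: {sorted(extra)[:10]}")
    N = len(collection.universe)
    n = len(query)
    results = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        K = len(members)
        k = len(query & members)
        p = hypergeom_upper_tail(N, K, n, k)
        fold = (k / n) / (K / N) if n > 0 and K > 0 else 0.0
        results.append(EnrichmentResult(name, N, K, n, k, p, fold))
    results.sort(key=lambda r: (r.p_value, r.set_name))
    fdr = bh_fdr([r.p_value for r in results])
    for r, q in zip(results, fdr):
        r.fdr = float(q)
        r.passes_filter = bool(q <= fdr_max and r.fold_enrichment >= fold_min
                               and r.observed >= min_genes)
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view of enrichment results (one row per set)."""
    return pd.DataFrame([{
        "set_name": r.set_name, "population": r.population, "successes": r.successes,
        "draws": r.draws, "observed": r.observed, "p_value": r.p_value,
        "fold_enrichment": r.fold_enrichment, "fdr": r.fdr,
        "passes_filter": r.passes_filter,
    } for r in results])
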