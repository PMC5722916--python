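"""TPM normalization, log transform, gene selection and sample PCA.

TPM divides each count first by gene length (per kilobase) and then by the
per-sample total of length-normalized rates, scaled to 1e6 — so every
normalized column sums to one million by construction.  Selection rules
reduce the matrix to the genes the network and PCA stages consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneAnnotation, TraitDesign, ValidationError


@dataclass
class SelectionResult:
    """An ordered gene selection with the rule and parameters that produced it."""

    selected_gene_ids: tuple[str, ...]
    criterion: str  # tpm_gt1 | top_quartile_variance | top_n_expressed
    parameters: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.selected_gene_ids)


def compute_tpm(counts: ExpressionMatrix, annotation: GeneAnnotation) -> ExpressionMatrix:
    """Transcripts-per-million: count / length_kb, column-normalized to 1e6."""
    if counts.unit != "raw_counts":
        raise ValidationError(f"compute_tpm expects raw counts, got {counts.unit!r}")
    lengths = annotation.lengths(counts.gene_ids).to_numpy(dtype=float)
    arr = counts.values.to_numpy(dtype=float)
    colsums = arr.sum(axis=0)
    if (colsums == 0).any():
        bad = [s for s, c in zip(counts.sample_ids, colsums) if c == 0]
        raise ValidationError(f"all-zero sample(s): {bad}")
    rate = arr / (lengths[:, None] / 1000.0)
    tpm = rate / rate.sum(axis=0, keepdims=True) * 1.0e6
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=counts.values.index, columns=counts.values.columns), "tpm"
    )


def log_transform(tpm: ExpressionMatrix) -> ExpressionMatrix:
    """value -> log2(value + 1); monotone and zero-preserving."""
    if tpm.unit != "tpm":
        raise ValidationError(f"log_transform expects TPM, got {tpm.unit!r}")
    arr = tpm.values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValidationError("negative TPM values")
    return ExpressionMatrix(
        pd.DataFrame(np.log2(arr + 1.0), index=tpm.values.index, columns=tpm.values.columns),
        "log2_tpm_plus1",
    )


def filter_expressed(tpm: ExpressionMatrix, threshold: float = 1.0,
                     mode: str = "mean") -> SelectionResult:
    """Keep genes expressed above ``threshold`` TPM (strict inequality).

    ``mode='mean'`` (default) tests the gene's mean TPM across all samples;
    ``'any'`` keeps genes exceeding the threshold in at least one sample;
    ``'all'`` requires every sample to exceed it.
    """
    if tpm.unit != "tpm":
        raise ValidationError(f"filter_expressed expects TPM, got {tpm.unit!r}")
    arr = tpm.values.to_numpy(dtype=float)
    if mode == "mean":
        keep = arr.mean(axis=1) > threshold
    elif mode == "any":
        keep = (arr > threshold).any(axis=1)
    elif mode == "all":
        keep = (arr > threshold).all(axis=1)
    else:
        raise ValidationError(f"unknown filter mode {mode!r}")
    selected = tuple(g for g, k in zip(tpm.gene_ids, keep) if k)
    return SelectionResult(selected, "tpm_gt1",
                           {"threshold": threshold, "mode": mode})


def select_top_quartile_variance(logtpm: ExpressionMatrix,
                                 genes: Optional[Sequence[str]] = None) -> SelectionResult:
    """The floor(n/4) genes of highest log-scale sample variance.

    Variance is the unbiased (n-1 denominator) sample variance of
    log2(TPM+1) across all samples; ties at the cut are broken by
    lexicographic gene id, so the selection is deterministic.
    """
    values = logtpm.values if genes is None else logtpm.values.loc[list(genes)]
    n = len(values)
    if n < 4:
        raise ValidationError("top-quartile selection needs at least 4 genes")
    var = values.var(axis=1, ddof=1)
    k = n // 4
    order = sorted(var.index, key=lambda g: (-var[g], g))
    return SelectionResult(tuple(order[:k]), "top_quartile_variance",
                           {"n_input": n, "n_selected": k})


def select_top_expressed(logtpm: ExpressionMatrix, traits: TraitDesign,
                         cell_type: str, n: int = 1000) -> SelectionResult:
    """Top ``n`` genes by mean log2(TPM+1) over one cell type's replicates."""
    samples = traits.samples_of(cell_type)
    missing = [s for s in samples if s not in logtpm.values.columns]
    if missing:
        raise ValidationError(f"samples absent from expression matrix: {missing}")
    if n > logtpm.n_genes:
        raise ValidationError("n exceeds the number of genes")
    means = logtpm.values[samples].mean(axis=1)
    order = sorted(means.index, key=lambda g: (-means[g], g))
    return SelectionResult(tuple(order[:n]), "top_n_expressed",
                           {"cell_type": cell_type, "n": n})


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    variance_fraction: np.ndarray  # non-increasing, sums to 1
    loadings: pd.DataFrame  # genes x components

    def cumulative_variance(self, k: int) -> float:
        return float(self.variance_fraction[:k].sum())


def pca_samples(logtpm: ExpressionMatrix,
                selection: Optional[SelectionResult] = None) -> PCAResult:
    """Principal components of samples over (optionally selected) genes.

    Genes are centered across samples; components come from the SVD of the
    samples x genes matrix.  Each component's sign is fixed by making its
    largest-magnitude gene loading positive.
    """
    values = logtpm.values
    if selection is not None:
        values = values.loc[list(selection.selected_gene_ids)]
    if values.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    X = values.to_numpy(dtype=float).T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    total = float((S ** 2).sum())
    if total == 0.0:
        raise ValidationError("all samples identical; PCA undefined")
    frac = S ** 2 / total
    # deterministic sign: largest-magnitude loading positive
    for c in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, j] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    scores = U * S
    comp_names = [f"PC{i + 1}" for i in range(len(S))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=values.columns, columns=comp_names),
        variance_fraction=frac,
        loadings=pd.DataFrame(Vt.T, index=values.index, columns=comp_names),
    )
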