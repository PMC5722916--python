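"""Readers, writers and validated in-memory containers for pipeline artifacts.

Every external file the pipeline touches — count matrices, gene annotation,
sample-by-cell-type trait designs, GMT gene-set collections, STRING-style
protein-interaction edge lists and differential-expression tables — comes
through this module, so validation happens exactly once, at the boundary.
All tabular formats are plain TSV; readers accept explicit ``delimiter`` and
``comment`` options.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EXPRESSION_UNITS = ("raw_counts", "tpm", "log2_tpm_plus1")
SPECIFICITY_CATEGORIES = ("tissue_enriched", "group_enriched", "tissue_enhanced", "none")


class ValidationError(ValueError):
    """An input violates a structural invariant (duplicate ids, bad range...)."""


class ParseError(ValueError):
    """A file could not be parsed; the message carries row/column coordinates."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Dense genes x samples expression grid with a declared unit.

    ``values`` is a DataFrame indexed by gene id with sample-id columns.
    ``unit`` is one of ``raw_counts`` (non-negative integers), ``tpm``
    (non-negative, each column sums to 1e6) or ``log2_tpm_plus1``.
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in EXPRESSION_UNITS:
            raise ValidationError(f"unknown expression unit {self.unit!r}")
        dup_genes = self.values.index[self.values.index.duplicated()].unique()
        if len(dup_genes):
            raise ValidationError(f"duplicate gene ids: {sorted(map(str, dup_genes))}")
        dup_samples = self.values.columns[self.values.columns.duplicated()].unique()
        if len(dup_samples):
            raise ValidationError(f"duplicate sample ids: {sorted(map(str, dup_samples))}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if np.isnan(arr).any():
            raise ValidationError("missing expression values are not supported")
        if self.unit == "raw_counts":
            if (arr < 0).any():
                raise ValidationError("raw counts must be non-negative")
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("raw counts must be integers")
            self.values = self.values.astype(np.int64)
        elif self.unit == "tpm" and (arr < 0).any():
            raise ValidationError("TPM values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def read_expression_matrix(path, unit: str, *, delimiter: str = "\t",
                           comment: str = "#") -> ExpressionMatrix:
    """Read a TSV count/TPM matrix: header row of sample ids, first column gene ids."""
    df = pd.read_csv(path, sep=delimiter, comment=comment, index_col=0, dtype_backend="numpy_nullable")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {df[col].iloc[i]!r} at row {i + 2}, column {j + 2} "
                f"(gene {df.index[i]!r}, sample {col!r})"
            )
        if coerced.isna().any():
            i = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise ParseError(f"missing value at row {i + 2}, column {j + 2}")
        df[col] = coerced.astype(float)
    return ExpressionMatrix(df.astype(float), unit)


def write_expression_matrix(matrix: ExpressionMatrix, path, *, delimiter: str = "\t") -> None:
    matrix.values.to_csv(path, sep=delimiter, index_label="gene_id")


def combine_technical_replicates(matrix: ExpressionMatrix,
                                 grouping: Mapping[str, str]) -> ExpressionMatrix:
    """Sum raw read counts of technical replicates into one column per group.

    ``grouping`` maps each sample id to its replicate-group name; samples not
    mentioned stay as singleton groups under their own id.  Output column
    order follows the first occurrence of each group in the input.  Total
    read count is conserved.
    """
    if matrix.unit != "raw_counts":
        raise ValidationError(
            "technical replicates are combined on raw counts; "
            f"got unit {matrix.unit!r} (summing normalized values is undefined)"
        )
    unknown = set(grouping) - set(matrix.sample_ids)
    if unknown:
        raise ValidationError(f"grouping mentions unknown samples: {sorted(unknown)}")
    order: list[str] = []
    members: dict[str, list[str]] = {}
    for sample in matrix.sample_ids:
        group = grouping.get(sample, sample)
        if group not in members:
            members[group] = []
            order.append(group)
        members[group].append(sample)
    combined = pd.DataFrame(
        {g: matrix.values[members[g]].sum(axis=1) for g in order},
        index=matrix.values.index,
    )
    return ExpressionMatrix(combined, "raw_counts")


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """Per-gene annotation: effective length (bp) and optional tissue specificity.

    ``table`` is indexed by gene id with columns ``length_bp`` (int, >= 1),
    ``specificity_category`` (one of the protein-atlas style categories
    ``tissue_enriched`` / ``group_enriched`` / ``tissue_enhanced`` or
    ``none``) and ``specific_tissues`` (frozenset of tissue names, nonempty
    exactly when the category is not ``none``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        dup = self.table.index[self.table.index.duplicated()].unique()
        if len(dup):
            raise ValidationError(f"duplicate annotation for genes: {sorted(map(str, dup))}")
        if "length_bp" not in self.table.columns:
            raise ValidationError("annotation requires a length_bp column")
        lengths = self.table["length_bp"]
        if (lengths < 1).any():
            bad = list(self.table.index[lengths < 1])
            raise ValidationError(f"gene lengths must be >= 1 bp: {bad}")
        if "specificity_category" not in self.table.columns:
            self.table = self.table.assign(specificity_category="none")
        if "specific_tissues" not in self.table.columns:
            self.table = self.table.assign(specific_tissues=[frozenset()] * len(self.table))
        for gene, row in self.table.iterrows():
            cat = row["specificity_category"]
            if cat not in SPECIFICITY_CATEGORIES:
                raise ValidationError(f"gene {gene!r}: unknown specificity category {cat!r}")
            tissues = row["specific_tissues"]
            if (cat == "none") != (len(tissues) == 0):
                raise ValidationError(
                    f"gene {gene!r}: specific_tissues must be nonempty iff category != none"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def lengths(self, genes: Optional[Sequence[str]] = None) -> pd.Series:
        if genes is None:
            return self.table["length_bp"]
        missing = [g for g in genes if g not in self.table.index]
        if missing:
            raise ValidationError(f"genes missing length annotation: {missing[:20]}")
        return self.table.loc[list(genes), "length_bp"]

    def tissues(self) -> list[str]:
        out: set[str] = set()
        for t in self.table["specific_tissues"]:
            out |= set(t)
        return sorted(out)

    def tissue_gene_set(self, tissue: str) -> frozenset[str]:
        mask = self.table["specific_tissues"].map(lambda s: tissue in s)
        return frozenset(self.table.index[mask])


def read_gene_annotation(path, *, delimiter: str = "\t", comment: str = "#") -> GeneAnnotation:
    df = pd.read_csv(path, sep=delimiter, comment=comment, index_col=0)
    df.index = df.index.astype(str)
    if "specificity_category" in df.columns:
        df["specificity_category"] = df["specificity_category"].fillna("none")
    if "specific_tissues" in df.columns:
        df["specific_tissues"] = df["specific_tissues"].map(
            lambda v: frozenset() if pd.isna(v) or v == "" else frozenset(str(v).split(","))
        )
    return GeneAnnotation(df)


def write_gene_annotation(annotation: GeneAnnotation, path, *, delimiter: str = "\t") -> None:
    df = annotation.table.copy()
    df["specific_tissues"] = df["specific_tissues"].map(lambda s: ",".join(sorted(s)))
    df.to_csv(path, sep=delimiter, index_label="gene_id")


# ---------------------------------------------------------------------------
# Trait design
# ---------------------------------------------------------------------------

@dataclass
class TraitDesign:
    """Binary samples x cell-types indicator; each sample belongs to one type."""

    indicator: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.indicator.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError("trait indicator must be binary")
        rowsum = arr.sum(axis=1)
        if (rowsum != 1).any():
            bad = list(self.indicator.index[rowsum != 1])
            raise ValidationError(f"each sample must map to exactly one cell type; bad: {bad}")
        self.indicator = self.indicator.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.indicator.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.indicator.columns)

    def cell_type_of(self, sample: str) -> str:
        row = self.indicator.loc[sample]
        return str(row.index[row.to_numpy().argmax()])

    def samples_of(self, cell_type: str) -> list[str]:
        if cell_type not in self.indicator.columns:
            raise ValidationError(f"unknown cell type {cell_type!r}")
        col = self.indicator[cell_type]
        return list(self.indicator.index[col == 1])


def read_traits(path, *, delimiter: str = "\t", comment: str = "#") -> TraitDesign:
    df = pd.read_csv(path, sep=delimiter, comment=comment, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return TraitDesign(df)


def write_traits(traits: TraitDesign, path, *, delimiter: str = "\t") -> None:
    traits.indicator.to_csv(path, sep=delimiter, index_label="sample_id")


# ---------------------------------------------------------------------------
# Gene set collections (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets over a declared universe; every set is a subset of it."""

    universe: frozenset[str]
    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}
        for name, members in self.sets.items():
            extra = members - self.universe
            if extra:
                raise ValidationError(
                    f"gene set {name!r} is not a subset of the universe: {sorted(extra)[:10]}"
                )

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path, *, universe: Optional[Iterable[str]] = None) -> GeneSetCollection:
    """Read a GMT file (set name, description, then member genes, tab-separated).

    When no universe is supplied, the union of all member genes is used.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"GMT line {lineno}: expected name, description and members")
            name = parts[0]
            if name in sets:
                raise ValidationError(f"duplicate gene set name {name!r} (line {lineno})")
            sets[name] = frozenset(g for g in parts[2:] if g)
    if universe is None:
        universe = frozenset().union(*sets.values()) if sets else frozenset()
    return GeneSetCollection(frozenset(universe), sets)


def write_gmt(collection: GeneSetCollection, path, *, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


# ---------------------------------------------------------------------------
# PPI edge lists
# ---------------------------------------------------------------------------

@dataclass
class PPIEdgeList:
    """Undirected protein-interaction edges with combined confidence in [0, 1].

    At most one edge per unordered pair (duplicates keep the maximum score);
    self-edges are dropped at load time.
    """

    edges: pd.DataFrame  # columns protein_a, protein_b, score

    def __post_init__(self) -> None:
        required = ["protein_a", "protein_b", "score"]
        if list(self.edges.columns[:3]) != required:
            self.edges = self.edges.rename(
                columns=dict(zip(self.edges.columns[:3], required))
            )
        scores = self.edges["score"].to_numpy(dtype=float)
        if ((scores < 0) | (scores > 1)).any():
            raise ValidationError("PPI scores must lie in [0, 1]")
        if (self.edges["protein_a"] == self.edges["protein_b"]).any():
            raise ValidationError("self-edges must be removed before constructing PPIEdgeList")

    def __len__(self) -> int:
        return len(self.edges)


def _canonical_edges(df: pd.DataFrame) -> pd.DataFrame:
    a = df["protein_a"].astype(str)
    b = df["protein_b"].astype(str)
    lo = a.where(a <= b, b)
    hi = b.where(a <= b, a)
    out = pd.DataFrame({"protein_a": lo, "protein_b": hi, "score": df["score"].astype(float)})
    out = (
        out.groupby(["protein_a", "protein_b"], as_index=False)["score"].max()
        .sort_values(["protein_a", "protein_b"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def read_ppi_edges(path, score_scale: str = "string", *, delimiter: Optional[str] = None,
                   comment: str = "#") -> PPIEdgeList:
    """Read a 3-column STRING-style edge list: protein_a protein_b combined_score.

    ``score_scale='string'`` expects 0-1000 integer combined scores (divided
    by 1000); ``'unit'`` expects pre-normalized [0, 1] scores.  Duplicate
    edges keep the maximum score; self-edges are dropped with a logged count.
    """
    if score_scale not in ("string", "unit"):
        raise ValidationError(f"unknown score scale {score_scale!r}")
    df = pd.read_csv(path, sep=delimiter or r"\s+", comment=comment, header=None,
                     names=["protein_a", "protein_b", "score"], engine="python")
    scores = pd.to_numeric(df["score"], errors="coerce")
    if scores.isna().any():
        i = int(np.flatnonzero(scores.isna().to_numpy())[0])
        raise ParseError(f"non-numeric score {df['score'].iloc[i]!r} at line {i + 1}")
    hi = 1000.0 if score_scale == "string" else 1.0
    if ((scores < 0) | (scores > hi)).any():
        raise ValidationError(f"score outside declared {score_scale!r} scale [0, {hi:g}]")
    df["score"] = scores / hi
    self_mask = df["protein_a"].astype(str) == df["protein_b"].astype(str)
    if self_mask.any():
        logger.info("dropped %d self-edge(s)", int(self_mask.sum()))
        df = df[~self_mask]
    return PPIEdgeList(_canonical_edges(df))


def write_ppi_edges(edges: PPIEdgeList, path, *, delimiter: str = "\t") -> None:
    edges.edges.to_csv(path, sep=delimiter, header=False, index=False)


# ---------------------------------------------------------------------------
# Differential expression tables
# ---------------------------------------------------------------------------

@dataclass
class DEResultTable:
    """One row per gene: log2 fold-change, p-value and adjusted p-value."""

    table: pd.DataFrame  # indexed by gene id; columns log2_fold_change, p_value, p_adjusted

    def __post_init__(self) -> None:
        dup = self.table.index[self.table.index.duplicated()].unique()
        if len(dup):
            raise ValidationError(f"duplicate DE records for genes: {sorted(map(str, dup))}")
        for col in ("p_value", "p_adjusted"):
            vals = self.table[col].to_numpy(dtype=float)
            if ((vals < 0) | (vals > 1)).any():
                raise ValidationError(f"{col} must lie in [0, 1]")


def read_de_table(path, *, delimiter: str = "\t", comment: str = "#") -> DEResultTable:
    df = pd.read_csv(path, sep=delimiter, comment=comment, index_col=0)
    df.index = df.index.astype(str)
    return DEResultTable(df)


def write_de_table(de: DEResultTable, path, *, delimiter: str = "\t") -> None:
    de.table.to_csv(path, sep=delimiter, index_label="gene_id")
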