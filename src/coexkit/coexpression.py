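"""Signed-hybrid weighted gene co-expression network analysis.

The model follows the classical weighted-network recipe: Pearson
correlations between gene expression profiles are soft-thresholded
(``cor^beta`` for positive correlations, 0 otherwise — the signed-hybrid
convention), the power beta is chosen as the smallest candidate whose
connectivity distribution fits a scale-free law at R^2 >= 0.9, genes are
clustered by average linkage on 1 - TOM (topological overlap), the
dendrogram is cut, undersized clusters are left unassigned, closely related
modules (eigengene correlation > 0.75) are merged, and each module is
summarized by its eigengene — the first principal component of its
standardized member expression.  Module membership (K_ME) is the correlation
of a gene with a module eigengene, and module-trait association is the
Pearson correlation of eigengenes with binary cell-type indicators, with
p-values from the exact Student-t transform.

Use the :class:`CoexpressionNetwork` model and its :meth:`fit` for the whole
stack, or call the stage functions directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as student_t

from .io import ExpressionMatrix, TraitDesign, ValidationError

DEFAULT_CANDIDATE_POWERS = tuple(range(1, 11)) + tuple(range(12, 31, 2))


@dataclass
class NetworkConfig:
    """Parameters of network construction and module detection."""

    power: Optional[int] = None  # None = pick by scale-free fit
    candidate_powers: Sequence[int] = DEFAULT_CANDIDATE_POWERS
    target_scale_free_r2: float = 0.9
    min_module_size: int = 30
    merge_cor_threshold: float = 0.75
    kme_threshold: float = 0.75
    n_degree_bins: int = 10
    cut_height_quantile: Optional[float] = None  # None = adaptive height

    def __post_init__(self) -> None:
        names = ["target_scale_free_r2", "merge_cor_threshold", "kme_threshold"]
        if self.cut_height_quantile is not None:
            names.append("cut_height_quantile")
        for name in names:
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must lie in (0, 1); got {v}")
        if self.power is not None and self.power < 1:
            raise ValidationError("power must be >= 1")
        if list(self.candidate_powers) != sorted(self.candidate_powers):
            raise ValidationError("candidate_powers must be ascending")


# ---------------------------------------------------------------------------
# Stage functions
# ---------------------------------------------------------------------------

def _expr_frame(expr) -> pd.DataFrame:
    if isinstance(expr, ExpressionMatrix):
        return expr.values
    return expr


def _check_variance(values: pd.DataFrame) -> None:
    sd = values.to_numpy(dtype=float).std(axis=1)
    if (sd == 0).any():
        bad = list(values.index[sd == 0])
        raise ValidationError(f"zero-variance gene(s): {bad[:20]}")


def signed_hybrid_adjacency(expr, beta: int) -> pd.DataFrame:
    """a_ij = cor(x_i, x_j)^beta for positive correlations, else 0; zero diagonal."""
    values = _expr_frame(expr)
    if values.shape[1] < 3:
        raise ValidationError("adjacency needs at least 3 samples")
    _check_variance(values)
    corr = np.corrcoef(values.to_numpy(dtype=float))
    adj = np.where(corr > 0.0, np.clip(corr, 0.0, 1.0) ** beta, 0.0)
    np.fill_diagonal(adj, 0.0)
    return pd.DataFrame(adj, index=values.index, columns=values.index)


def scale_free_fit(adjacency: pd.DataFrame, n_degree_bins: int = 10) -> tuple[float, float]:
    """Goodness of the power-law fit to the connectivity distribution.

    Connectivities k_i = sum_j a_ij are binned into equal-width bins; the
    regression of log10 frequency on log10 within-bin mean connectivity over
    nonempty bins yields (r2, slope).  A scale-free network gives a high r2
    with negative slope.
    """
    A = adjacency.to_numpy(dtype=float)
    k = A.sum(axis=1)
    if len(k) < n_degree_bins:
        raise ValidationError("need at least n_degree_bins genes")
    if np.allclose(k, k[0]):
        raise ValidationError("all connectivities equal; scale-free fit undefined")
    edges = np.linspace(k.min(), k.max(), n_degree_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    sums, _ = np.histogram(k, bins=edges, weights=k)
    nonempty = counts > 0
    mean_k = sums[nonempty] / counts[nonempty]
    freq = counts[nonempty] / counts.sum()
    usable = mean_k > 0
    mean_k, freq = mean_k[usable], freq[usable]
    if len(mean_k) < 2:
        raise ValidationError("fewer than two usable degree bins; fit undefined")
    x = np.log10(mean_k)
    y = np.log10(freq)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return 1.0, float(slope)
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot
    return float(r2), float(slope)


@dataclass
class SoftThresholdResult:
    power: int
    table: pd.DataFrame  # columns power, r2, slope, mean_k
    reached_target: bool


def pick_soft_threshold(expr, candidate_powers: Sequence[int] = DEFAULT_CANDIDATE_POWERS,
                        target_r2: float = 0.9,
                        n_degree_bins: int = 10) -> SoftThresholdResult:
    """Smallest candidate power whose scale-free fit reaches ``target_r2``.

    If no candidate reaches the target the best-fitting power is returned
    with ``reached_target=False``.  The full (power, r2, slope, mean k)
    table is kept for reporting.
    """
    if not len(candidate_powers):
        raise ValidationError("candidate_powers must be nonempty")
    if list(candidate_powers) != sorted(candidate_powers):
        raise ValidationError("candidate_powers must be ascending")
    values = _expr_frame(expr)
    _check_variance(values)
    corr = np.corrcoef(values.to_numpy(dtype=float))
    pos = np.clip(np.where(corr > 0.0, corr, 0.0), 0.0, 1.0)
    rows = []
    for beta in candidate_powers:
        adj = pos ** beta
        np.fill_diagonal(adj, 0.0)
        k = adj.sum(axis=1)
        try:
            r2, slope = scale_free_fit(
                pd.DataFrame(adj, index=values.index, columns=values.index), n_degree_bins
            )
        except ValidationError:
            r2, slope = float("nan"), float("nan")
        rows.append({"power": beta, "r2": r2, "slope": slope, "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    # a scale-free fit must decay: only negative-slope fits qualify
    ok = table[(table["r2"] >= target_r2) & (table["slope"] < 0)]
    if len(ok):
        power = int(ok.iloc[0]["power"])
        reached = True
    else:
        signed = table["r2"].where(table["slope"] < 0, -np.inf)
        power = int(table.loc[signed.idxmax(), "power"])
        reached = False
        warnings.warn(
            f"no candidate power reached scale-free R^2 >= {target_r2}; "
            f"using best power {power}", stacklevel=2,
        )
    return SoftThresholdResult(power, table, reached)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), unit diagonal.

    l_ij sums shared-neighbor strength a_iu * a_uj; entries lie in [0, 1]
    when the adjacency does.
    """
    A = adjacency.to_numpy(dtype=float)
    k = A.sum(axis=1)
    L = A @ A  # zero diagonal of A makes u = i, j terms vanish
    min_k = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + A) / (min_k + 1.0 - A)
    tom = np.clip(np.nan_to_num(tom, nan=0.0), 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    tom = (tom + tom.T) / 2.0
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def cluster_genes(tom: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Average-linkage hierarchical clustering on dissimilarity 1 - TOM.

    Genes are sorted lexicographically before clustering so tie handling is
    reproducible.  Returns the scipy linkage matrix and the leaf gene order.
    """
    order = sorted(map(str, tom.index))
    d = 1.0 - tom.loc[order, order].to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    Z = linkage(squareform(d, checks=False), method="average")
    return Z, order


def cut_tree(dendrogram: np.ndarray, gene_ids: Sequence[str],
             min_module_size: int = 30,
             height_quantile: Optional[float] = None,
             max_candidate_heights: int = 256) -> pd.Series:
    """Adaptive-height cut of the dendrogram into modules.

    By default the cut height is chosen from the merge heights as the one
    that maximizes the number of clusters reaching ``min_module_size`` (ties
    broken toward the highest such cut, i.e. the coarsest partition), which
    adapts to however many well-separated blocks the tree contains.  Passing
    ``height_quantile`` instead cuts at that fixed quantile of merge
    heights.  Clusters below ``min_module_size`` become label 0
    (unassigned); the rest are renumbered 1..M by decreasing size (ties by
    smallest member id).
    """
    heights = dendrogram[:, 2]
    if height_quantile is not None:
        h_star = float(np.quantile(heights, height_quantile))
        raw = fcluster(dendrogram, t=h_star, criterion="distance")
    else:
        candidates = np.unique(heights)
        if len(candidates) > max_candidate_heights:
            qs = np.linspace(0.0, 1.0, max_candidate_heights)
            candidates = np.unique(np.quantile(candidates, qs))
        # cutting just below each merge height splits that merge
        eps = 1e-12
        best = None
        for h in candidates:
            cand = fcluster(dendrogram, t=max(h - eps, 0.0), criterion="distance")
            sizes = np.bincount(cand)
            n_big = int((sizes >= min_module_size).sum())
            key = (n_big, h)
            if best is None or key >= best[0]:
                best = (key, cand)
        raw = best[1]
    labels = pd.Series(raw, index=list(gene_ids))
    sizes = labels.value_counts()
    kept = [c for c in sizes.index if sizes[c] >= min_module_size]
    kept.sort(key=lambda c: (-sizes[c], min(labels.index[labels == c])))
    remap = {c: i + 1 for i, c in enumerate(kept)}
    return labels.map(lambda c: remap.get(c, 0)).astype(np.int64)


def _standardize_rows(values: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    ok = sd[:, 0] > 0
    dropped = list(values.index[~ok])
    if dropped:
        warnings.warn(f"excluding zero-variance member gene(s): {dropped[:10]}", stacklevel=3)
    arr = (arr[ok] - mean[ok]) / sd[ok]
    return arr, list(values.index[ok])


def module_eigengene(expr, member_genes: Sequence[str]) -> pd.Series:
    """Unit-norm first principal component of the standardized member rows.

    The sign is oriented so the eigengene correlates positively with the
    mean standardized member profile.
    """
    values = _expr_frame(expr)
    members = [g for g in member_genes if g in values.index]
    if not members:
        raise ValidationError("module has no member genes in the expression matrix")
    if values.shape[1] < 2:
        raise ValidationError("eigengene needs at least 2 samples")
    X, kept = _standardize_rows(values.loc[members])
    if X.shape[0] == 0:
        raise ValidationError("all member genes have zero variance")
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    eig = Vt[0]
    mean_profile = X.mean(axis=0)
    if float(eig @ mean_profile) < 0:
        eig = -eig
    eig = eig / np.linalg.norm(eig)
    return pd.Series(eig, index=values.columns)


def compute_eigengenes(expr, labels: pd.Series) -> pd.DataFrame:
    """Eigengene per labeled module (module x sample grid)."""
    values = _expr_frame(expr)
    modules = sorted(set(labels) - {0})
    rows = {}
    for m in modules:
        genes = list(labels.index[labels == m])
        rows[m] = module_eigengene(values, genes)
    return pd.DataFrame(rows).T if rows else pd.DataFrame(columns=values.columns)


def merge_modules(expr, labels: pd.Series, threshold: float = 0.75) -> pd.Series:
    """Merge module pairs whose eigengene correlation exceeds ``threshold``.

    Iteratively merges the most-correlated pair first and recomputes
    eigengenes, until no pair exceeds the threshold; final ids are
    renumbered by decreasing size.  Terminates because the module count
    strictly decreases on every merge.
    """
    labels = labels.copy()
    while True:
        modules = sorted(set(labels) - {0})
        if len(modules) < 2:
            break
        eig = compute_eigengenes(expr, labels)
        E = eig.loc[modules].to_numpy(dtype=float)
        corr = np.corrcoef(E)
        np.fill_diagonal(corr, -np.inf)
        best = float(corr.max())
        if best <= threshold:
            break
        i, j = np.unravel_index(int(corr.argmax()), corr.shape)
        a, b = sorted((modules[i], modules[j]))
        labels[labels == b] = a
    modules = sorted(set(labels) - {0})
    sizes = labels.value_counts()
    modules.sort(key=lambda m: (-sizes[m], min(labels.index[labels == m])))
    remap = {m: i + 1 for i, m in enumerate(modules)}
    return labels.map(lambda m: remap.get(m, 0)).astype(np.int64)


def module_membership(expr, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """K_ME grid: Pearson correlation of every gene with every module eigengene."""
    values = _expr_frame(expr)
    X = values.to_numpy(dtype=float)
    E = eigengenes.to_numpy(dtype=float)
    n = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    Ec = E - E.mean(axis=1, keepdims=True)
    x_sd = Xc.std(axis=1)
    e_sd = Ec.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        kme = (Xc @ Ec.T) / n / np.outer(x_sd, e_sd)
    kme = np.clip(np.nan_to_num(kme, nan=0.0), -1.0, 1.0)
    return pd.DataFrame(kme, index=values.index, columns=eigengenes.index)


def assign_by_kme(kme: pd.DataFrame, threshold: float = 0.75) -> dict[int, frozenset[str]]:
    """Module -> genes with K_ME above the threshold; sets may overlap."""
    return {
        m: frozenset(kme.index[kme[m] > threshold]) for m in kme.columns
    }


def module_trait_correlation(eigengenes: pd.DataFrame,
                             traits: TraitDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of eigengenes with binary cell-type indicators.

    p-values come from the two-sided Student test
    t = r sqrt(n-2) / sqrt(1-r^2) on n-2 degrees of freedom.
    """
    samples = list(eigengenes.columns)
    missing = [s for s in samples if s not in traits.indicator.index]
    if missing:
        raise ValidationError(f"samples missing from traits: {missing}")
    n = len(samples)
    if n < 3:
        raise ValidationError("module-trait correlation needs at least 3 samples")
    T = traits.indicator.loc[samples].to_numpy(dtype=float)
    E = eigengenes.to_numpy(dtype=float)
    Ec = E - E.mean(axis=1, keepdims=True)
    Tc = T - T.mean(axis=0, keepdims=True)
    e_sd = Ec.std(axis=1)
    t_sd = Tc.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Ec @ Tc) / n / np.outer(e_sd, t_sd)
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt(n - 2) / np.sqrt(1.0 - r ** 2)
    p = 2.0 * student_t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    r_df = pd.DataFrame(r, index=eigengenes.index, columns=traits.cell_types)
    p_df = pd.DataFrame(p, index=eigengenes.index, columns=traits.cell_types)
    return r_df, p_df


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class CoexpressionNetwork:
    """Weighted co-expression network model over a log-expression matrix.

    Parameters
    ----------
    expr : ExpressionMatrix or DataFrame
        Genes x samples log2(TPM+1) expression (already filtered/selected).
    traits : TraitDesign, optional
        Binary sample-by-cell-type design for module-trait statistics.
    config : NetworkConfig
        Power selection, cut and merge parameters.
    """

    def __init__(self, expr, traits: Optional[TraitDesign] = None,
                 config: Optional[NetworkConfig] = None) -> None:
        self.values = _expr_frame(expr).astype(float)
        self.traits = traits
        self.config = config or NetworkConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, traits: Optional[TraitDesign] = None,
                       **config_kwargs) -> "CoexpressionNetwork":
        return cls(df, traits, NetworkConfig(**config_kwargs))

    def fit(self) -> "CoexpressionResults":
        cfg = self.config
        if cfg.power is None:
            st = pick_soft_threshold(self.values, cfg.candidate_powers,
                                     cfg.target_scale_free_r2, cfg.n_degree_bins)
            power, fit_table, reached = st.power, st.table, st.reached_target
        else:
            power, reached = int(cfg.power), True
            try:
                r2, slope = scale_free_fit(
                    signed_hybrid_adjacency(self.values, power), cfg.n_degree_bins)
            except ValidationError:
                r2, slope = float("nan"), float("nan")
            fit_table = pd.DataFrame([{"power": power, "r2": r2, "slope": slope,
                                       "mean_k": float("nan")}])
        adjacency = signed_hybrid_adjacency(self.values, power)
        tom = topological_overlap(adjacency)
        Z, leaf_order = cluster_genes(tom)
        labels = cut_tree(Z, leaf_order, cfg.min_module_size, cfg.cut_height_quantile)
        labels = merge_modules(self.values.loc[leaf_order], labels,
                               cfg.merge_cor_threshold)
        labels = labels.reindex(self.values.index).astype(np.int64)
        eigengenes = compute_eigengenes(self.values, labels)
        if len(eigengenes):
            kme = module_membership(self.values, eigengenes)
            membership = assign_by_kme(kme, cfg.kme_threshold)
        else:
            kme = pd.DataFrame(index=self.values.index)
            membership = {}
        if self.traits is not None and len(eigengenes):
            trait_r, trait_p = module_trait_correlation(eigengenes, self.traits)
        else:
            trait_r = trait_p = None
        return CoexpressionResults(
            model=self, power=power, reached_target=reached, fit_table=fit_table,
            dendrogram=Z, leaf_order=leaf_order, labels=labels,
            eigengenes=eigengenes, kme=kme, membership_sets=membership,
            trait_correlation=trait_r, trait_p=trait_p,
        )


@dataclass
class CoexpressionResults:
    """Fitted module decomposition with eigengenes and association statistics."""

    model: CoexpressionNetwork
    power: int
    reached_target: bool
    fit_table: pd.DataFrame
    dendrogram: np.ndarray
    leaf_order: list[str]
    labels: pd.Series  # gene -> module id, 0 = unassigned
    eigengenes: pd.DataFrame  # module x sample
    kme: pd.DataFrame  # gene x module
    membership_sets: Mapping[int, frozenset[str]]
    trait_correlation: Optional[pd.DataFrame]
    trait_p: Optional[pd.DataFrame]

    @property
    def modules(self) -> list[int]:
        return sorted(set(self.labels) - {0})

    def module_genes(self, module: int) -> list[str]:
        return sorted(self.labels.index[self.labels == module])

    def summary(self) -> str:
        lines = [
            "Weighted co-expression network",
            f"  genes: {len(self.labels)}   samples: {self.model.values.shape[1]}",
            f"  soft-threshold power: {self.power}"
            + ("" if self.reached_target else "  (scale-free target not reached)"),
            f"  modules: {len(self.modules)}   unassigned genes: {int((self.labels == 0).sum())}",
            "",
        ]
        rows = []
        for m in self.modules:
            row = {"module": m, "size": int((self.labels == m).sum()),
                   "kme_members": len(self.membership_sets.get(m, frozenset()))}
            if self.trait_correlation is not None:
                best = self.trait_correlation.loc[m].idxmax()
                row["top_trait"] = best
                row["r"] = round(float(self.trait_correlation.loc[m, best]), 3)
                row["p"] = float(f"{self.trait_p.loc[m, best]:.3g}")
            rows.append(row)
        if rows:
            lines.append(pd.DataFrame(rows).to_string(index=False))
        return "\n".join(lines)
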