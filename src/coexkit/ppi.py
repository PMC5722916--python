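"""Protein-interaction networks: thresholded graph, betweenness, bottlenecks.

Edges with combined confidence >= 0.7 among a supplied gene set form a
simple unweighted graph; the largest connected component is extracted, each
node's unnormalized shortest-path betweenness is computed (fractional path
counting, each unordered pair counted once), and genes at or above the 95th
percentile of betweenness are flagged as bottlenecks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .io import PPIEdgeList, ValidationError


@dataclass
class PPIGraph:
    """Thresholded interaction graph with betweenness scores and bottleneck calls."""

    graph: nx.Graph
    betweenness: dict[str, float] = field(default_factory=dict)
    bottlenecks: frozenset[str] = field(default_factory=frozenset)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)


def build_graph(edges: PPIEdgeList, genes: Iterable[str],
                weight_min: float = 0.7) -> nx.Graph:
    """Simple unweighted graph of confident interactions within a gene set.

    Keeps edges with score >= ``weight_min`` (inclusive) whose both
    endpoints belong to ``genes``; every supplied gene becomes a node, so
    interaction-free genes appear as isolates.
    """
    gene_set = set(map(str, genes))
    if not gene_set:
        raise ValidationError("empty gene set")
    G = nx.Graph()
    G.add_nodes_from(sorted(gene_set))
    df = edges.edges
    keep = (df["score"] >= weight_min) & df["protein_a"].isin(gene_set) \
        & df["protein_b"].isin(gene_set)
    G.add_edges_from(df.loc[keep, ["protein_a", "protein_b"]].itertuples(index=False))
    return G


def largest_connected_component(graph: nx.Graph) -> nx.Graph:
    """Node-induced subgraph on the largest component.

    Ties go to the component containing the lexicographically smallest node;
    an edgeless graph yields a single-node graph (smallest id) with a
    warning.
    """
    if graph.number_of_nodes() == 0:
        raise ValidationError("empty graph")
    comps = sorted(nx.connected_components(graph),
                   key=lambda c: (-len(c), min(map(str, c))))
    best = comps[0]
    if len(best) == 1 and graph.number_of_nodes() > 1:
        warnings.warn("graph has no edges; returning a single-node component",
                      stacklevel=2)
    return graph.subgraph(best).copy()


def betweenness(graph: nx.Graph) -> dict[str, float]:
    """Unnormalized shortest-path betweenness with fractional path counting.

    Node v accrues sigma_st(v)/sigma_st for every unordered pair {s, t} not
    containing v, where sigma_st counts shortest s-t paths (Brandes
    accumulation).
    """
    return {str(v): float(b) for v, b in
            nx.betweenness_centrality(graph, normalized=False).items()}


def call_bottlenecks(scores: Mapping[str, float], percentile: float = 95.0) -> frozenset[str]:
    """Genes whose betweenness reaches the top (100 - percentile)% of the network.

    The threshold is the k-th largest score with k = max(1,
    ceil(n * (100 - percentile) / 100)); the comparison is inclusive, so
    ties at the threshold are all called (the set may exceed the nominal
    fraction).  Invariant to node relabeling and to any monotone rescaling
    of the scores.
    """
    if not scores:
        raise ValidationError("no scores supplied")
    vals = sorted(scores.values(), reverse=True)
    n = len(vals)
    k = max(1, math.ceil(n * (100.0 - percentile) / 100.0))
    threshold = vals[k - 1]
    return frozenset(v for v, s in scores.items() if s >= threshold)


def bottleneck_analysis(edges: PPIEdgeList, genes: Iterable[str],
                        weight_min: float = 0.7,
                        percentile: float = 95.0) -> PPIGraph:
    """Full chain: threshold -> largest component -> betweenness -> bottlenecks."""
    G = build_graph(edges, genes, weight_min)
    lcc = largest_connected_component(G)
    scores = betweenness(lcc)
    return PPIGraph(lcc, scores, call_bottlenecks(scores, percentile))
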