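"""Protein-protein interaction subnetwork, edge enrichment, and hub genes.

Edges come from a STRING-dialect TSV (node1, node2, combined_score; scores
either on [0, 1] or STRING's integer 0-999 dialect, auto-detected).  The
candidate-gene subnetwork is the induced subgraph on the significant genes
with edges re-filtered at a higher confidence (default >= 0.9) and isolated
nodes removed.  Edge enrichment is tested against an explicit null of
uniformly drawn random gene sets of the same size from the graph background —
exhaustive enumeration replaces sampling when the subset count is small.
Hub genes are the top decile of nodes by degree.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class EnrichmentReport:
    observed_edges: int
    expected_edges: float
    p_enrich: float
    n_null_draws: int
    connected_node_count: int
    exact: bool = False


def load_edge_table(path, min_score: float = 0.7) -> nx.Graph:
    """Read a STRING-dialect edge TSV into an undirected simple graph.

    Any score > 1 switches the whole table to the integer dialect (divide by
    1000).  Edges below ``min_score`` after normalization are dropped;
    symmetric duplicates are merged keeping the maximum score; self-loops are
    discarded.  Malformed rows raise with their line number.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = ["node1", "node2", "combined_score"]
    if list(table.columns[:3]) != required:
        raise ValueError(f"expected columns {required}, got {list(table.columns)}")
    scores = pd.to_numeric(table["combined_score"], errors="coerce")
    bad = table.index[scores.isna() | table["node1"].isna() | table["node2"].isna()]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ValueError(f"malformed row at line {int(bad[0]) + 2} of {path}")
    scores = scores.to_numpy(dtype=float)
    if (scores > 1).any():
        scores = scores / 1000.0
    if (scores < 0).any() or (scores > 1).any():
        raise ValueError("combined_score outside both supported dialects")
    graph = nx.Graph()
    for n1, n2, s in zip(table["node1"], table["node2"], scores):
        if n1 == n2:
            continue
        if s < min_score:
            continue
        if graph.has_edge(n1, n2):
            graph[n1][n2]["combined_score"] = max(graph[n1][n2]["combined_score"], s)
        else:
            graph.add_edge(n1, n2, combined_score=s)
    return graph


def candidate_subnetwork(
    graph: nx.Graph, gene_set, min_score: float = 0.9
) -> nx.Graph:
    """Induced subgraph on the candidate genes at a higher score cutoff.

    Edges are re-filtered at ``min_score`` and isolated nodes removed; the
    retained node count is the number of candidate genes that form an
    interconnected network.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("gene set is empty")
    nodes = gene_set & set(graph.nodes)
    sub = nx.Graph()
    for n1, n2, data in graph.subgraph(nodes).edges(data=True):
        if data["combined_score"] >= min_score:
            sub.add_edge(n1, n2, **data)
    if sub.number_of_nodes() == 0:
        warnings.warn("candidate subnetwork is empty", stacklevel=2)
    return sub


def _induced_edge_count(adj: np.ndarray, idx: np.ndarray) -> int:
    return int(adj[np.ix_(idx, idx)].sum() // 2)


def edge_enrichment(
    graph: nx.Graph,
    gene_set,
    n_null: int = 10000,
    rng_seed: int = 0,
    exact: bool | None = None,
    max_exact: int = 100000,
) -> EnrichmentReport:
    """Edge-count enrichment of a gene set against random same-size node sets.

    The null draws ``n_null`` uniform random node sets of the same size from
    all graph nodes and counts their induced edges; ``expected_edges`` is the
    null mean and ``p_enrich = (#{null >= observed} + 1) / (n_null + 1)``.
    When the number of possible subsets is at most ``max_exact`` (or
    ``exact=True``), all subsets are enumerated instead of sampled, and the
    same add-one form is applied with n = number of subsets.
    """
    background = sorted(graph.nodes)
    members = sorted(set(gene_set) & set(background))
    if len(members) < 2:
        raise ValueError("need at least two candidate genes present in the graph")
    if len(set(gene_set)) > len(background):
        raise ValueError("gene set is larger than the graph background")
    order = {n: i for i, n in enumerate(background)}
    n_nodes = len(background)
    adj = np.zeros((n_nodes, n_nodes), dtype=np.uint8)
    for n1, n2 in graph.edges:
        adj[order[n1], order[n2]] = adj[order[n2], order[n1]] = 1
    member_idx = np.array([order[n] for n in members])
    observed = _induced_edge_count(adj, member_idx)

    k = len(members)
    n_subsets = math.comb(n_nodes, k)
    use_exact = exact if exact is not None else n_subsets <= max_exact
    if use_exact:
        counts = np.fromiter(
            (
                _induced_edge_count(adj, np.fromiter(c, dtype=int))
                for c in combinations(range(n_nodes), k)
            ),
            dtype=int,
            count=n_subsets,
        )
    else:
        rng = np.random.default_rng(rng_seed)
        counts = np.empty(n_null, dtype=int)
        for i in range(n_null):
            counts[i] = _induced_edge_count(adj, rng.choice(n_nodes, size=k, replace=False))
    exceed = int((counts >= observed).sum())
    return EnrichmentReport(
        observed_edges=observed,
        expected_edges=float(counts.mean()),
        p_enrich=(exceed + 1) / (len(counts) + 1),
        n_null_draws=len(counts),
        connected_node_count=sum(1 for n in members if graph.degree[n] > 0),
        exact=bool(use_exact),
    )


def hub_genes(graph: nx.Graph, fraction: float = 0.10) -> list[str]:
    """Top ``fraction`` of nodes by degree (ties broken lexicographically).

    Returns the first ``ceil(fraction * node count)`` nodes of the ranking.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    ranked = sorted(graph.nodes, key=lambda n: (-graph.degree[n], str(n)))
    n_hub = math.ceil(fraction * graph.number_of_nodes())
    return ranked[:n_hub]
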