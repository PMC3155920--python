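"""Protein-interaction network topology and centrality-diversity correlation.

Centrality is always computed on the full interaction graph (focal genes
plus all their first neighbors), since a protein's position in the whole
interactome, not in the focal-only subgraph, is what constrains it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class InteractionGraph:
    """Simple undirected interaction graph plus the focal study genes.

    Self-loops and duplicate edges are dropped on construction.
    """

    graph: nx.Graph
    focal: frozenset = frozenset()

    def __post_init__(self) -> None:
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        g.add_edges_from((u, v) for u, v in self.graph.edges if u != v)
        self.graph = g
        self.focal = frozenset(self.focal)
        missing = self.focal - set(g.nodes)
        if missing:
            raise ValueError(f"focal nodes absent from graph: {sorted(missing)[:5]}")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    tau: float
    p_value: float
    n_pairs: int


def degree_centrality(ig: InteractionGraph) -> dict:
    """Raw degree (incident edge count) per node."""
    return dict(ig.graph.degree())


def betweenness_centrality(ig: InteractionGraph) -> dict:
    """Normalized betweenness: the fraction of all shortest paths between
    unordered node pairs (endpoints excluded) passing through each node.

    Brandes accumulation with the (N-1)(N-2)/2 denominator; pairs in
    different components contribute no paths.
    """
    return nx.betweenness_centrality(ig.graph, normalized=True)


def centrality_table(ig: InteractionGraph) -> pd.DataFrame:
    deg = degree_centrality(ig)
    btw = betweenness_centrality(ig)
    return pd.DataFrame(
        {
            "node": list(deg),
            "degree": [deg[v] for v in deg],
            "betweenness": [btw[v] for v in deg],
            "focal": [v in ig.focal for v in deg],
        }
    ).set_index("node")


def kendall_tau(x, y, labels: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Kendall's tau-b with tie correction; two-sided p-value from the
    normal approximation with tie-adjusted variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(labels, math.nan, math.nan, int(x.size))
    res = sps.kendalltau(x, y, variant="b", method="asymptotic")
    return CorrelationResult(labels, float(res.statistic), float(res.pvalue), int(x.size))


def correlate_centrality(
    gene_table: pd.DataFrame,
    ig: InteractionGraph,
    variables: tuple[str, ...] = ("pi_whole", "pi_cds", "dnds"),
    centralities: tuple[str, ...] = ("degree", "betweenness"),
) -> pd.DataFrame:
    """Rank-correlate node centrality with per-gene diversity/divergence.

    ``gene_table`` needs columns ``gene``, ``population`` and the requested
    variables; genes without a focal node in the graph are dropped.  One
    row per (centrality, variable, population).
    """
    cent = centrality_table(ig)
    rows = []
    for pop, sub in gene_table.groupby("population", sort=True):
        sub = sub[sub["gene"].isin(ig.focal)]
        for var in variables:
            if var not in sub.columns:
                continue
            merged = sub[["gene", var]].dropna()
            merged = merged[merged["gene"].isin(cent.index)]
            if len(merged) < 3:
                raise ValueError(
                    f"fewer than 3 usable genes for {var} in population {pop}"
                )
            for c in centralities:
                cvals = cent.loc[merged["gene"], c].to_numpy(dtype=float)
                res = kendall_tau(cvals, merged[var].to_numpy(), labels=(c, var))
                rows.append(
                    {
                        "population": pop,
                        "centrality": c,
                        "variable": var,
                        "tau": res.tau,
                        "p_value": res.p_value,
                        "n_genes": res.n_pairs,
                    }
                )
    return pd.DataFrame(rows)


def generate_synthetic_network(
    n_focal: int,
    n_neighbors: int,
    diversity: np.ndarray,
    coupling: float = 0.2,
    attachment_exponent: float = 1.0,
    edges_per_node: int = 8,
    focal_names: list | None = None,
    seed: int | None = None,
) -> InteractionGraph:
    """Scale-free interaction graph whose focal-node degree is negatively
    coupled to per-gene diversity.

    The graph grows by preferential attachment (probability proportional to
    ``degree ** attachment_exponent``); the first ``n_focal`` nodes seeded
    into the graph become the focal study genes, which naturally makes them
    hub-like, mirroring a query-centred interactome snapshot.  ``coupling``
    in [0, 1] (sign ignored) sets the magnitude of the planted *negative*
    Kendall correlation between focal degree and diversity via
    Gaussian-copula rank matching: ``coupling = 1`` pairs the highest-degree
    node with the lowest-diversity gene exactly (tau = -1), ``coupling = 0``
    decouples them.
    """
    if n_focal < 1 or n_neighbors < 1:
        raise ValueError("sizes must be >= 1")
    if abs(coupling) > 1:
        raise ValueError("|coupling| must be <= 1")
    diversity = np.asarray(diversity, dtype=float)
    if diversity.size != n_focal:
        raise ValueError("diversity vector must have length n_focal")
    rng = np.random.default_rng(seed)

    total = n_focal + n_neighbors
    m = min(edges_per_node, n_focal)
    deg = np.zeros(total)
    edges: list[tuple[int, int]] = []
    # seed ring over the first m+1 nodes so every node has positive weight
    for i in range(m + 1):
        j = (i + 1) % (m + 1)
        edges.append((i, j))
        deg[i] += 1
        deg[j] += 1
    for v in range(m + 1, total):
        w = deg[:v] ** attachment_exponent
        targets: set[int] = set()
        while len(targets) < m:
            cw = np.cumsum(w)
            pick = int(np.searchsorted(cw, rng.uniform(0, cw[-1]), side="right"))
            if pick not in targets:
                targets.add(pick)
                w[pick] = 0.0
        for u in targets:
            edges.append((u, v))
            deg[u] += 1
            deg[v] += 1

    # couple focal degree ranks to (low) diversity via a Gaussian copula
    rho = math.sin(math.pi * abs(coupling) / 2.0)
    div_rank = sps.rankdata(diversity)
    z_div = sps.norm.ppf(div_rank / (n_focal + 1.0))
    score = -rho * z_div + math.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal(n_focal)
    # focal node with the k-th largest degree gets the gene with the k-th
    # largest score (i.e. lowest diversity when coupling is strong)
    if focal_names is None:
        focal_names = [f"g{i + 1:03d}" for i in range(n_focal)]
    gene_by_score = [focal_names[i] for i in np.argsort(-score, kind="stable")]
    name_of_node = {}
    rank_of_node = np.argsort(np.argsort(-deg[:n_focal], kind="stable"))
    for node in range(n_focal):
        name_of_node[node] = gene_by_score[rank_of_node[node]]
    mapping = {v: name_of_node.get(v, f"nbr{v - n_focal + 1:04d}") for v in range(total)}

    g = nx.Graph()
    g.add_nodes_from(mapping.values())
    g.add_edges_from((mapping[u], mapping[v]) for u, v in edges)
    return InteractionGraph(graph=g, focal=frozenset(focal_names))
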