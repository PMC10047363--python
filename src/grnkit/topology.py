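"""Hub identification, network comparison and over-representation tests.

Regulatory hubs are ranked by out-degree (regulatory influence), with
shortest-path betweenness on the unweighted directed graph as tiebreak
(endpoints excluded, unnormalized) and lexicographic node id as the final
tiebreak, making the ranking a total order.

Gene-set over-representation uses the upper-tail hypergeometric test with
Benjamini–Hochberg adjustment across the tested sets; gene sets are
arbitrary user-supplied collections (no ontology is bundled).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import Network
from .simulate import benjamini_hochberg

__all__ = [
    "NetworkComparison",
    "compute_hubs",
    "compare_networks",
    "hypergeom_enrichment",
]


def compute_hubs(
    network: Network, top_k: int = 10, allow_empty: bool = False
) -> pd.DataFrame:
    """Rank nodes by (out-degree desc, betweenness desc, id asc).

    Returns a DataFrame indexed by node with columns ``out_degree``,
    ``in_degree``, ``betweenness``, ``hub_rank`` (1..n) and ``is_hub``
    (rank ≤ top_k). An edgeless network is an error unless
    ``allow_empty``, in which case an all-zero table is returned.
    """
    nodes = sorted(network.node_set())
    if not nodes:
        raise ValueError("cannot rank hubs of an empty network")
    if network.n_edges == 0 and not allow_empty:
        raise ValueError(
            "network has no edges; pass allow_empty=True for an all-zero table"
        )
    g = network.to_networkx()
    betweenness = nx.betweenness_centrality(g, normalized=False)
    df = pd.DataFrame(
        {
            "out_degree": [g.out_degree(n) for n in nodes],
            "in_degree": [g.in_degree(n) for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    df = df.sort_values(
        by=["out_degree", "betweenness", "node"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    df["hub_rank"] = np.arange(1, len(df) + 1)
    df["is_hub"] = df["hub_rank"] <= top_k
    return df


@dataclass(frozen=True)
class NetworkComparison:
    """Shared / unique node and edge sets between two networks."""

    shared_nodes: frozenset
    unique_to_a: frozenset
    unique_to_b: frozenset
    shared_edges: frozenset
    edges_unique_to_a: frozenset
    edges_unique_to_b: frozenset

    @property
    def n_shared_nodes(self) -> int:
        return len(self.shared_nodes)

    @property
    def n_unique_to_a(self) -> int:
        return len(self.unique_to_a)

    @property
    def n_unique_to_b(self) -> int:
        return len(self.unique_to_b)

    @property
    def n_shared_edges(self) -> int:
        return len(self.shared_edges)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "count": [
                    self.n_shared_nodes,
                    self.n_unique_to_a,
                    self.n_unique_to_b,
                    self.n_shared_edges,
                    len(self.edges_unique_to_a),
                    len(self.edges_unique_to_b),
                ]
            },
            index=pd.Index(
                [
                    "shared_nodes",
                    "nodes_unique_to_a",
                    "nodes_unique_to_b",
                    "shared_edges",
                    "edges_unique_to_a",
                    "edges_unique_to_b",
                ],
                name="quantity",
            ),
        )


def compare_networks(net_a: Network, net_b: Network) -> NetworkComparison:
    """Exact set arithmetic on node ids and (regulator, target) pairs."""
    nodes_a, nodes_b = net_a.node_set(), net_b.node_set()
    edges_a, edges_b = net_a.edge_pairs(), net_b.edge_pairs()
    return NetworkComparison(
        shared_nodes=frozenset(nodes_a & nodes_b),
        unique_to_a=frozenset(nodes_a - nodes_b),
        unique_to_b=frozenset(nodes_b - nodes_a),
        shared_edges=frozenset(edges_a & edges_b),
        edges_unique_to_a=frozenset(edges_a - edges_b),
        edges_unique_to_b=frozenset(edges_b - edges_a),
    )


def hypergeom_enrichment(
    query: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    With universe size N, set size K (after intersecting the set with the
    universe), query size n and overlap k, p = P(X ≥ k) for
    X ~ Hypergeometric(N, K, n); P(X ≥ 0) = 1. Adjusted p-values are BH
    across the tested sets. Query genes outside the universe are a hard
    error (listing the offenders), as is an empty universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query)
    offenders = sorted(query - universe)
    if offenders:
        raise ValueError(f"query genes outside the universe: {offenders}")
    N, n = len(universe), len(query)
    rows = []
    for set_id in sorted(gene_sets):
        members = set(gene_sets[set_id]) & universe
        K = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_id": set_id, "k": k, "K": K, "n": n, "N": N, "p": p})
    df = pd.DataFrame(rows, columns=["set_id", "k", "K", "n", "N", "p"])
    if len(df):
        df["padj"] = benjamini_hochberg(df["p"].to_numpy())
    else:
        df["padj"] = pd.Series(dtype=float)
    return df.set_index("set_id")
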