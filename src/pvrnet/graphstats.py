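"""Sub-network induction, betweenness centrality, and communities.

The genes shared between a DE comparison and the p38 neighborhood
induce a sub-network of the interaction graph.  Node and edge
betweenness (unnormalized, undirected, each unordered source-target
pair counted once, unweighted shortest paths) determine node size and
edge thickness in the exported graph; communities found by greedy
modularity maximization determine color; the Venn region a gene came
from determines shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .core_io import GeneSet

__all__ = [
    "induce_subnetwork",
    "betweenness",
    "detect_communities",
    "export_styled_graph",
    "CommunityPartition",
]

log = logging.getLogger(__name__)


@dataclass
class CommunityPartition:
    community_of: dict[str, int]
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.community_of.values()))


def induce_subnetwork(
    net: nx.Graph,
    genes: GeneSet,
    keep_seed: str | None = None,
    largest_component_only: bool = False,
) -> nx.Graph:
    """Vertex-induced subgraph on ``genes`` (plus an optional seed gene).

    Isolated nodes are retained unless ``largest_component_only`` is
    set.  An empty intersection yields an empty graph with a warning.
    """
    if len(genes) == 0:
        raise ValueError("gene set is empty")
    keep = set(genes.genes)
    if keep_seed is not None:
        keep.add(keep_seed)
    present = keep & set(net.nodes)
    if not present:
        log.warning("gene set %r does not intersect the network", genes.name)
        return nx.Graph()
    sub = nx.Graph(net.subgraph(present))
    if largest_component_only and sub.number_of_nodes():
        biggest = max(nx.connected_components(sub), key=len)
        sub = nx.Graph(sub.subgraph(biggest))
    return sub


def betweenness(sub: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact node and edge betweenness, unnormalized pair-count convention.

    Shortest paths are unweighted; for an undirected graph each
    unordered pair contributes once, so a star center scores C(k, 2).
    Returns (node table, edge table).
    """
    nb = nx.betweenness_centrality(sub, normalized=False, weight=None)
    eb = nx.edge_betweenness_centrality(sub, normalized=False, weight=None)
    nodes = pd.DataFrame(
        {"gene": list(nb), "betweenness": [nb[v] for v in nb]}
    ).sort_values("betweenness", ascending=False, kind="stable", ignore_index=True)
    edges = pd.DataFrame(
        {
            "gene1": [a for a, _ in eb],
            "gene2": [b for _, b in eb],
            "betweenness": list(eb.values()),
        }
    ).sort_values("betweenness", ascending=False, kind="stable", ignore_index=True)
    return nodes, edges


def detect_communities(sub: nx.Graph, rng_seed: int = 0) -> CommunityPartition:
    """Greedy modularity (CNM) partition with its modularity Q.

    Deterministic for a given graph: ties inside the greedy merge are
    broken by the library's fixed ordering, so the seed only matters for
    potential future stochastic back-ends.
    """
    if sub.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if sub.number_of_edges() == 0:
        communities = [{v} for v in sub.nodes]
    else:
        communities = list(nx.community.greedy_modularity_communities(sub))
    q = nx.community.modularity(sub, communities) if sub.number_of_edges() else 0.0
    mapping = {v: i for i, comm in enumerate(communities) for v in comm}
    return CommunityPartition(mapping, q)


def export_styled_graph(
    sub: nx.Graph,
    node_betweenness: pd.DataFrame,
    edge_betweenness: pd.DataFrame,
    partition: CommunityPartition,
    path,
    venn_region: dict[str, str] | None = None,
) -> None:
    """Write GraphML with display attributes.

    Node attributes: betweenness (size), community (color key),
    venn_region (shape key).  Edge attribute: betweenness (thickness).
    Every node and edge must be covered by the tables.
    """
    styled = nx.Graph(sub)
    nb = dict(zip(node_betweenness["gene"], node_betweenness["betweenness"]))
    eb = {
        frozenset((a, b)): v
        for a, b, v in edge_betweenness[["gene1", "gene2", "betweenness"]].itertuples(
            index=False
        )
    }
    for v in styled.nodes:
        if v not in nb:
            raise ValueError(f"node {v!r} missing from centrality table")
        if v not in partition.community_of:
            raise ValueError(f"node {v!r} missing from community partition")
        styled.nodes[v]["betweenness"] = float(nb[v])
        styled.nodes[v]["community"] = int(partition.community_of[v])
        styled.nodes[v]["venn_region"] = (venn_region or {}).get(v, "")
    for a, b in styled.edges:
        key = frozenset((a, b))
        if key not in eb:
            raise ValueError(f"edge {a!r}-{b!r} missing from edge table")
        styled.edges[a, b]["betweenness"] = float(eb[key])
    nx.write_graphml(styled, str(path))
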