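"""Clustered Boolean implication networks (CBIN).

Genes connected by equivalence relations are grouped into clusters after
pruning weak equivalence edges by the Jaccard similarity of the two
endpoints' closed equivalence neighborhoods; connected components of the
pruned graph become cluster nodes.  Inter-cluster edges are typed by the
majority Boolean relation between each cluster's best-connected gene and a
small rank-based sample of the other cluster's genes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx

from .booleannet import ImplicationNetwork, Relation

__all__ = [
    "Cluster",
    "ClusteredNetwork",
    "ClusterEdge",
    "extract_clusters",
    "sample_representatives",
    "link_clusters",
    "cluster_size_distribution",
    "internal_inconsistencies",
]


@dataclass(frozen=True)
class Cluster:
    """A set of equivalent genes, ranked by within-cluster equivalence degree.

    ``members[0]`` (rank 1) is the gene with the most equivalence partners
    inside the cluster; ties break lexicographically by gene id.
    """

    cluster_id: int
    members: tuple

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ClusterEdge:
    cluster_a: int
    cluster_b: int
    relation: Relation
    support: float  # fraction of tested representative pairs agreeing


@dataclass
class ClusteredNetwork:
    clusters: list  # of Cluster
    edges: list  # of ClusterEdge, ordered pairs
    jaccard_cutoff: float = 0.5
    majority_threshold: float = 0.5

    def cluster_of(self, gene) -> int:
        for c in self.clusters:
            if gene in c.members:
                return c.cluster_id
        raise KeyError(f"gene {gene!r} not in any cluster")


def _jaccard_closed(graph: nx.Graph, a, b) -> float:
    na = set(graph[a]) | {a}
    nb = set(graph[b]) | {b}
    return len(na & nb) / len(na | nb)


def _rank_members(graph: nx.Graph, component) -> tuple:
    comp = set(component)
    degree = {g: sum(1 for nb in graph[g] if nb in comp) for g in comp}
    return tuple(sorted(comp, key=lambda g: (-degree[g], str(g))))


def extract_clusters(
    bin_net: ImplicationNetwork,
    jaccard_cutoff: float = 0.5,
    mode: str = "all-edges",
) -> list:
    """Cluster the network along equivalence edges with Jaccard pruning.

    ``mode="all-edges"`` computes, for every equivalence edge (A, B), the
    Jaccard coefficient of the closed equivalence neighborhoods
    ``J = |N[A] & N[B]| / |N[A] | N[B]|`` and removes edges with
    J < ``jaccard_cutoff``; clusters are the connected components of what
    remains.  ``mode="mst"`` instead builds a minimum spanning tree per
    component (edge weight 1 - J) and prunes only weak MST edges, keeping
    the components of the surviving forest.  Genes left without equivalence
    partners become size-1 clusters, so the clusters partition all network
    nodes.  Two genes with identical equivalence neighborhoods always have
    J = 1 and stay together.
    """
    eq = nx.Graph()
    eq.add_nodes_from(bin_net.nodes)
    eq.add_edges_from(bin_net.equivalence_pairs())

    kept = nx.Graph()
    kept.add_nodes_from(eq.nodes)
    if mode == "all-edges":
        for a, b in eq.edges:
            if _jaccard_closed(eq, a, b) >= jaccard_cutoff:
                kept.add_edge(a, b)
    elif mode == "mst":
        weighted = nx.Graph()
        weighted.add_nodes_from(eq.nodes)
        for a, b in eq.edges:
            weighted.add_edge(a, b, weight=1.0 - _jaccard_closed(eq, a, b))
        for a, b, data in nx.minimum_spanning_edges(weighted, data=True):
            if 1.0 - data["weight"] >= jaccard_cutoff:
                kept.add_edge(a, b)
    else:
        raise ValueError(f"unknown clustering mode {mode!r}")

    components = sorted(
        nx.connected_components(kept), key=lambda c: str(min(c, key=str))
    )
    return [
        Cluster(cluster_id=i, members=_rank_members(eq, comp))
        for i, comp in enumerate(components)
    ]


def sample_representatives(cluster: Cluster) -> list:
    """Rank-based representative genes used to type inter-cluster edges.

    Clusters larger than 10 contribute the genes at ranks 1, 2, n/2,
    n/2 - 1, n/4 and n/8 (floor division, duplicates removed); clusters of
    2-10 genes contribute ranks 1, 2 and n/2; a singleton contributes its
    only gene.
    """
    n = cluster.size
    if n == 0:
        raise ValueError("empty cluster")
    if n == 1:
        ranks = [1]
    elif n <= 10:
        ranks = [1, 2, n // 2]
    else:
        ranks = [1, 2, n // 2, n // 2 - 1, n // 4, n // 8]
    seen: list = []
    for r in ranks:
        if r >= 1 and r not in seen:
            seen.append(r)
    return [cluster.members[r - 1] for r in seen]


def link_clusters(
    bin_net: ImplicationNetwork,
    clusters: list,
    majority_threshold: float = 0.5,
) -> ClusteredNetwork:
    """Type the edge between every ordered cluster pair by majority vote.

    For clusters (A, B), the rank-1 gene of A is paired against B's
    representative sample; an edge of the modal non-NONE relation is
    emitted only when its share of all tested pairs (NONE included in the
    denominator) strictly exceeds ``majority_threshold``.  Ties for the
    modal relation yield no edge.
    """
    edges = []
    reps = {c.cluster_id: sample_representatives(c) for c in clusters}
    for ca in clusters:
        top = ca.members[0]
        for cb in clusters:
            if cb.cluster_id == ca.cluster_id:
                continue
            tally = Counter(bin_net.relation(top, g) for g in reps[cb.cluster_id])
            n_tested = sum(tally.values())
            tally.pop(Relation.NONE, None)
            if not tally:
                continue
            best_count = max(tally.values())
            modal = [r for r, c in tally.items() if c == best_count]
            if len(modal) != 1:
                continue
            support = best_count / n_tested
            if support > majority_threshold:
                edges.append(
                    ClusterEdge(ca.cluster_id, cb.cluster_id, modal[0], support)
                )
    return ClusteredNetwork(
        clusters=list(clusters),
        edges=edges,
        majority_threshold=majority_threshold,
    )


def cluster_size_distribution(clusters: list) -> dict:
    """Histogram {cluster size: count} for the scale-free diagnostic.

    Plotted on a log-log scale, an approximately straight line indicates
    scale-free cluster sizes; the Jaccard cutoff can be adjusted until the
    distribution straightens.
    """
    sizes = Counter(c.size for c in clusters)
    return dict(sorted(sizes.items()))


def internal_inconsistencies(bin_net: ImplicationNetwork, clusters: list) -> list:
    """Gene pairs inside one cluster whose network relation is OPPOSITE.

    Jaccard pruning exists to prevent these; on noisy data any remaining
    pairs are reported so they can be logged.
    """
    bad = []
    for c in clusters:
        members = list(c.members)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if bin_net.relation(a, b) is Relation.OPPOSITE:
                    bad.append((c.cluster_id, a, b))
    return bad
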