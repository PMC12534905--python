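"""Genome clustering on the ANI graph.

Single-linkage connected components are found by iterative depth-first
search; within each component all maximal cliques are enumerated with
Bron–Kerbosch (pivoting), so a bin may belong to several clusters. Nodes
left out of every clique — singleton components under exact enumeration,
possibly more under the greedy fallback for oversized components — are
attached to cliques containing one of their neighbors, or become singleton
clusters. Together this guarantees that every graph edge has both endpoints
co-occurring in at least one cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .ani_engine import AniGraph

logger = logging.getLogger(__name__)

DEFAULT_MAX_EXACT_COMPONENT = 5_000


@dataclass(frozen=True)
class BinCluster:
    """A maximal-clique-derived group of bins.

    ``attached_members`` are the members added by orphan assignment; the
    remaining (core) members are pairwise connected in the ANI graph.
    """

    cluster_id: str
    members: tuple[str, ...]
    component_id: str
    attached_members: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(sorted(self.members)))


def connected_components(graph: AniGraph) -> list[set[str]]:
    """Undirected components by iterative DFS.

    Isolated nodes form singleton components; components are ordered by
    their lexicographically smallest member.
    """
    adj = graph.adjacency()
    seen: set[str] = set()
    components: list[set[str]] = []
    for start in sorted(graph.nodes):
        if start in seen:
            continue
        component: set[str] = set()
        stack = [start]
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            component.add(node)
            # reverse-sorted push so neighbors are visited in lexicographic order
            stack.extend(sorted(adj[node], reverse=True))
        components.append(component)
    components.sort(key=lambda c: min(c))
    return components


def _bron_kerbosch_pivot(
    r: set[str],
    p: set[str],
    x: set[str],
    adj: dict[str, set[str]],
    out: list[frozenset[str]],
) -> None:
    if not p and not x:
        if len(r) >= 2:
            out.append(frozenset(r))
        return
    pivot = max(p | x, key=lambda u: (len(adj[u] & p), u))
    for v in sorted(p - adj[pivot]):
        _bron_kerbosch_pivot(r | {v}, p & adj[v], x & adj[v], adj, out)
        p = p - {v}
        x = x | {v}


def maximal_cliques(nodes: set[str], adj: dict[str, set[str]]) -> list[frozenset[str]]:
    """All maximal cliques of size >= 2, deterministically ordered.

    Singleton "cliques" are not emitted; isolated nodes are handled by
    orphan assignment.
    """
    out: list[frozenset[str]] = []
    _bron_kerbosch_pivot(set(), set(nodes), set(), adj, out)
    out.sort(key=lambda c: (-len(c), tuple(sorted(c))))
    return out


def greedy_cliques(nodes: set[str], adj: dict[str, set[str]]) -> list[frozenset[str]]:
    """Greedy clique cover used above the exact-enumeration safety bound.

    Each unassigned node (in lexicographic order) seeds a clique grown by
    scanning its neighbors in lexicographic order. Edges not covered by any
    grown clique are emitted as pair-cliques so the edge-coverage guarantee
    survives the heuristic. Cliques of size >= 2 are emitted; leftovers fall
    through to orphan assignment.
    """
    assigned: set[str] = set()
    out: list[frozenset[str]] = []
    for seed in sorted(nodes):
        if seed in assigned:
            continue
        clique = {seed}
        for v in sorted(adj[seed]):
            if v in assigned:
                continue
            if all(v in adj[u] for u in clique):
                clique.add(v)
        if len(clique) >= 2:
            assigned.update(clique)
            out.append(frozenset(clique))
    covered: set[tuple[str, str]] = set()
    for clique in out:
        members = sorted(clique)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                covered.add((a, b))
    for a in sorted(nodes):
        for b in sorted(adj[a]):
            if a < b and (a, b) not in covered:
                out.append(frozenset((a, b)))
    out.sort(key=lambda c: (-len(c), tuple(sorted(c))))
    return out


def assign_orphans(
    cliques: list[frozenset[str]],
    adj: dict[str, set[str]],
    nodes: set[str],
    component_id: str,
) -> list[BinCluster]:
    """Turn cliques into clusters and attach/seed the unclustered nodes.

    A node in no clique is attached to every clique containing one of its
    neighbors; a node with no neighbors becomes a singleton cluster.
    """
    in_clique: set[str] = set().union(*cliques) if cliques else set()
    attachments: list[set[str]] = [set() for _ in cliques]
    singletons: list[str] = []
    for node in sorted(nodes - in_clique):
        neighbor_cliques = [i for i, c in enumerate(cliques) if adj[node] & c]
        if neighbor_cliques:
            for i in neighbor_cliques:
                attachments[i].add(node)
        else:
            singletons.append(node)

    clusters: list[BinCluster] = []
    for i, clique in enumerate(cliques):
        clusters.append(
            BinCluster(
                cluster_id=f"{component_id}.{i:03d}",
                members=tuple(sorted(clique | attachments[i])),
                component_id=component_id,
                attached_members=frozenset(attachments[i]),
            )
        )
    offset = len(cliques)
    for j, node in enumerate(singletons):
        clusters.append(
            BinCluster(
                cluster_id=f"{component_id}.{offset + j:03d}",
                members=(node,),
                component_id=component_id,
            )
        )
    return clusters


def cluster_graph(
    graph: AniGraph, max_exact_component: int = DEFAULT_MAX_EXACT_COMPONENT
) -> list[BinCluster]:
    """Full clustering: components → maximal cliques → orphan assignment."""
    adj = graph.adjacency()
    clusters: list[BinCluster] = []
    for ci, component in enumerate(connected_components(graph)):
        component_id = f"c{ci:04d}"
        sub_adj = {n: adj[n] & component for n in component}
        if len(component) > max_exact_component:
            logger.warning(
                "component %s has %d nodes (> %d); using greedy clique heuristic",
                component_id,
                len(component),
                max_exact_component,
            )
            cliques = greedy_cliques(component, sub_adj)
        else:
            cliques = maximal_cliques(component, sub_adj)
        clusters.extend(assign_orphans(cliques, sub_adj, component, component_id))
    return clusters


def write_cluster_table(clusters: list[BinCluster], path) -> None:
    """Debug dump: one row per (cluster, member) with the attached flag."""
    with open(path, "w") as out:
        out.write("cluster_id\tcomponent_id\tmember\tattached\n")
        for cluster in clusters:
            for member in cluster.members:
                flag = "1" if member in cluster.attached_members else "0"
                out.write(f"{cluster.cluster_id}\t{cluster.component_id}\t{member}\t{flag}\n")
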