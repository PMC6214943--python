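"""Nearest-neighbor graph over reads and center-anchored partitioning.

The partition phase groups a multiset of strings into clusters anchored at
*centers*: build the directed nearest-neighbor graph (an edge x -> y iff y is
a closest neighbor of x, y != x), repeatedly pick the vertex that the largest
number of vertices can reach, cut out everything that reaches it as one
cluster, and iterate on the residual graph (edges are not recomputed after
removal). The resulting partition guarantees that every string has at least
one of its closest neighbors (other than itself) in its cluster, relative to
the residual graph it was drawn from.

Identical strings are distinct vertices at distance 0; internally they are
condensed into one node with a multiplicity, which is exact because a
duplicate's unique closest neighbors are its copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .alignment import edit_distance


def _as_mapping(strings) -> dict[str, str]:
    if isinstance(strings, Mapping):
        return dict(strings)
    return {f"s{i}": s for i, s in enumerate(strings)}


@dataclass
class NearestNeighborGraph:
    """Directed closest-neighbor graph over a multiset of strings."""

    vertices: dict[str, str]                 # read id -> string
    edges: set[tuple[str, str]]              # (x, y): y closest neighbor of x
    min_distance: dict[str, int]             # per-vertex distance to closest

    def neighbors(self, x: str) -> list[str]:
        return sorted(y for (u, y) in self.edges if u == x)

    def to_dot(self) -> str:
        lines = ["digraph nn {"]
        for x, y in sorted(self.edges):
            lines.append(f'  "{x}" -> "{y}";')
        lines.append("}")
        return "\n".join(lines)


@dataclass
class Cluster:
    """One partition cell: a center read id plus its member read ids."""

    center: str
    members: set[str]

    def __len__(self) -> int:
        return len(self.members)


def _condense(id_to_str: dict[str, str]):
    """Group read ids by identical string; deterministic sorted orders."""
    groups: dict[str, list[str]] = {}
    for rid in sorted(id_to_str):
        groups.setdefault(id_to_str[rid], []).append(rid)
    uniq = sorted(groups)
    return uniq, groups


def _unique_nn(uniq: list[str], groups: dict[str, list[str]], max_dist: int | None):
    """Closest-neighbor sets among unique strings.

    Returns ``nn[s] = (min_dist, [neighbor strings])``. A string with
    multiplicity >= 2 has its duplicates as (the only) closest neighbors at
    distance 0, so it gets no edges to other strings.
    """
    nn: dict[str, tuple[int, list[str]]] = {}
    singles = [s for s in uniq if len(groups[s]) == 1]
    for s in uniq:
        if len(groups[s]) >= 2:
            nn[s] = (0, [])
    lengths = {s: len(s) for s in uniq}
    for s in singles:
        best = max_dist if max_dist is not None else None
        hits: list[tuple[int, str]] = []
        for t in uniq:
            if t == s:
                continue
            lb = abs(lengths[s] - lengths[t])
            if best is not None and lb > best:
                continue
            d = edit_distance(s, t, k=-1 if best is None else best)
            if d < 0:
                continue
            hits.append((d, t))
            if best is None or d < best:
                best = d
        if best is None or not hits:
            nn[s] = (-1, [])  # isolated under the distance cap
        else:
            m = min(d for d, _ in hits)
            nn[s] = (m, sorted(t for d, t in hits if d == m))
    return nn


def nearest_neighbor_graph(
    strings: Mapping[str, str] | Iterable[str], max_dist: int | None = None
) -> NearestNeighborGraph:
    """Build the directed nearest-neighbor graph of a multiset of strings."""
    id_to_str = _as_mapping(strings)
    uniq, groups = _condense(id_to_str)
    nn = _unique_nn(uniq, groups, max_dist)
    edges: set[tuple[str, str]] = set()
    min_distance: dict[str, int] = {}
    for s in uniq:
        ids = groups[s]
        d, neigh = nn[s]
        for rid in ids:
            if len(ids) >= 2:
                min_distance[rid] = 0
                for other in ids:
                    if other != rid:
                        edges.add((rid, other))
            elif d >= 0:
                min_distance[rid] = d
                for t in neigh:
                    for tid in groups[t]:
                        edges.add((rid, tid))
            else:
                min_distance[rid] = -1
    return NearestNeighborGraph(id_to_str, edges, min_distance)


def partition_strings(
    strings: Mapping[str, str] | Iterable[str], max_dist: int | None = None
) -> list[Cluster]:
    """Partition a multiset of strings into center-anchored clusters.

    Works on the condensed graph of unique strings weighted by multiplicity.
    Center ties (equal reachability weight) are broken by the higher
    multiplicity of the center's string, then by the lexicographically
    smallest read id holding it.
    """
    id_to_str = _as_mapping(strings)
    if not id_to_str:
        return []
    uniq, groups = _condense(id_to_str)
    nn = _unique_nn(uniq, groups, max_dist)

    G = nx.DiGraph()
    G.add_nodes_from(uniq)
    for s in uniq:
        for t in nn[s][1]:
            G.add_edge(s, t)

    clusters: list[Cluster] = []
    while G.number_of_nodes():
        best_key = None
        best_node = None
        best_reach: set[str] | None = None
        for s in G.nodes:
            reach = nx.ancestors(G, s) | {s}
            weight = sum(len(groups[t]) for t in reach)
            key = (weight, len(groups[s]), _neg_lex(min(groups[s])))
            if best_key is None or key > best_key:
                best_key, best_node, best_reach = key, s, reach
        members = set()
        for s in best_reach:
            members.update(groups[s])
        clusters.append(Cluster(center=min(groups[best_node]), members=members))
        G.remove_nodes_from(best_reach)
    return clusters


class _neg_lex(str):
    """Wrapper making lexicographically *smaller* strings compare greater."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)
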