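"""Grouping final transcripts into putative gene copies.

Isoforms of one gene copy differ only by exon presence/absence: they align to
each other with large insertions/deletions but without substitutions. Two
transcripts are *compatible* when their optimal alignment (with mismatches
penalized so heavily that any substitution-free co-linear alignment wins if
one exists) contains no mismatched column and no gap run shorter than
``min_indel_length``. A *group* is a maximal clique of the compatibility
graph; the reported number of groups is the exact minimum number of maximal
cliques needed to cover all transcripts (a transcript may sit in several
groups when a copy-distinguishing exon is skipped). The search is exhaustive
and guarded to small transcript counts, which is where this method operates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import networkx as nx
from Bio import Align


@dataclass
class CompatibilityGraph:
    vertices: list[str]
    edges: set[frozenset]
    min_indel_length: int

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(self.vertices)
        G.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return G


@dataclass
class GroupCover:
    groups: list[list[str]]              # the chosen cover, each a maximal clique
    n_groups: int
    membership: dict[str, list[int]]     # transcript -> indices into groups


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1000      # substitution-free alignments dominate
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -1
    return aligner


def indel_only_compatible(u: str, v: str, min_indel_length: int = 20) -> bool:
    """True iff u and v differ only by gap runs of >= ``min_indel_length``."""
    if not u or not v:
        raise ValueError("sequences must be non-empty")
    if u == v:
        return True
    aln = _aligner().align(u, v)[0]
    blocks_u, blocks_v = aln.aligned
    if len(blocks_u) == 0:
        return False
    # substitutions inside aligned blocks
    for (us, ue), (vs, ve) in zip(blocks_u, blocks_v):
        if u[us:ue] != v[vs:ve]:
            return False
    # gap runs: unaligned stretches between/around blocks, per sequence
    runs = []
    prev_u, prev_v = 0, 0
    for (us, ue), (vs, ve) in zip(blocks_u, blocks_v):
        runs.append(us - prev_u)
        runs.append(vs - prev_v)
        prev_u, prev_v = ue, ve
    runs.append(len(u) - prev_u)
    runs.append(len(v) - prev_v)
    return all(r == 0 or r >= min_indel_length for r in runs)


def compatibility_graph(
    transcripts: Mapping[str, str], min_indel_length: int = 20
) -> CompatibilityGraph:
    ids = sorted(transcripts)
    edges: set[frozenset] = set()
    for a, b in combinations(ids, 2):
        if indel_only_compatible(transcripts[a], transcripts[b], min_indel_length):
            edges.add(frozenset((a, b)))
    return CompatibilityGraph(ids, edges, min_indel_length)


def minimum_group_cover(
    transcripts: Mapping[str, str],
    min_indel_length: int = 20,
    max_transcripts: int = 64,
) -> GroupCover:
    """Exact minimum cover of all transcripts by maximal cliques.

    Cover-size ties are broken by preferring larger cliques, then
    lexicographic transcript ids (cliques are enumerated in that order and
    the first minimum cover found is returned).
    """
    ids = sorted(transcripts)
    if len(ids) > max_transcripts:
        raise ValueError(
            f"{len(ids)} transcripts exceed the exact-search guard of "
            f"{max_transcripts}; raise max_transcripts to override"
        )
    if not ids:
        return GroupCover([], 0, {})
    G = compatibility_graph(transcripts, min_indel_length).to_networkx()
    cliques = sorted(
        (sorted(c) for c in nx.find_cliques(G)), key=lambda c: (-len(c), c)
    )
    universe = set(ids)
    for k in range(1, len(cliques) + 1):
        for combo in combinations(range(len(cliques)), k):
            covered: set[str] = set()
            for ci in combo:
                covered.update(cliques[ci])
            if covered == universe:
                groups = [cliques[ci] for ci in combo]
                membership: dict[str, list[int]] = {t: [] for t in ids}
                for gi, grp in enumerate(groups):
                    for t in grp:
                        membership[t].append(gi)
                return GroupCover(groups, k, membership)
    raise AssertionError("maximal cliques always cover all vertices")
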