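"""Iterative cluster-and-correct loop producing candidate transcripts.

Each round partitions the current (possibly already corrected) read strings
into center-anchored clusters, then partially corrects every read towards its
cluster consensus: among a read's variant cells (state != match in the
multi-alignment against the center) the half with the lowest state-specific
support is corrected to the column majority character — but only where that
majority is unique. Correcting only half of the suspicious positions per
round, and skipping majority ties, is what protects genuine low-frequency
variants from being homogenized away.

Termination is enforced by three heuristics on top of convergence (a cluster
has converged when all its member strings are identical):

* undo - a read's correction is reverted if it increased the read's edit
  distance to its center relative to the previous round;
* freeze - a read whose cluster assignment alternates cyclically (center
  signature A,B,A within a 3-round window) is no longer corrected;
* tie-stall - a cluster whose membership repeats and in which a round makes
  no change (all selected positions are majority ties) is declared converged.

A global cycle check on the multiset of working strings and a hard iteration
cap back these heuristics up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .alignment import (
    DEL,
    GAP,
    MATCH,
    PairwiseAlignment,
    align_pair,
    annotate_states_and_support,
    build_multi_alignment,
    consensus,
    edit_distance,
)
from .config import logger
from .formats_io import CcsRead
from .partitioning import Cluster, partition_strings


class ConvergenceError(RuntimeError):
    """Raised when the correction loop exceeds its iteration cap."""


@dataclass
class CandidateTranscript:
    """A corrected consensus sequence proposed as a transcript."""

    transcript_id: str
    sequence: str
    source_cluster_size: int = 0
    assigned_reads: set[str] | None = None
    significance: float | None = None


def correct_cluster_once(members: list[str], center: str) -> list[str]:
    """One partial-correction pass over a cluster.

    For each member string, its variant cells are ranked by support
    ascending (ties by column index) and the ceil(k/2) lowest-support cells
    are set to the column's most frequent character when that character is
    unique; nothing else is touched. Returns corrected strings in input
    order.
    """
    if not members:
        raise ValueError("empty cluster")
    corrected, _ = _correct_rows(members, center)
    return corrected


def _correct_rows(members: list[str], center: str):
    """Correct all members against ``center``; returns (strings, n_changed).

    Duplicate member strings are aligned and corrected once and the result
    shared, which matters late in the loop when most reads agree.
    """
    uniq: dict[str, PairwiseAlignment] = {}
    for s in members:
        if s not in uniq:
            uniq[s] = align_pair(s, center)
    uniq_strings = sorted(uniq)
    A = build_multi_alignment(
        [uniq[s] for s in uniq_strings for _ in _ids_of(members, s)],
        row_ids=[rid for s in uniq_strings for rid in _ids_of(members, s)],
    )
    consensus(A)
    annotate_states_and_support(A)

    cons = A.consensus_codes
    tie = A.consensus_tie
    # correct each unique row pattern once
    row_of_string: dict[str, int] = {}
    pos = 0
    for s in uniq_strings:
        row_of_string[s] = pos
        pos += len(_ids_of(members, s))

    corrected_of: dict[str, str] = {}
    for s in uniq_strings:
        i = row_of_string[s]
        states_row = A.states[i]
        var_cols = [j for j in range(A.n_cols) if states_row[j] != MATCH]
        if not var_cols:
            corrected_of[s] = s
            continue
        var_cols.sort(key=lambda j: (A.support[i, j], j))
        n_fix = math.ceil(len(var_cols) / 2)
        row = A.matrix[i].copy()
        for j in var_cols[:n_fix]:
            if tie[j]:
                continue  # most frequent character not unique: no correction
            row[j] = cons[j]
        corrected_of[s] = _row_to_string(row)

    out = [corrected_of[s] for s in members]
    n_changed = sum(1 for old, new in zip(members, out) if old != new)
    return out, n_changed


def _ids_of(members: list[str], s: str):
    return [k for k, m in enumerate(members) if m == s]


def _row_to_string(row) -> str:
    from .alignment import _CHAR_OF

    return "".join(_CHAR_OF[row[row != 0]])


@dataclass
class CorrectionState:
    """Bookkeeping carried across correction rounds."""

    current_strings: dict[str, str]
    previous_center_distance: dict[str, float]
    partition_history: dict[str, list[str]]
    frozen: set[str] = field(default_factory=set)
    converged_signatures: set[frozenset] = field(default_factory=set)


def cluster_correct(
    reads: list[CcsRead],
    max_rounds: int = 20,
    max_dist: int | None = None,
) -> list[CandidateTranscript]:
    """Run the partition/correct loop to convergence; return candidates.

    Candidates are the distinct center sequences of the converged clusters,
    deduplicated by exact sequence, each annotated with the size of the
    largest cluster that produced it.
    """
    if not reads:
        raise ValueError("need at least one read")
    state = CorrectionState(
        current_strings={r.read_id: r.sequence for r in reads},
        previous_center_distance={r.read_id: math.inf for r in reads},
        partition_history={r.read_id: [] for r in reads},
    )
    seen_states: set[int] = set()
    prev_members: set[frozenset] = set()
    final_clusters: list[Cluster] | None = None

    for rnd in range(1, max_rounds + 1):
        clusters = partition_strings(state.current_strings, max_dist=max_dist)
        for cl in clusters:
            center_id = cl.center
            for rid in cl.members:
                hist = state.partition_history[rid]
                hist.append(center_id)
                if len(hist) > 3:
                    del hist[0]
                # cyclic alternation A,B,A: stop correcting this read
                if len(hist) == 3 and hist[0] == hist[2] != hist[1]:
                    state.frozen.add(rid)

        unconverged = [
            cl
            for cl in clusters
            if len({state.current_strings[rid] for rid in cl.members}) > 1
            and frozenset(cl.members) not in state.converged_signatures
        ]
        if not unconverged:
            final_clusters = clusters
            break

        total_changed = 0
        for cl in unconverged:
            member_ids = sorted(cl.members)
            center_seq = state.current_strings[cl.center]
            old = [state.current_strings[rid] for rid in member_ids]
            corrected, _ = _correct_rows(old, center_seq)
            dist_cache: dict[str, int] = {}
            changed_here = 0
            for rid, old_s, new_s in zip(member_ids, old, corrected):
                if rid in state.frozen or new_s == old_s:
                    kept = old_s
                else:
                    if new_s not in dist_cache:
                        dist_cache[new_s] = edit_distance(new_s, center_seq)
                    d_new = dist_cache[new_s]
                    if d_new > state.previous_center_distance[rid]:
                        kept = old_s  # undo: correction moved away from center
                    else:
                        kept = new_s
                        changed_here += 1
                state.current_strings[rid] = kept
                state.previous_center_distance[rid] = edit_distance(
                    kept, center_seq
                ) if kept != center_seq else 0
            total_changed += changed_here
            sig = frozenset(cl.members)
            if changed_here == 0 and sig in prev_members:
                # same membership twice and only tie columns differ: converged
                state.converged_signatures.add(sig)

        prev_members = {frozenset(cl.members) for cl in clusters}
        logger.debug(
            "correction round %d: %d clusters, %d unconverged, %d strings changed",
            rnd,
            len(clusters),
            len(unconverged),
            total_changed,
        )
        if total_changed == 0:
            final_clusters = clusters
            break
        fingerprint = hash(tuple(sorted(state.current_strings.values())))
        if fingerprint in seen_states:
            final_clusters = clusters
            break
        seen_states.add(fingerprint)
    else:
        raise ConvergenceError(
            f"correction did not converge within {max_rounds} rounds; "
            f"{len(set(state.current_strings.values()))} distinct strings remain"
        )

    if final_clusters is None:
        final_clusters = partition_strings(state.current_strings, max_dist=max_dist)

    by_seq: dict[str, int] = {}
    for cl in final_clusters:
        seq = state.current_strings[cl.center]
        by_seq[seq] = max(by_seq.get(seq, 0), len(cl.members))
    candidates = [
        CandidateTranscript(f"candidate_{k}", seq, source_cluster_size=by_seq[seq])
        for k, seq in enumerate(sorted(by_seq, key=lambda s: (-by_seq[s], s)))
    ]
    logger.info(
        "correction finished: %d reads -> %d candidate transcripts",
        len(reads),
        len(candidates),
    )
    return candidates
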