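"""Candidate filtering: read assignment, pairwise testing, and the driver.

After correction proposes candidate transcripts, the *original* (uncorrected)
reads are greedily assigned to candidates: repeatedly pick the candidate that
is a closest neighbor (by edit distance) of the most unassigned reads, bind
those reads to it, and repeat on the reduced sets. Each surviving candidate
is then tested against each of its closest-neighbor candidates with the
quality-weighted tail bound, pooling both candidates' reads, and receives its
*least* significant (largest) pairwise p-value. Candidates whose p-value
exceeds alpha are eliminated, at most tau per round, and the
assign/test/remove loop repeats until every survivor is significant.

The whole pipeline is deterministic: no randomness anywhere, and all
tie-breaks are by support and lexicographic order.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .alignment import edit_distance
from .config import RunConfig, logger
from .correction import CandidateTranscript, cluster_correct
from .formats_io import CcsRead, write_run_report, write_transcripts_fasta
from .significance import candidate_pair_pvalue


@dataclass
class ReadAssignment:
    """Mapping of every read to exactly one of its closest candidates."""

    assignment: dict[str, str]          # read_id -> candidate_id
    distance: dict[str, int]            # read_id -> edit distance to candidate

    def reads_of(self, candidate_id: str) -> list[str]:
        return sorted(r for r, c in self.assignment.items() if c == candidate_id)


@dataclass
class FilterRound:
    """Outcome of one test round."""

    round_index: int
    pvalues: dict[str, float]           # candidate_id -> least significant p
    removed: list[str] = field(default_factory=list)


def _distance_matrix(reads: list[CcsRead], candidates: list[CandidateTranscript]):
    """Read-by-candidate edit distances, with duplicate reads computed once."""
    dist = np.zeros((len(reads), len(candidates)), dtype=np.int64)
    cache: dict[tuple[str, str], int] = {}
    for i, r in enumerate(reads):
        for j, c in enumerate(candidates):
            key = (r.sequence, c.sequence)
            if key not in cache:
                cache[key] = edit_distance(r.sequence, c.sequence)
            dist[i, j] = cache[key]
    return dist


def assign_reads(
    reads: list[CcsRead], candidates: list[CandidateTranscript]
) -> ReadAssignment:
    """Greedy cover: bind reads to one of their closest-neighbor candidates.

    Ties between candidates covering equally many unassigned reads are broken
    by the lexicographically smallest candidate sequence.
    """
    if not candidates:
        raise ValueError("no candidates to assign reads to")
    dist = _distance_matrix(reads, candidates)
    unassigned = set(range(len(reads)))
    remaining = set(range(len(candidates)))
    assignment: dict[str, str] = {}
    distance: dict[str, int] = {}
    while unassigned:
        rows = sorted(unassigned)
        cols = sorted(remaining)
        sub = dist[np.ix_(rows, cols)]
        row_min = sub.min(axis=1)
        closest = sub == row_min[:, None]           # per-read closest candidates
        counts = closest.sum(axis=0)
        best = max(
            range(len(cols)),
            key=lambda jj: (
                counts[jj],
                candidates[cols[jj]].source_cluster_size,
                _rev(candidates[cols[jj]].sequence),
            ),
        )
        cj = cols[best]
        chosen = [rows[ii] for ii in range(len(rows)) if closest[ii, best]]
        if not chosen:  # unchosen candidate: drop it from further rounds
            remaining.discard(cj)
            continue
        for ri in chosen:
            assignment[reads[ri].read_id] = candidates[cj].transcript_id
            distance[reads[ri].read_id] = int(dist[ri, cj])
            unassigned.discard(ri)
        remaining.discard(cj)
        if not remaining and unassigned:
            raise AssertionError("reads left but candidate set exhausted")
    return ReadAssignment(assignment, distance)


class _rev(str):
    """Sort helper: lexicographically smaller strings compare greater."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)


def test_round(
    candidates: list[CandidateTranscript],
    assignment: ReadAssignment,
    reads: list[CcsRead],
    cfg: RunConfig,
    round_index: int = 0,
) -> FilterRound:
    """Test every candidate against its closest-neighbor candidates.

    p_i is the maximum (least significant) p-value over the tested pairs; a
    candidate with no neighbor (singleton candidate set) keeps p = 0.
    """
    reads_by_id = {r.read_id: r for r in reads}
    pooled: dict[str, list[CcsRead]] = {
        c.transcript_id: [reads_by_id[rid] for rid in assignment.reads_of(c.transcript_id)]
        for c in candidates
    }
    pvals: dict[str, float] = {}
    for ci in candidates:
        if len(candidates) == 1:
            pvals[ci.transcript_id] = 0.0
            continue
        dists = {
            cj.transcript_id: edit_distance(ci.sequence, cj.sequence)
            for cj in candidates
            if cj.transcript_id != ci.transcript_id
        }
        dmin = min(dists.values())
        neighbors = sorted(t for t, d in dists.items() if d == dmin)
        seq_of = {c.transcript_id: c.sequence for c in candidates}
        p_i = 0.0
        for tj in neighbors:
            res = candidate_pair_pvalue(
                ci.sequence,
                seq_of[tj],
                pooled[ci.transcript_id],
                pooled[tj],
                max_variants=cfg.max_variants,
                p_convention=cfg.p_convention,
                delta_convention=cfg.delta_convention,
                p_floor=cfg.p_floor,
                p_cap=cfg.p_cap,
            )
            p_i = max(p_i, res.p_value)
        pvals[ci.transcript_id] = p_i
    return FilterRound(round_index, pvals)


test_round.__test__ = False  # library function, not a pytest case


def filter_candidates(
    reads: list[CcsRead],
    candidates: list[CandidateTranscript],
    cfg: RunConfig | None = None,
) -> tuple[list[CandidateTranscript], ReadAssignment, dict[str, float]]:
    """Iteratively remove unsupported candidates until all survivors pass.

    Per round at most ``cfg.tau`` candidates with p > alpha are removed (the
    ones with the highest p-values). Returns survivors with their final
    assignment and p-values.
    """
    cfg = cfg or RunConfig()
    current = list(candidates)
    round_index = 0
    while current:
        round_index += 1
        assignment = assign_reads(reads, current)
        fr = test_round(current, assignment, reads, cfg, round_index)
        doomed = [t for t, p in fr.pvalues.items() if p > cfg.alpha]
        if not doomed:
            for c in current:
                c.assigned_reads = set(assignment.reads_of(c.transcript_id))
                c.significance = fr.pvalues[c.transcript_id]
            logger.info(
                "filtering converged after %d rounds: %d transcripts",
                round_index,
                len(current),
            )
            return current, assignment, fr.pvalues
        seq_of = {c.transcript_id: c.sequence for c in current}
        doomed.sort(key=lambda t: (-fr.pvalues[t], seq_of[t]))
        removed = set(doomed[: cfg.tau])
        logger.info(
            "filtering round %d: removing %d/%d candidates (max p=%.3g)",
            round_index,
            len(removed),
            len(current),
            max(fr.pvalues[t] for t in removed),
        )
        current = [c for c in current if c.transcript_id not in removed]
    return [], ReadAssignment({}, {}), {}


def run_pipeline(
    reads: list[CcsRead],
    cfg: RunConfig | None = None,
    out_dir: str | os.PathLike | None = None,
) -> list[CandidateTranscript]:
    """Full pipeline: cluster-correct, then statistically filter.

    Deterministic for a fixed input ordering; optionally writes FASTA, the
    two TSV reports and a JSON echo of the configuration to ``out_dir``.
    """
    cfg = cfg or RunConfig()
    if not reads:
        raise ValueError("no reads supplied")
    candidates = cluster_correct(
        reads, max_rounds=cfg.max_rounds, max_dist=cfg.max_dist
    )
    final, assignment, pvalues = filter_candidates(reads, candidates, cfg)
    # stable output ids ordered by support then sequence
    final.sort(key=lambda c: (-(len(c.assigned_reads or ())), c.sequence))
    renamed: dict[str, str] = {}
    for k, c in enumerate(final, start=1):
        new_id = f"transcript_{k}"
        renamed[c.transcript_id] = new_id
        c.transcript_id = new_id
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_transcripts_fasta(final, os.path.join(out_dir, "transcripts.fasta"))
        assignments = {
            rid: (renamed[tid], assignment.distance[rid])
            for rid, tid in assignment.assignment.items()
            if tid in renamed
        }
        stats = {
            c.transcript_id: (len(c.assigned_reads or ()), c.significance)
            for c in final
        }
        write_run_report(assignments, stats, out_dir)
        with open(os.path.join(out_dir, "run_config.json"), "w") as fh:
            fh.write(cfg.to_json() + "\n")
    return final
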