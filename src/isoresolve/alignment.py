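"""Edit distances, pairwise alignments, and the multi-alignment matrix.

The correction and significance stages both operate on a multi-alignment
matrix *A* built by stacking pairwise global alignments of reads against a
common target (a cluster center or a candidate transcript). Cells of *A* are
characters over {A,C,G,T,-}; relative to the per-column consensus every cell
is in one of four states (match / substitution / insertion / deletion), and
the *support* of a cell is the frequency of its state in its column relative
to all occurrences of that state in the matrix (n_j^t / n^t). Support is
state-specific on purpose: insertions and deletions are more frequent error
types than substitutions in CCS reads, so more coverage is required before an
indel variant is protected from correction.

Alignments are computed with edlib (exact unit-cost global alignment, banded
internally), which keeps distances and alignment paths mutually consistent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np

GAP = "-"

# byte codes used inside the matrix; '-' deliberately sorts first so that
# np.argmax tie-breaking is deterministic over the fixed order (-, A, C, G, T)
_CODE_OF = {"-": 0, "A": 1, "C": 2, "G": 3, "T": 4}
_CHAR_OF = np.array(["-", "A", "C", "G", "T"])

# cell states
MATCH, SUB, INS, DEL = 0, 1, 2, 3
N_STATES = 4

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def edit_distance(x: str, y: str, k: int = -1) -> int:
    """Unit-cost Levenshtein distance between two strings.

    With ``k >= 0`` the computation may stop early and return -1 when the
    distance exceeds ``k``.
    """
    if x == y:
        return 0
    return edlib.align(x, y, mode="NW", task="distance", k=k)["editDistance"]


@dataclass
class PairwiseAlignment:
    """A global alignment of ``query`` against ``target`` as two gapped rows."""

    query_row: str
    target_row: str
    edit_distance: int

    @property
    def query(self) -> str:
        return self.query_row.replace(GAP, "")

    @property
    def target(self) -> str:
        return self.target_row.replace(GAP, "")


def align_pair(query: str, target: str) -> PairwiseAlignment:
    """Optimal unit-cost global alignment of ``query`` to ``target``."""
    if query == target:
        return PairwiseAlignment(query, target, 0)
    res = edlib.align(query, target, mode="NW", task="path")
    q_parts: list[str] = []
    t_parts: list[str] = []
    qi = ti = 0
    for m in _CIGAR_RE.finditer(res["cigar"]):
        n, op = int(m.group(1)), m.group(2)
        if op in "=X":
            q_parts.append(query[qi : qi + n])
            t_parts.append(target[ti : ti + n])
            qi += n
            ti += n
        elif op == "I":  # insertion in query relative to target
            q_parts.append(query[qi : qi + n])
            t_parts.append(GAP * n)
            qi += n
        else:  # 'D': query gap over target bases
            q_parts.append(GAP * n)
            t_parts.append(target[ti : ti + n])
            ti += n
    return PairwiseAlignment("".join(q_parts), "".join(t_parts), res["editDistance"])


def _parse_against_target(aln: PairwiseAlignment, target_len: int):
    """Split an alignment into per-target-position cells and insertions.

    Returns ``(bases, insertions)`` where ``bases[p]`` is the query character
    (or '-') aligned to target position ``p`` and ``insertions[p]`` the string
    of query bases inserted immediately before target position ``p``
    (``p == target_len`` collects trailing insertions).
    """
    bases = [GAP] * target_len
    insertions: dict[int, str] = {}
    p = 0
    for qc, tc in zip(aln.query_row, aln.target_row):
        if tc != GAP:
            bases[p] = qc
            p += 1
        else:
            insertions[p] = insertions.get(p, "") + qc
    return bases, insertions


@dataclass
class MultiAlignmentMatrix:
    """Reads (and optionally a reference row) stacked against one target.

    ``matrix`` holds byte codes (0='-', 1..4=ACGT) with one row per read, in
    input order, followed by the optional reference row. ``target_row`` is
    the gapped target; columns where it is '-' are insertion columns.
    """

    matrix: np.ndarray            # (n_rows, n_cols) uint8
    row_ids: list[str]
    target: str
    target_row: np.ndarray        # (n_cols,) uint8
    reference_index: int | None = None
    # filled by annotate_states_and_support:
    consensus_codes: np.ndarray | None = None
    consensus_tie: np.ndarray | None = None
    states: np.ndarray | None = None
    column_state_counts: np.ndarray | None = None   # (n_cols, N_STATES)
    total_state_counts: np.ndarray | None = None    # (N_STATES,)
    support: np.ndarray | None = None               # (n_rows, n_cols)

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    def row_string(self, i: int) -> str:
        return "".join(_CHAR_OF[self.matrix[i]])

    def row_sequence(self, i: int) -> str:
        """Row ``i`` with gaps removed (the original ungapped string)."""
        row = self.matrix[i]
        return "".join(_CHAR_OF[row[row != 0]])

    def dump(self) -> str:
        """Padded text rendering of the matrix (debugging aid)."""
        lines = ["target\t" + "".join(_CHAR_OF[self.target_row])]
        for i, rid in enumerate(self.row_ids):
            lines.append(f"{rid}\t{self.row_string(i)}")
        return "\n".join(lines)


def _encode(chars: list[str]) -> np.ndarray:
    return np.array([_CODE_OF[c] for c in chars], dtype=np.uint8)


def build_multi_alignment(
    alignments: list[PairwiseAlignment],
    row_ids: list[str] | None = None,
    reference: PairwiseAlignment | None = None,
) -> MultiAlignmentMatrix:
    """Stack pairwise alignments sharing one target into a matrix.

    Target columns are preserved in order; between consecutive target
    positions enough insertion columns are created to hold the longest
    insertion any row places there, insertions being left-aligned within the
    slot.  Every row spells its original string after gap removal.
    """
    if not alignments:
        raise ValueError("need at least one alignment")
    target = alignments[0].target
    all_alns = list(alignments) + ([reference] if reference is not None else [])
    for aln in all_alns:
        if aln.target != target:
            raise ValueError("alignments do not share a common target")
    if row_ids is None:
        row_ids = [f"row{i}" for i in range(len(alignments))]
    if len(row_ids) != len(alignments):
        raise ValueError("row_ids length mismatch")

    L = len(target)
    parsed = [_parse_against_target(a, L) for a in all_alns]
    max_ins = [0] * (L + 1)
    for _, ins in parsed:
        for p, s in ins.items():
            if len(s) > max_ins[p]:
                max_ins[p] = len(s)

    n_cols = L + sum(max_ins)
    # gapped target row and column layout
    t_chars: list[str] = []
    for p in range(L):
        t_chars.extend(GAP * max_ins[p])
        t_chars.append(target[p])
    t_chars.extend(GAP * max_ins[L])
    target_row = _encode(t_chars)

    rows = np.zeros((len(all_alns), n_cols), dtype=np.uint8)
    for r, (bases, ins) in enumerate(parsed):
        chars: list[str] = []
        for p in range(L):
            s = ins.get(p, "")
            chars.append(s + GAP * (max_ins[p] - len(s)))
            chars.append(bases[p])
        s = ins.get(L, "")
        chars.append(s + GAP * (max_ins[L] - len(s)))
        rows[r] = _encode(list("".join(chars)))

    ref_index = None
    ids = list(row_ids)
    if reference is not None:
        ref_index = len(all_alns) - 1
        ids = ids + ["__reference__"]
    return MultiAlignmentMatrix(rows, ids, target, target_row, ref_index)


def consensus(A: MultiAlignmentMatrix) -> str:
    """Ungapped per-column majority consensus of the matrix.

    Ties are tracked internally (``A.consensus_tie``); a tie column carries
    the first character in the fixed order (-, A, C, G, T) for state
    annotation but is never used for correction. Columns whose consensus is
    '-' contribute nothing to the returned string.
    """
    codes, tie = _consensus_profile(A)
    A.consensus_codes, A.consensus_tie = codes, tie
    return "".join(_CHAR_OF[codes[codes != 0]])


def _consensus_profile(A: MultiAlignmentMatrix):
    counts = np.zeros((5, A.n_cols), dtype=np.int64)
    for code in range(5):
        counts[code] = (A.matrix == code).sum(axis=0)
    top = counts.max(axis=0)
    codes = counts.argmax(axis=0).astype(np.uint8)
    tie = (counts == top).sum(axis=0) > 1
    return codes, tie


def annotate_states_and_support(A: MultiAlignmentMatrix) -> MultiAlignmentMatrix:
    """Classify every cell against the column consensus and compute supports.

    A cell is a match iff it equals the column consensus; an insertion iff it
    is a base where the consensus is '-'; a deletion iff it is '-' where the
    consensus is a base; a substitution otherwise. The support of cell (i,j)
    in state t is n_j^t / n^t.
    """
    if A.consensus_codes is None:
        consensus(A)
    cons = A.consensus_codes
    M = A.matrix
    states = np.full(M.shape, SUB, dtype=np.uint8)
    states[M == cons[None, :]] = MATCH
    states[(M != 0) & (cons[None, :] == 0)] = INS
    states[(M == 0) & (cons[None, :] != 0)] = DEL

    col_counts = np.zeros((A.n_cols, N_STATES), dtype=np.int64)
    for t in range(N_STATES):
        col_counts[:, t] = (states == t).sum(axis=0)
    totals = col_counts.sum(axis=0)

    safe_totals = np.where(totals == 0, 1, totals)
    per_col = col_counts / safe_totals[None, :]          # (n_cols, N_STATES)
    support = per_col[np.arange(A.n_cols)[None, :], states.astype(np.int64)]

    A.states = states
    A.column_state_counts = col_counts
    A.total_state_counts = totals
    A.support = support
    return A
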