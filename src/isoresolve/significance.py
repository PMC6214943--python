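"""Quality-weighted hypothesis test between two candidate transcripts.

Given candidates c and d with their assigned reads, the null hypothesis is
that all reads originated from d and that the positions where c and d differ
(the variant positions V) are sequencing errors. For read i, S_i = 1 iff the
read carries c's character at every variant column, and under the null S_i is
Bernoulli with mean p_i = prod_{j in V} p_ij, where p_ij is the probability
(from the read's Phred qualities) that position j matches c by error. The
test statistic is the weighted support

    T = prod_{i: s_i = 1} 1 / p_i ,

so high-quality reads supporting many linked variants weigh more. After a log
transform and normalization by max_k(-log p_k), T' is a weighted sum of
Bernoulli variables with coefficients in (0,1], and the classic
Chernoff-Hoeffding bound for such sums,

    P(T' > (1+delta) mu) < (e^delta / (1+delta)^(1+delta))^mu ,

gives a closed-form significance value. When the observed t' does not exceed
the null expectation mu the observation is clearly insignificant and the
p-value defaults to 0.5.

Validity rests on four documented assumptions, asserted nowhere at runtime:
d is error-free; where c and d agree they are not both wrong; errors at
different positions of one read are independent; reads are independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alignment import (
    GAP,
    MultiAlignmentMatrix,
    align_pair,
    build_multi_alignment,
)
from .formats_io import CcsRead


@dataclass
class VariantPositions:
    """Multi-alignment columns where candidates c and d disagree."""

    columns: list[int]

    def __len__(self) -> int:
        return len(self.columns)


@dataclass
class SupportProfile:
    """Per-read support indicators and null error probabilities."""

    read_ids: list[str]
    s: np.ndarray          # (n,) bool: read matches c at all variant columns
    log_p: np.ndarray      # (n,) float: log p_i (negative)

    @property
    def n(self) -> int:
        return len(self.read_ids)

    @property
    def p(self) -> np.ndarray:
        return np.exp(self.log_p)


@dataclass
class TestResult:
    t: float
    t_prime: float
    mu: float
    delta: float
    p_value: float
    n_variants: int = 0
    skipped: bool = False


def variant_positions(A: MultiAlignmentMatrix) -> VariantPositions:
    """Columns where the reference row (candidate c) differs from the target d.

    Gap characters count as disagreement (insertions/deletions in c relative
    to d are variants).
    """
    if A.reference_index is None:
        raise ValueError("matrix has no reference row for candidate c")
    ref = A.matrix[A.reference_index]
    cols = np.nonzero(ref != A.target_row)[0]
    return VariantPositions(columns=[int(j) for j in cols])


def read_error_probabilities(
    read: CcsRead,
    A: MultiAlignmentMatrix,
    row_index: int,
    V: VariantPositions,
    p_convention: str = "specific",
    p_floor: float = 1e-7,
    p_cap: float = 0.5,
) -> list[float]:
    """Null error probabilities p_ij of read ``read`` at the variant columns.

    The Phred quality of the read base occupying column j is converted to an
    error probability; at substitution variants the ``specific`` convention
    divides by 3 (the error must produce the one base c carries). Where the
    read has a gap, the quality is the minimum over the two flanking read
    bases. Probabilities are clamped to [p_floor, p_cap].
    """
    row = A.matrix[row_index]
    ref = A.matrix[A.reference_index] if A.reference_index is not None else None
    # map matrix columns to read base indices
    nongap = row != 0
    base_index = np.cumsum(nongap) - 1  # valid where nongap
    quals = read.qualities
    n_bases = len(quals)

    probs: list[float] = []
    for j in V.columns:
        if nongap[j]:
            q = quals[base_index[j]]
        else:  # read gap: min of flanking base qualities
            left = base_index[j]          # last base at or before j (-1 if none)
            right = left + 1              # next base after j
            cand = []
            if left >= 0:
                cand.append(quals[left])
            if right < n_bases:
                cand.append(quals[right])
            q = min(cand) if cand else 0
        p = 10.0 ** (-q / 10.0)
        if p_convention == "specific" and _is_substitution_variant(A, ref, j):
            p /= 3.0
        probs.append(min(max(p, p_floor), p_cap))
    return probs


def _is_substitution_variant(A, ref, j) -> bool:
    """Variant type at column j from c (reference row) versus the target d."""
    if ref is None:
        return False
    return ref[j] != 0 and A.target_row[j] != 0


def build_support_profile(
    reads: list[CcsRead],
    A: MultiAlignmentMatrix,
    V: VariantPositions,
    p_convention: str = "specific",
    p_floor: float = 1e-7,
    p_cap: float = 0.5,
) -> SupportProfile:
    """Assemble S_i and p_i for every read against variant positions V."""
    if A.reference_index is None:
        raise ValueError("matrix has no reference row")
    ref = A.matrix[A.reference_index]
    cols = np.array(V.columns, dtype=np.int64)
    s = np.zeros(len(reads), dtype=bool)
    log_p = np.zeros(len(reads), dtype=np.float64)
    for i, read in enumerate(reads):
        row = A.matrix[i]
        s[i] = bool(np.all(row[cols] == ref[cols])) if len(cols) else False
        probs = read_error_probabilities(
            read, A, i, V, p_convention=p_convention, p_floor=p_floor, p_cap=p_cap
        )
        log_p[i] = float(np.sum(np.log(probs)))
    return SupportProfile([r.read_id for r in reads], s, log_p)


def weighted_support(profile: SupportProfile) -> float:
    """Observed statistic t = prod over supporting reads of 1/p_i (1 if none)."""
    log_t = float(-np.sum(profile.log_p[profile.s]))
    return math.exp(log_t) if log_t < 700 else math.inf


def tail_bound(
    profile: SupportProfile, delta_convention: str = "printed"
) -> TestResult:
    """Closed-form upper bound on P(T >= t); the significance value.

    Computed entirely in log space: log t = sum over supporting reads of
    -log p_i, so neither t nor the bound can overflow for thousands of reads
    with p_i down to 1e-300. Returns 0.5 on the insignificant branch
    (t' <= mu) and in the degenerate all-p_i=1 case.
    """
    neg_log_p = -profile.log_p
    mx = float(np.max(neg_log_p)) if profile.n else 0.0
    if mx <= 0.0:
        return TestResult(1.0, 0.0, 0.0, 0.0, 0.5)
    log_t = float(np.sum(neg_log_p[profile.s]))
    t_prime = log_t / mx
    mu = float(np.sum(np.exp(profile.log_p) * neg_log_p)) / mx
    t = math.exp(log_t) if log_t < 700 else math.inf
    if t_prime <= mu or mu == 0.0:
        return TestResult(t, t_prime, mu, 0.0, 0.5)
    if delta_convention == "printed":
        delta = t_prime / mu
    else:  # shifted: apply the bound exactly at t'
        delta = t_prime / mu - 1.0
    if delta <= 0.0:
        return TestResult(t, t_prime, mu, delta, 0.5)
    log_bound = mu * (delta - (1.0 + delta) * math.log1p(delta))
    p_value = min(math.exp(log_bound), 1.0)
    p_value = max(p_value, 5e-324)  # keep strictly positive
    return TestResult(t, t_prime, mu, delta, p_value)


def candidate_pair_pvalue(
    c_seq: str,
    d_seq: str,
    reads_c: list[CcsRead],
    reads_d: list[CcsRead],
    max_variants: int = 10,
    p_convention: str = "specific",
    delta_convention: str = "printed",
    p_floor: float = 1e-7,
    p_cap: float = 0.5,
) -> TestResult:
    """Significance of candidate c against neighbor candidate d.

    Aligns the pooled reads and c itself to d, extracts the variant columns,
    and evaluates the tail bound. Pairs with more than ``max_variants``
    variant columns are not evaluated (their p-value would be nearly 0) and
    are reported as significant with p = 0.
    """
    if c_seq == d_seq:
        raise ValueError("c and d must be distinct candidates")
    reads = list(reads_c) + list(reads_d)
    if not reads:
        raise ValueError("no reads to test")
    alignments = [align_pair(r.sequence, d_seq) for r in reads]
    ref_aln = align_pair(c_seq, d_seq)
    A = build_multi_alignment(
        alignments, row_ids=[r.read_id for r in reads], reference=ref_aln
    )
    V = variant_positions(A)
    if len(V) > max_variants:
        return TestResult(
            math.inf, math.inf, 0.0, math.inf, 0.0, n_variants=len(V), skipped=True
        )
    profile = build_support_profile(
        reads, A, V, p_convention=p_convention, p_floor=p_floor, p_cap=p_cap
    )
    result = tail_bound(profile, delta_convention=delta_convention)
    result.n_variants = len(V)
    return result
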