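import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoresolve import (
    align_pair,
    annotate_states_and_support,
    build_multi_alignment,
    consensus,
    edit_distance,
)
from isoresolve.alignment import DEL, INS, MATCH, SUB


def dp_edit_distance(x: str, y: str) -> int:
    """Independent quadratic DP oracle for the Levenshtein distance."""
    prev = list(range(len(y) + 1))
    for i, cx in enumerate(x, 1):
        cur = [i]
        for j, cy in enumerate(y, 1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (cx != cy))
            )
        prev = cur
    return prev[-1]


dna = st.text(alphabet="ACGT", min_size=0, max_size=50)


class TestEditDistance:
    @pytest.mark.parametrize(
        "x, y, expected",
        [("ACGT", "ACGT", 0), ("ACGT", "ACTT", 1), ("AAA", "", 3), ("", "", 0)],
    )
    def test_known_values(self, x, y, expected):
        assert edit_distance(x, y) == expected

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(dna, dna)
    def test_matches_dp_oracle_and_symmetric(self, x, y):
        d = edit_distance(x, y)
        assert d == dp_edit_distance(x, y)
        assert d == edit_distance(y, x)


class TestAlignPair:
    def test_identity(self):
        aln = align_pair("ACGT", "ACGT")
        assert (aln.query_row, aln.target_row, aln.edit_distance) == (
            "ACGT",
            "ACGT",
            0,
        )

    def test_single_gap(self):
        aln = align_pair("ACT", "ACGT")
        assert aln.edit_distance == 1
        assert aln.query_row.replace("-", "") == "ACT"
        assert aln.target_row == "ACGT"
        assert aln.query_row.count("-") == 1

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(dna.filter(bool), dna.filter(bool))
    def test_rows_consistent_with_distance(self, x, y):
        aln = align_pair(x, y)
        assert aln.query == x and aln.target == y
        assert len(aln.query_row) == len(aln.target_row)
        assert not any(
            q == t == "-" for q, t in zip(aln.query_row, aln.target_row)
        )
        column_dist = sum(
            1 for q, t in zip(aln.query_row, aln.target_row) if q != t
        )
        assert aln.edit_distance == column_dist == edit_distance(x, y)


class TestMultiAlignment:
    def test_identical_reads_no_gap_columns(self):
        alns = [align_pair("ACGT", "ACGT") for _ in range(3)]
        A = build_multi_alignment(alns)
        assert A.n_cols == 4
        consensus(A)
        annotate_states_and_support(A)
        assert (A.states == MATCH).all()

    def test_single_insertion_creates_one_column(self):
        alns = [align_pair("ACGTT", "ACGTT"), align_pair("ACGATT", "ACGTT")]
        A = build_multi_alignment(alns)
        assert A.n_cols == 6
        ins_cols = np.nonzero(A.target_row == 0)[0]
        assert len(ins_cols) == 1
        j = ins_cols[0]
        assert A.row_string(0)[j] == "-"
        assert A.row_string(1)[j] == "A"

    def test_column_counts(self):
        reads = ["ACGT", "ACTT", "ACGT"]
        A = build_multi_alignment([align_pair(r, "ACGT") for r in reads])
        col = [A.row_string(i)[2] for i in range(3)]
        assert sorted(col) == ["G", "G", "T"]

    def test_rows_spell_original_strings(self):
        rng = np.random.default_rng(7)
        target = "".join(rng.choice(list("ACGT"), size=40))
        reads = []
        for _ in range(6):
            # random small perturbations
            s = list(target)
            for _ in range(int(rng.integers(0, 4))):
                i = int(rng.integers(len(s)))
                op = rng.integers(3)
                if op == 0:
                    s[i] = "ACGT"[rng.integers(4)]
                elif op == 1 and len(s) > 1:
                    del s[i]
                else:
                    s.insert(i, "ACGT"[rng.integers(4)])
            reads.append("".join(s))
        A = build_multi_alignment([align_pair(r, target) for r in reads])
        for i, r in enumerate(reads):
            assert A.row_sequence(i) == r

    def test_mismatched_targets_rejected(self):
        with pytest.raises(ValueError):
            build_multi_alignment([align_pair("ACGT", "ACGT"), align_pair("AC", "AC")])


class TestConsensusAndSupport:
    def test_majority_consensus(self):
        reads = ["ACGT"] * 5 + ["ACTT"]
        A = build_multi_alignment([align_pair(r, "ACGT") for r in reads])
        assert consensus(A) == "ACGT"

    def test_tie_column_flagged_undefined(self):
        A = build_multi_alignment([align_pair("AC", "AC"), align_pair("AG", "AC")])
        consensus(A)
        assert not A.consensus_tie[0]
        assert A.consensus_tie[1]

    def test_substitution_support_single_variant(self):
        reads = ["ACGT"] * 5 + ["ACTT"]
        A = build_multi_alignment([align_pair(r, "ACGT") for r in reads])
        consensus(A)
        annotate_states_and_support(A)
        assert A.states[5, 2] == SUB
        assert A.support[5, 2] == 1.0  # n_2^sub / n^sub = 1/1

    def test_two_substitutions_share_state_mass(self):
        reads = ["ACGTACGT"] * 8 + ["ATGTACGT", "ACGTAGGT"]
        A = build_multi_alignment([align_pair(r, "ACGTACGT") for r in reads])
        consensus(A)
        annotate_states_and_support(A)
        assert A.states[8, 1] == SUB and A.states[9, 5] == SUB
        assert A.support[8, 1] == 0.5 and A.support[9, 5] == 0.5

    def test_uniform_matrix_support(self):
        reads = ["ACGT"] * 4
        A = build_multi_alignment([align_pair(r, "ACGT") for r in reads])
        consensus(A)
        annotate_states_and_support(A)
        assert np.allclose(A.support, 4 / (4 * 4))

    def test_supports_sum_to_one_per_state(self):
        rng = np.random.default_rng(3)
        target = "".join(rng.choice(list("ACGT"), size=30))
        reads = [target]
        for k in range(5):
            s = list(target)
            s[3 + k] = "ACGT"[(("ACGT".index(s[3 + k])) + 1) % 4]
            reads.append("".join(s))
        A = build_multi_alignment([align_pair(r, target) for r in reads])
        consensus(A)
        annotate_states_and_support(A)
        for t in (MATCH, SUB, INS, DEL):
            total = A.total_state_counts[t]
            if total:
                assert A.column_state_counts[:, t].sum() == total
                assert np.isclose(
                    (A.column_state_counts[:, t] / total).sum(), 1.0
                )
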