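import math

import numpy as np
import pytest

from isoresolve import (
    CcsRead,
    SupportProfile,
    align_pair,
    build_multi_alignment,
    build_support_profile,
    candidate_pair_pvalue,
    read_error_probabilities,
    tail_bound,
    variant_positions,
    weighted_support,
)

from conftest import perfect_reads, random_seq


def _matrix_with_reference(read_seqs, c_seq, d_seq, quals=40):
    reads = [
        CcsRead(f"r{i}", s, [quals] * len(s)) for i, s in enumerate(read_seqs)
    ]
    A = build_multi_alignment(
        [align_pair(r.sequence, d_seq) for r in reads],
        row_ids=[r.read_id for r in reads],
        reference=align_pair(c_seq, d_seq),
    )
    return reads, A


class TestVariantPositions:
    def test_identical_candidates_no_variants(self):
        _, A = _matrix_with_reference(["ACGTACGT"], "ACGTACGT", "ACGTACGT")
        assert variant_positions(A).columns == []

    def test_substitution_plus_two_nt_deletion(self):
        d = "ACGTACGTAC"
        c = "ACTTACAC"  # sub at pos 2, 2-nt deletion of "GT" at 6-8
        _, A = _matrix_with_reference([d], c, d)
        assert len(variant_positions(A)) == 3

    def test_single_insertion_column(self):
        d = "ACGTACGT"
        c = "ACGTAACGT"  # 1-nt insertion
        _, A = _matrix_with_reference([d], c, d)
        assert len(variant_positions(A)) == 1

    def test_missing_reference_row_rejected(self):
        A = build_multi_alignment([align_pair("ACGT", "ACGT")])
        with pytest.raises(ValueError):
            variant_positions(A)


class TestReadErrorProbabilities:
    def test_phred40_substitution_specific_convention(self):
        d = "ACGTACGT"
        c = "ACTTACGT"  # substitution at column 2
        reads, A = _matrix_with_reference([d], c, d, quals=40)
        V = variant_positions(A)
        [p] = read_error_probabilities(reads[0], A, 0, V)
        assert p == pytest.approx(1e-4 / 3)

    def test_phred0_clamped_to_cap(self):
        d = "ACGTACGT"
        c = "ACTTACGT"
        reads, A = _matrix_with_reference([d], c, d, quals=0)
        V = variant_positions(A)
        # raw convention: 10^0 = 1.0 clamps to the 0.5 cap
        [p] = read_error_probabilities(reads[0], A, 0, V, p_convention="raw")
        assert p == 0.5
        # specific convention at a substitution divides by 3 first
        [p] = read_error_probabilities(reads[0], A, 0, V)
        assert p == pytest.approx(1 / 3)

    def test_raw_convention_no_division(self):
        d = "ACGTACGT"
        c = "ACTTACGT"
        reads, A = _matrix_with_reference([d], c, d, quals=40)
        V = variant_positions(A)
        [p] = read_error_probabilities(reads[0], A, 0, V, p_convention="raw")
        assert p == pytest.approx(1e-4)

    def test_read_gap_takes_min_flanking_quality(self):
        d = "ACGTACGT"
        c = "ACGACGT"  # deletion of T at column 3
        read = CcsRead("r0", "ACGACGT", [40, 40, 10, 30, 40, 40, 40])
        A = build_multi_alignment(
            [align_pair(read.sequence, d)],
            row_ids=["r0"],
            reference=align_pair(c, d),
        )
        V = variant_positions(A)
        [p] = read_error_probabilities(read, A, 0, V)
        # the read's gap at the variant column is flanked by Phred 10 and 30
        assert p == pytest.approx(10 ** (-10 / 10))


class TestWeightedSupport:
    def _profile(self, s, p):
        return SupportProfile(
            [f"r{i}" for i in range(len(s))],
            np.array(s, dtype=bool),
            np.log(np.array(p)),
        )

    def test_no_support_gives_unit_statistic(self):
        assert weighted_support(self._profile([0, 0, 0], [0.1, 0.2, 0.3])) == 1.0

    def test_product_of_inverse_probabilities(self):
        t = weighted_support(self._profile([1, 1, 0], [0.01, 0.1, 0.2]))
        assert t == pytest.approx(1000.0)

    def test_single_coin_flip_support(self):
        assert weighted_support(self._profile([1], [0.5])) == pytest.approx(2.0)


class TestTailBound:
    def _profile(self, s, p):
        return SupportProfile(
            [f"r{i}" for i in range(len(s))],
            np.array(s, dtype=bool),
            np.log(np.array(p)),
        )

    def test_insignificant_branch_returns_half(self):
        res = tail_bound(self._profile([0, 0, 0, 0], [0.4] * 4))
        assert res.p_value == 0.5

    def test_closed_form_frozen_value(self):
        res = tail_bound(self._profile([1, 1], [0.1, 0.1]))
        assert res.t == pytest.approx(100.0)
        assert res.t_prime == pytest.approx(2.0)
        assert res.mu == pytest.approx(0.2)
        assert res.delta == pytest.approx(10.0)
        # exp(0.2 * (10 - 11*ln 11))
        assert res.p_value == pytest.approx(0.0378, abs=2e-4)

    def test_shifted_delta_convention_is_larger(self):
        prof = self._profile([1, 1], [0.1, 0.1])
        printed = tail_bound(prof, delta_convention="printed").p_value
        shifted = tail_bound(prof, delta_convention="shifted").p_value
        assert shifted > printed  # bound applied at a lower threshold

    def test_lowering_a_support_probability_never_hurts(self):
        # fixed max_k(-log p_k) held by read 0; lower read 1's p
        base = None
        for p1 in (0.3, 0.1, 0.03, 0.011):
            res = tail_bound(self._profile([1, 1, 0], [0.01, p1, 0.3]))
            if base is not None:
                assert res.p_value <= base + 1e-15
            base = res.p_value

    def test_no_underflow_at_extreme_supports(self):
        n = 10_000
        s = np.zeros(n, dtype=bool)
        s[:50] = True
        log_p = np.full(n, math.log(1e-300))
        prof = SupportProfile([f"r{i}" for i in range(n)], s, log_p)
        res = tail_bound(prof)
        assert 0.0 < res.p_value < 1e-100
        assert math.isfinite(res.t_prime) and math.isfinite(res.mu)


class TestCandidatePairPvalue:
    def test_variant_cutoff_skips_evaluation(self, rng):
        d = random_seq(rng, 120)
        c = list(d)
        for i in range(0, 33, 3):  # 11 substitutions
            c[i] = "ACGT"[("ACGT".index(c[i]) + 1) % 4]
        c = "".join(c)
        reads = perfect_reads(d, 5)
        res = candidate_pair_pvalue(c, d, [], reads)
        assert res.skipped and res.p_value == 0.0 and res.n_variants == 11

    def test_small_clean_minority_is_significant(self, rng):
        d = random_seq(rng, 300)
        c = d[:150] + ("A" if d[150] != "A" else "C") + d[151:]
        reads_c = perfect_reads(c, 5, prefix="c", q=40)
        reads_d = perfect_reads(d, 300, prefix="d", q=40)
        res = candidate_pair_pvalue(c, d, reads_c, reads_d)
        assert res.p_value < 1e-10

    def test_single_weak_read_is_insignificant(self, rng):
        d = random_seq(rng, 200)
        c = d[:100] + ("A" if d[100] != "A" else "C") + d[101:]
        reads_c = perfect_reads(c, 1, prefix="c", q=1)  # near-coin-flip quality
        reads_d = perfect_reads(d, 50, prefix="d", q=1)
        res = candidate_pair_pvalue(c, d, reads_c, reads_d)
        assert res.p_value > 0.01

    def test_identical_candidates_rejected(self):
        with pytest.raises(ValueError):
            candidate_pair_pvalue("ACGT", "ACGT", [], perfect_reads("ACGT", 1))

    def test_no_reads_rejected(self):
        with pytest.raises(ValueError):
            candidate_pair_pvalue("ACGT", "ACTT", [], [])
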