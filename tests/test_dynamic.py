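"""Distribution probability, mutation matrix / future composition, and
pair predictability, each checked against independent oracles."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crystprop.dynamic import (
    MutationMatrix,
    OccupancyPattern,
    _expected_pair_fraction,
    build_mutation_matrix,
    distribution_probability,
    distribution_probability_bruteforce,
    distribution_vector,
    expected_pair_count,
    future_composition,
    pair_predictability,
    partition_boundaries,
    partition_occupancy,
)
from crystprop.sequences import AMINO_ACIDS, ProteinRecord


def integer_partitions(r, max_parts):
    """All multisets of positive integers summing to r with <= max_parts parts."""
    def gen(remaining, largest):
        if remaining == 0:
            yield ()
            return
        for first in range(min(remaining, largest), 0, -1):
            for rest in gen(remaining - first, first):
                yield (first,) + rest
    return [p for p in gen(r, r) if len(p) <= max_parts]


def occupancy_from_partition(parts, n):
    """Pad an integer partition with zeros to an n-hole occupancy vector."""
    return OccupancyPattern(tuple(parts) + (0,) * (n - len(parts)))


class TestPartitioning:
    @pytest.mark.parametrize(
        "positions, length, expected_occ",
        [
            ([1, 4, 6], 6, (1, 1, 1)),
            ([5], 122, (1,)),
            ([1, 2, 7], 7, (2, 0, 1)),  # lengths (3,2,2), longer first
        ],
    )
    def test_worked_examples(self, positions, length, expected_occ):
        assert partition_occupancy(positions, length).occ == expected_occ

    def test_boundaries_cover_sequence_with_near_equal_sizes(self):
        bounds = partition_boundaries(10, 3)
        assert bounds == [(1, 4), (5, 7), (8, 10)]
        sizes = [hi - lo + 1 for lo, hi in bounds]
        assert max(sizes) - min(sizes) <= 1

    def test_rejects_empty_and_out_of_range(self):
        with pytest.raises(ValueError):
            partition_occupancy([], 10)
        with pytest.raises(ValueError):
            partition_occupancy([0], 10)
        with pytest.raises(ValueError):
            partition_occupancy([11], 10)

    def test_pattern_invariants(self):
        p = OccupancyPattern((2, 0, 1))
        assert p.r == p.n == 3
        assert sum(p.q) == p.n
        assert sum(j * qj for j, qj in enumerate(p.q)) == p.r
        with pytest.raises(ValueError):
            OccupancyPattern((2, 2))  # sum != n


class TestDistributionProbability:
    @pytest.mark.parametrize(
        "occ, expected",
        [
            ((2, 1, 0), 18 / 27),        # table-style worked value 0.6667
            ((1,), 1.0),                 # singleton residue
            ((1, 1, 1), 6 / 27),
            ((3, 0, 0), 3 / 27),
            ((2, 2, 1, 1, 0, 0), 0.3472222222222222),
        ],
    )
    def test_closed_form_values(self, occ, expected):
        assert distribution_probability(OccupancyPattern(occ)) == \
            pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("r", range(1, 7))
    def test_oracle_equivalence_and_sum_to_one(self, r):
        """Formula matches exhaustive enumeration for every pattern with
        r <= 6, and the probabilities sum to 1 over occupancy multisets."""
        total = 0.0
        for parts in integer_partitions(r, r):
            pattern = occupancy_from_partition(parts, r)
            p_formula = distribution_probability(pattern)
            p_brute = distribution_probability_bruteforce(pattern)
            assert p_formula == pytest.approx(p_brute, abs=1e-12)
            total += p_formula
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_bruteforce_refuses_large_r(self):
        with pytest.raises(ValueError, match="r <= 8"):
            distribution_probability_bruteforce(OccupancyPattern((1,) * 9))

    def test_large_r_uses_exact_integer_arithmetic(self):
        # all 17 balls in one of 17 holes: q0=16, q17=1, so the pattern
        # probability is [17!/(16! 1!)] * [17!/17!] * 17**-17 = 17**-16
        p = distribution_probability(
            OccupancyPattern((17,) + (0,) * 16))
        assert p == pytest.approx(float(Fraction(17, 17**17)), rel=1e-14)


class TestDistributionVector:
    def test_singletons_map_to_one_and_absent_to_zero(self):
        r = ProteinRecord("p", "ACDEF")
        v = distribution_vector(r)
        present = [AMINO_ACIDS.index(a) for a in "ACDEF"]
        assert np.allclose(v[present], 1.0)
        absent = [i for i in range(20) if i not in present]
        assert np.allclose(v[absent], 0.0)

    def test_sensitive_to_residue_order(self):
        a = ProteinRecord("a", "AAKKAA")
        b = ProteinRecord("b", "AKAKAA")  # same composition, different order
        va, vb = distribution_vector(a), distribution_vector(b)
        assert not np.allclose(va, vb)


class TestMutationMatrix:
    def test_trp_single_codon_enumeration(self):
        # UGG's 9 mutants: R,R,G (pos1); stop,S,L (pos2); stop,C,C (pos3)
        m = build_mutation_matrix(stop_handling="exclude")
        assert m.prob("W", "R") == pytest.approx(2 / 7)
        assert m.prob("W", "G") == pytest.approx(1 / 7)
        assert m.prob("W", "C") == pytest.approx(2 / 7)
        assert m.prob("W", "W") == 0.0

    def test_met_to_ile(self):
        m = build_mutation_matrix()
        assert m.prob("M", "I") == pytest.approx(3 / 9)

    @pytest.mark.parametrize("stop_handling", ["exclude", "renormalize"])
    @pytest.mark.parametrize("synonymous", ["include", "exclude"])
    def test_rows_stochastic(self, stop_handling, synonymous):
        m = build_mutation_matrix(stop_handling, synonymous)
        assert np.allclose(m.probs.sum(axis=1), 1.0, atol=1e-12)

    def test_synonymous_exclude_zeroes_diagonal(self):
        m = build_mutation_matrix(synonymous="exclude")
        assert np.allclose(np.diag(m.probs), 0.0)

    def test_rejects_bad_shape(self):
        with pytest.raises(ValueError):
            MutationMatrix(np.ones((3, 3)))


class TestFutureComposition:
    def test_identity_matrix_returns_current_composition(self, simple_record):
        ident = MutationMatrix(np.eye(20))
        fc = future_composition(simple_record, ident)
        current = np.array([simple_record.counts[a] / simple_record.length
                            for a in AMINO_ACIDS])
        assert np.allclose(fc, 100 * current)

    def test_pure_trp_projects_matrix_row(self):
        r = ProteinRecord("w", "WWWW")
        fc = future_composition(r)
        assert fc[AMINO_ACIDS.index("R")] == pytest.approx(100 * 2 / 7)

    def test_conserves_total_mass(self, small_planted_dataset):
        for rec in small_planted_dataset.records[:10]:
            assert future_composition(rec).sum() == pytest.approx(100, abs=1e-9)


class TestExpectedPairCount:
    @pytest.mark.parametrize(
        "counts, x, y, expected",
        [
            ({"K": 17}, "K", "K", 2.23),   # 17/122 * 16/121 * 121
            ({"G": 7, "S": 8}, "G", "S", 0.46),
            ({"G": 0, "S": 8}, "G", "S", 0.0),
        ],
    )
    def test_worked_examples(self, counts, x, y, expected):
        assert round(expected_pair_count(counts, 122, x, y), 2) == expected

    def test_requires_length_two(self):
        with pytest.raises(ValueError):
            expected_pair_count({"A": 1}, 1, "A", "A")

    @given(counts=st.lists(st.integers(0, 60), min_size=20, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_conservation_sums_to_L_minus_1(self, counts):
        """Sum of expectations over the 400 ordered pair types is exactly
        L - 1 in rational arithmetic, for any composition."""
        L = sum(counts)
        if L < 2:
            return
        cmap = dict(zip(AMINO_ACIDS, counts))
        total = sum(
            _expected_pair_fraction(cmap, L, x, y)
            for x in AMINO_ACIDS for y in AMINO_ACIDS
        )
        assert total == Fraction(L - 1)

    def test_monotone_in_first_count(self):
        vals = [expected_pair_count({"A": r, "C": 5}, 200, "A", "C")
                for r in range(0, 60)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestPairPredictability:
    def test_exact_match_fully_predictable(self):
        _, p, u = pair_predictability(ProteinRecord("p", "AAAA"))
        assert (p, u) == (100.0, 0.0)

    def test_hand_enumerated_mixed_case(self):
        # AGAG: AG actual 2 vs predicted 1 (unpredictable, 2 pairs);
        # GA actual 1 vs predicted 1 (predictable, 1 pair)
        reports, p, u = pair_predictability(ProteinRecord("p", "AGAG"))
        assert p == pytest.approx(100 / 3)
        by_pair = {rep.pair: rep for rep in reports}
        assert by_pair[("A", "G")].actual == 2
        assert by_pair[("A", "G")].predicted == 1
        assert not by_pair[("A", "G")].predictable
        assert by_pair[("G", "A")].predictable

    def test_min_rule_credits_partial_overlap(self):
        _, p_strict, _ = pair_predictability(ProteinRecord("p", "AGAG"),
                                             rule="strict")
        _, p_min, _ = pair_predictability(ProteinRecord("p", "AGAG"),
                                          rule="min")
        # min rule credits 1 of the 2 AG pairs as predictable
        assert p_min == pytest.approx(200 / 3)
        assert p_min > p_strict

    @given(seq=st.text(alphabet="AGKV", min_size=2, max_size=100))
    @settings(max_examples=60, deadline=None)
    @pytest.mark.parametrize("rule", ["strict", "min"])
    def test_portions_sum_to_100_and_actuals_to_L_minus_1(self, rule, seq):
        rec = ProteinRecord("h", seq)
        reports, p, u = pair_predictability(rec, rule=rule)
        assert p + u == pytest.approx(100.0)
        assert sum(r.actual for r in reports) == rec.length - 1
        assert len(reports) == 400

    def test_rejects_single_residue(self):
        with pytest.raises(ValueError):
            pair_predictability(ProteinRecord("p", "A"))
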