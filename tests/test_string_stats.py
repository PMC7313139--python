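"""Containment probability, base-composition estimate and Z-score.

The recurrence is validated against two independent oracles: exhaustive
enumeration over all L-mers and a dynamic program on the KMP failure
automaton of the pattern.
"""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fsbc.string_stats as ss
from fsbc.sequence_io import pool_from_counts
from fsbc.string_stats import (
    AlphabetProbs,
    ScoreUndefinedError,
    border_set,
    containment_prob_table,
    count_containing_reads,
    estimate_base_probs,
    exact_containment_oracle,
    length_averaged_prob,
    score_string,
    substring_containment_counts,
    z_score,
)

UNIFORM = AlphabetProbs.uniform()
ACGT_STR = st.text(alphabet="ACGT", min_size=1, max_size=8)


def random_probs(rng: random.Random) -> AlphabetProbs:
    x = [rng.random() + 0.05 for _ in range(4)]
    total = sum(x)
    p = [v / total for v in x]
    p[3] = 1.0 - p[0] - p[1] - p[2]
    return AlphabetProbs(tuple(p))


class TestAlphabetProbs:
    def test_estimate_from_symmetric_pool(self):
        pool = pool_from_counts({"AC": 1, "GT": 1})
        assert estimate_base_probs(pool).p == (0.25, 0.25, 0.25, 0.25)

    def test_estimate_degenerate_pool(self):
        pool = pool_from_counts({"AAAA": 1})
        assert estimate_base_probs(pool).p == (1.0, 0.0, 0.0, 0.0)

    def test_estimate_weights_by_multiplicity(self):
        pool = pool_from_counts({"AAC": 2, "G": 1})
        p = estimate_base_probs(pool)
        assert p.p == (4 / 7, 2 / 7, 1 / 7, 0.0)

    def test_normalization_enforced(self):
        with pytest.raises(ValueError):
            AlphabetProbs((0.5, 0.5, 0.5, 0.5))

    @given(st.dictionaries(ACGT_STR, st.integers(1, 9), min_size=1, max_size=10))
    @settings(deadline=None, max_examples=50)
    def test_estimate_sums_to_one(self, counts):
        p = estimate_base_probs(pool_from_counts(counts))
        assert math.isclose(sum(p.p), 1.0, abs_tol=1e-12)


class TestBorderSet:
    @pytest.mark.parametrize(
        "s,expected",
        [
            ("ATATA", ["A", "ATA"]),
            ("GACTT", []),
            ("AAAA", ["A", "AA", "AAA"]),
            ("ATGATG", ["ATG"]),
            ("A", []),
        ],
    )
    def test_known_borders(self, s, expected):
        assert border_set(s) == expected

    def test_empty_string_rejected(self):
        with pytest.raises(ValueError):
            border_set("")

    @given(ACGT_STR)
    @settings(deadline=None, max_examples=100)
    def test_borders_are_proper_prefix_and_suffix(self, s):
        for t in border_set(s):
            assert 0 < len(t) < len(s)
            assert s.startswith(t) and s.endswith(t)


class TestContainmentRecurrence:
    def test_zero_below_pattern_length(self):
        table = containment_prob_table("ATATA", UNIFORM, 4)
        assert np.all(table == 0.0)

    def test_single_base_closed_form(self):
        table = containment_prob_table("A", UNIFORM, 2)
        assert table[2] == pytest.approx(1 - 0.75**2, abs=1e-15)

    def test_bordered_pair_hand_enumeration(self):
        # full enumeration of the 8 length-3 outcomes with p_A = 0.5
        probs = AlphabetProbs((0.5, 0.5 / 3, 0.5 / 3, 0.5 / 3))
        assert containment_prob_table("AA", probs, 3)[3] == pytest.approx(
            0.375, abs=1e-12
        )

    def test_impossible_string_gives_zero_table(self):
        probs = AlphabetProbs((0.5, 0.5, 0.0, 0.0))
        assert np.all(containment_prob_table("AGA", probs, 10) == 0.0)

    def test_at_pattern_length_equals_q(self):
        probs = AlphabetProbs((0.1, 0.2, 0.3, 0.4))
        table = containment_prob_table("ACG", probs, 3)
        assert table[3] == pytest.approx(0.1 * 0.2 * 0.3, abs=1e-15)

    @given(ACGT_STR, st.integers(0, 30))
    @settings(deadline=None, max_examples=60)
    def test_table_monotone_and_bounded(self, s, L_max):
        table = containment_prob_table(s, UNIFORM, L_max)
        assert np.all(table >= 0.0) and np.all(table <= 1.0)
        assert np.all(np.diff(table) >= -1e-15)

    def test_substring_dominates_superstring(self):
        sub = containment_prob_table("ACG", UNIFORM, 20)
        sup = containment_prob_table("TACGT", UNIFORM, 20)
        assert np.all(sub >= sup)


class TestOracles:
    def test_enumeration_examples(self):
        assert exact_containment_oracle("A", UNIFORM, 2, "enumerate") == pytest.approx(
            0.4375, abs=1e-15
        )
        # all 64 trinucleotides: AT occurs in 2*16 - 1 of them
        assert exact_containment_oracle("AT", UNIFORM, 3, "enumerate") == pytest.approx(
            0.125, abs=1e-15
        )

    def test_enumeration_refuses_large_l(self):
        with pytest.raises(ValueError):
            exact_containment_oracle("A", UNIFORM, 12, "enumerate")

    def test_methods_agree_and_match_recurrence(self):
        rng = random.Random(7)
        for _ in range(10):
            s = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 6)))
            probs = random_probs(rng)
            rec = containment_prob_table(s, probs, 8)
            enu = ss._enumeration_table(s, probs, 8)
            aut = ss._automaton_table(s, probs, 8)
            assert np.abs(enu - aut).max() < 1e-12
            assert np.abs(rec - enu).max() < 1e-10

    def test_impossible_string_zero(self):
        probs = AlphabetProbs((1.0, 0.0, 0.0, 0.0))
        assert exact_containment_oracle("AC", probs, 5, "automaton") == 0.0

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            exact_containment_oracle("A", UNIFORM, 3, "bogus")


class TestLengthAveraging:
    def test_constant_length_pool(self):
        pool = pool_from_counts({"ACGTACGTAC": 3, "TTGGCCAATT": 2})
        table = containment_prob_table("ACG", UNIFORM, pool.max_length)
        assert length_averaged_prob(table, pool) == pytest.approx(table[10])

    def test_weighted_mean_over_lengths(self):
        pool = pool_from_counts({"A" * 30: 3, "C" * 28: 1})
        table = containment_prob_table("GAT", UNIFORM, 30)
        expected = (3 * table[30] + table[28]) / 4
        assert length_averaged_prob(table, pool) == pytest.approx(expected)

    def test_all_reads_shorter_than_pattern(self):
        pool = pool_from_counts({"ACG": 2})
        table = containment_prob_table("ACGTT", UNIFORM, 3)
        assert length_averaged_prob(table, pool) == 0.0

    def test_short_table_rejected(self):
        pool = pool_from_counts({"ACGTACGT": 1})
        with pytest.raises(ValueError):
            length_averaged_prob([0.0] * 5, pool)


class TestContainmentCounting:
    def test_containment_not_occurrence(self):
        pool = pool_from_counts({"AAAA": 5})
        assert count_containing_reads("AA", pool) == 5

    def test_absent_string(self):
        pool = pool_from_counts({"AAAA": 5})
        assert count_containing_reads("GG", pool) == 0

    @given(st.dictionaries(st.text(alphabet="ACGT", min_size=4, max_size=10),
                           st.integers(1, 5), min_size=1, max_size=10),
           st.integers(1, 4))
    @settings(deadline=None, max_examples=50)
    def test_batch_counts_match_per_string_scan(self, counts, length):
        pool = pool_from_counts(counts)
        batch = substring_containment_counts(pool, length)
        for s, F in batch.items():
            assert F == count_containing_reads(s, pool)
        # completeness: every contained substring of that length is present
        for seq in pool.sequences():
            for i in range(len(seq) - length + 1):
                assert seq[i: i + length] in batch


class TestZScore:
    def test_zero_when_observed_matches_expected(self):
        assert z_score(5, 10, 0.5) == pytest.approx(0.0)

    def test_enriched_string(self):
        # direct arithmetic: (0.1 - 0.05)/sqrt(0.05*0.95/100)
        assert z_score(10, 100, 0.05) == pytest.approx(2.2941573387, abs=1e-9)

    def test_depleted_string(self):
        assert z_score(0, 4, 0.5) == pytest.approx(-2.0)

    def test_degenerate_probability_raises(self):
        with pytest.raises(ScoreUndefinedError):
            z_score(1, 10, 0.0)
        with pytest.raises(ScoreUndefinedError):
            z_score(1, 10, 1.0)

    @given(st.integers(0, 50), st.integers(1, 50),
           st.floats(0.01, 0.99))
    @settings(deadline=None, max_examples=100)
    def test_sign_matches_enrichment(self, F, N, P):
        F = min(F, N)
        z = z_score(F, N, P)
        if F / N > P:
            assert z > 0
        elif F / N < P:
            assert z < 0


def test_score_string_profile_consistency():
    pool = pool_from_counts({"ACGTACGTAC": 4, "TTTTTTTTTT": 1})
    profile = score_string("ACGT", pool)
    assert profile.F == 4
    assert profile.Q == pytest.approx(
        math.prod(estimate_base_probs(pool)[b] for b in "ACGT")
    )
    assert profile.Z == pytest.approx(
        z_score(profile.F, pool.n_reads, profile.P)
    )
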