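import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualindex.compatibility import (
    DistanceParams,
    SelectionError,
    filter_against_existing,
    hamming,
    is_self_priming,
    levenshtein,
    min_pairwise_distance,
    reverse_complement,
    select_mutually_distant,
)

from _oracles import lev_dp, naive_self_priming, revcomp

dna = st.text(alphabet="ACGT", min_size=1, max_size=16)


def random_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a,b,d",
        [
            ("ACGTACGT", "ACGTACGT", 0),
            ("ACGT", "AGT", 1),
            ("AAAA", "TTTT", 4),
            ("ACGT", "", 4),
        ],
    )
    def test_examples(self, a, b, d):
        assert levenshtein(a, b) == d

    def test_against_dp_oracle_1000_pairs(self):
        """Edit distance agrees with a quadratic DP oracle on 1000 random
        pairs of lengths 4-16."""
        rng = random.Random(99)
        for _ in range(1000):
            a = random_dna(rng, rng.randint(4, 16))
            b = random_dna(rng, rng.randint(4, 16))
            assert levenshtein(a, b) == lev_dp(a, b)

    @given(dna, dna)
    @settings(max_examples=200, deadline=None)
    def test_symmetry_and_identity(self, a, b):
        assert levenshtein(a, b) == levenshtein(b, a)
        assert (levenshtein(a, b) == 0) == (a == b)

    @given(st.integers(4, 12).flatmap(
        lambda n: st.tuples(
            st.text(alphabet="ACGT", min_size=n, max_size=n),
            st.text(alphabet="ACGT", min_size=n, max_size=n),
        )
    ))
    @settings(max_examples=200, deadline=None)
    def test_bounded_by_hamming(self, pair):
        a, b = pair
        assert levenshtein(a, b) <= hamming(a, b)


class TestHamming:
    @pytest.mark.parametrize(
        "a,b,d",
        [("ACGT", "ACGT", 0), ("AAAA", "AAAT", 1), ("ACGTACGT", "TGCATGCA", 8)],
    )
    def test_examples(self, a, b, d):
        assert hamming(a, b) == d

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal lengths"):
            hamming("ACGT", "ACG")


class TestReverseComplement:
    @pytest.mark.parametrize("s,rc", [("ACGT", "ACGT"), ("AAAA", "TTTT"), ("GATC", "GATC"), ("AACG", "CGTT")])
    def test_examples(self, s, rc):
        assert reverse_complement(s) == rc

    @given(dna)
    @settings(max_examples=200, deadline=None)
    def test_involution(self, s):
        assert reverse_complement(reverse_complement(s)) == s

    def test_invalid_characters(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGN")


class TestExistingExclusion:
    def test_identical_removed(self):
        assert filter_against_existing(["AAACCGTT"], ["AAACCGTT"]) == []

    def test_empty_existing_is_noop(self):
        assert filter_against_existing(["AAACCGTT"], []) == ["AAACCGTT"]

    def test_distance_exactly_three_kept(self):
        # "within 3" removes at distance <= 2; exactly 3 survives
        a, b = "AAAAAAAA", "AAAAATTT"
        assert levenshtein(a, b) == 3
        assert filter_against_existing([a], [b]) == [a]
        c = "AAAAAATT"
        assert levenshtein(a, c) == 2
        assert filter_against_existing([c], [a]) == []

    def test_brute_force_oracle(self):
        """100 random candidates against 10 random existing indexes match
        an all-pairs DP check."""
        rng = random.Random(5)
        cands = [random_dna(rng, 8) for _ in range(100)]
        existing = [random_dna(rng, 8) for _ in range(10)]
        got = filter_against_existing(cands, existing, 3)
        expected = [
            c for c in cands if all(lev_dp(c, e) >= 3 for e in existing)
        ]
        assert got == expected

    def test_unequal_length_existing_supported(self):
        # existing set may have a different index length than candidates
        got = filter_against_existing(["ACGTACGT"], ["ACGTACGTAA"], 3)
        assert got == []  # distance 2 (two insertions)


class TestSelection:
    def test_greedy_trace(self):
        got = select_mutually_distant(
            ["AAACCGTT", "AAACCGTA", "TTGGCACA"], 3, 2, shuffle=False
        )
        assert got == ["AAACCGTT", "TTGGCACA"]

    def test_single_required(self):
        got = select_mutually_distant(["AAACCGTT", "AAACCGTA"], 3, 1, shuffle=False)
        assert got == ["AAACCGTT"]

    def test_shortfall_raises_with_counts(self):
        with pytest.raises(SelectionError, match="only 1 of the required 5"):
            select_mutually_distant(["AAACCGTT", "AAACCGTA"], 3, 5)

    def test_seed_determinism_and_pairwise_guarantee(self):
        rng = random.Random(11)
        pool = list({random_dna(rng, 8) for _ in range(400)})
        a = select_mutually_distant(pool, 3, 20, seed=7)
        b = select_mutually_distant(pool, 3, 20, seed=7)
        assert a == b
        assert min_pairwise_distance(a) >= 3

    def test_union_with_existing_stays_distant(self):
        """After both filters, selected plus existing indexes are all
        mutually separated by the smaller of the two thresholds."""
        rng = random.Random(21)
        params = DistanceParams()
        existing = [random_dna(rng, 8) for _ in range(5)]
        pool = list({random_dna(rng, 8) for _ in range(500)})
        surv = filter_against_existing(pool, existing, params.min_dist_existing)
        chosen = select_mutually_distant(surv, params.min_dist_internal, 10, seed=2)
        floor = min(params.min_dist_existing, params.min_dist_internal)
        for i, a in enumerate(chosen + existing):
            for b in (chosen + existing)[i + 1 :]:
                if a in existing and b in existing:
                    continue  # the user's own set carries no guarantee
                assert levenshtein(a, b) >= floor


class TestSelfPriming:
    FLANK5 = "CAAGCAGAAGACGGCATACGAGAT"
    FLANK3 = "GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT"

    def test_planted_revcomp_hit(self):
        # index made equal to the revcomp of the 3'-terminal 8-mer: Hamming 0
        probe_source = self.FLANK3[-8:]
        index = revcomp(probe_source)
        full = self.FLANK5 + index + self.FLANK3
        i0 = len(self.FLANK5)
        assert is_self_priming(full, i0, i0 + 8) is True

    def test_distant_windows_pass(self):
        full = self.FLANK5 + "AACCGGTT" + self.FLANK3
        i0 = len(self.FLANK5)
        probe = revcomp(full[-8:])
        all_far = all(
            sum(x != y for x, y in zip(probe, full[s : s + 8])) >= 3
            for s in range(i0 - 7, i0 + 8)
        )
        assert is_self_priming(full, i0, i0 + 8) is (not all_far)

    def test_brute_force_enumerator_50_constructions(self):
        """Screening decisions match an exhaustive overlapping-window
        enumerator on 50 random primer constructions."""
        rng = random.Random(3)
        for _ in range(50):
            f5 = random_dna(rng, rng.randint(8, 24))
            f3 = random_dna(rng, rng.randint(8, 24))
            idx = random_dna(rng, 8)
            full = f5 + idx + f3
            i0, i1 = len(f5), len(f5) + 8
            assert is_self_priming(full, i0, i1) == naive_self_priming(full, i0, i1)

    def test_invariant_outside_scanned_windows(self):
        """Bases 5' of the scanned windows cannot change the decision."""
        rng = random.Random(8)
        f3 = random_dna(rng, 20)
        idx = random_dna(rng, 8)
        for f5a, f5b in [(random_dna(rng, 20), random_dna(rng, 20)) for _ in range(10)]:
            # same suffix near the index so the scanned windows are identical
            f5b = f5b[:-7] + f5a[-7:]
            full_a, full_b = f5a + idx + f3, f5b + idx + f3
            ra = is_self_priming(full_a, len(f5a), len(f5a) + 8)
            rb = is_self_priming(full_b, len(f5b), len(f5b) + 8)
            assert ra == rb

    def test_window_longer_than_primer_rejected(self):
        with pytest.raises(ValueError, match="window"):
            is_self_priming("ACGT", 0, 2, window=8)

    def test_invalid_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            is_self_priming("ACGTACGTACGT", 10, 8)


class TestDistanceParams:
    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            DistanceParams(min_dist_existing=0)
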