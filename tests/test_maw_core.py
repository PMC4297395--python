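import itertools

import pytest
from hypothesis import given, settings, strategies as st

from mawkit import (
    Alphabet,
    IndexedWord,
    IntervalTable,
    LcpStack,
    LetterSet,
    MawTuple,
    PrecedingSets,
    bottom_up_pass,
    brute_force_maws,
    compute_maw_strings,
    compute_maws,
    decode_tuple,
    emit_maws,
    enumerate_factor_pairs,
    reverse_complement,
    top_down_pass,
)
from mawkit.oracle import RandomWordSpec, preceding_letter_sets, random_words

AB = Alphabet(("A", "B"))


def run_passes(text, alphabet=None):
    """Index a word and run both sweeps; returns (ix, completed sets)."""
    if alphabet is None:
        alphabet = Alphabet.from_text(text)
    ix = IndexedWord.build(alphabet.encode(text))
    all_letters = 0
    for c in set(text):
        all_letters |= 1 << alphabet.index[c]
    sets = PrecedingSets(len(ix), alphabet.size, all_letters)
    interval = IntervalTable(int(ix.lcp.max()) + 2)
    down = LcpStack()
    top_down_pass(ix, sets, interval, down)
    interval.reset()
    up = LcpStack()
    bottom_up_pass(ix, sets, interval, up)
    return ix, sets, down, up


class TestLetterSet:
    def test_membership_insert_difference(self):
        s = LetterSet(4)
        s.add(1)
        s.add(3)
        assert 1 in s and 3 in s and 0 not in s
        t = LetterSet(4)
        t.add(3)
        assert sorted(s.difference(t)) == [1]
        assert len(s) == 2
        s.clear()
        assert len(s) == 0


class TestEnumerateFactorPairs:
    def test_worked_example_rank0(self, worked_word):
        ix = IndexedWord.build(AB.encode(worked_word))
        pairs = dict((j, (start, length)) for j, start, length in enumerate_factor_pairs(ix))
        assert pairs[0] == (0, 1)  # S_0 = "A"
        assert pairs[1] == (0, 2)  # S_1 = "AA"

    def test_all_single_letters_when_lcp_zero(self):
        ix = IndexedWord.build(AB.encode("AB"))
        got = list(enumerate_factor_pairs(ix))
        assert got == [(0, 0, 1), (1, 0, 1), (2, 1, 1), (3, 1, 1)]

    def test_overrunning_pair_skipped(self):
        # ABAB: SA=[2,0,3,1], LCP=[0,2,0,1]; at rank 0 the odd factor would
        # need length LCP[1]+1 = 3 > suffix length 2.
        ix = IndexedWord.build(AB.encode("ABAB"))
        ids = {j for j, _, _ in enumerate_factor_pairs(ix)}
        assert 1 not in ids
        assert 0 in ids and 2 in ids

    def test_even_factors_never_overrun(self):
        for text in ("AAA", "ABAB", "AABABABB", "BBBBA"):
            ix = IndexedWord.build(AB.encode(text))
            for j, start, length in enumerate_factor_pairs(ix):
                assert length <= len(text) - start


class TestPasses:
    def test_completed_sets_match_definition_oracle(self):
        for spec in (
            RandomWordSpec(sigma=2, min_len=1, max_len=40, seed=11, count=40),
            RandomWordSpec(sigma=4, min_len=1, max_len=60, seed=12, count=30),
            RandomWordSpec(sigma=1, min_len=1, max_len=10, seed=13, count=10),
        ):
            for text in random_words(spec):
                alphabet = Alphabet.from_text(text)
                ix, sets, _, _ = run_passes(text, alphabet)
                for j, start, length in enumerate_factor_pairs(ix):
                    factor = text[start : start + length]
                    b1, b2 = preceding_letter_sets(text, factor)
                    got_b1 = {alphabet.letters[a] for a in sets.b1_set(j)}
                    got_b2 = {alphabet.letters[a] for a in sets.b2_set(j)}
                    assert got_b1 == b1, (text, j, factor)
                    assert got_b2 == b2, (text, j, factor)

    def test_top_down_partials_are_subsets_of_completed_sets(self):
        text = "AABABABB"
        ix = IndexedWord.build(AB.encode(text))
        sets_td = PrecedingSets(len(ix), 2, 0b11)
        interval = IntervalTable(int(ix.lcp.max()) + 2)
        top_down_pass(ix, sets_td, interval, LcpStack())
        _, sets_full, _, _ = run_passes(text, AB)
        for j in range(2 * len(ix)):
            assert sets_td.b1[j] & ~sets_full.b1[j] == 0
            assert sets_td.b2[j] & ~sets_full.b2[j] == 0

    def test_single_letter_word_has_no_preceding_letters_in_b1(self):
        _, sets, _, _ = run_passes("A")
        assert sets.b1[0] == 0 and sets.b1[1] == 0

    def test_b1_subset_of_b2_after_completion(self):
        for text in ("AABABABB", "ABAB", "AAAA", "ACGTACGGT"):
            ix, sets, _, _ = run_passes(text)
            for j, _, _ in enumerate_factor_pairs(ix):
                assert sets.b1[j] & ~sets.b2[j] == 0

    def test_at_most_one_push_per_rank(self):
        spec = RandomWordSpec(sigma=3, min_len=1, max_len=120, seed=21, count=30)
        for text in random_words(spec):
            ix, _, down, up = run_passes(text)
            assert down.pushes <= len(ix)
            assert up.pushes <= len(ix)


class TestEmission:
    def test_worked_example_full_set(self, worked_word, worked_maws):
        assert set(compute_maw_strings(worked_word)) == worked_maws
        assert len(compute_maws(worked_word)) == 7

    def test_in_text_example_aabb(self, worked_word):
        # A·AB and AB·B occur but A·AB·B does not
        assert "AABB" in compute_maw_strings(worked_word)

    def test_length_range_filter(self, worked_word):
        assert compute_maw_strings(worked_word, min_len=4, max_len=4) == ["AABB"]
        assert compute_maw_strings(worked_word, min_len=3, max_len=3) == [
            "AAA", "BAA", "BBA", "BBB",
        ]
        assert compute_maw_strings(worked_word, min_len=25, max_len=25) == []

    @pytest.mark.parametrize(
        "text, expected",
        [
            ("AB", {"AA", "BA", "BB"}),
            ("AAAA", {"AAAAA"}),
            ("A", {"AA"}),
            ("ABAB", {"AA", "BB", "BABA"}),
        ],
    )
    def test_small_words(self, text, expected):
        assert set(compute_maw_strings(text)) == expected

    def test_no_duplicate_tuples(self, worked_word):
        tuples = compute_maws(worked_word)
        decoded = [decode_tuple(worked_word, t) for t in tuples]
        assert len(decoded) == len(set(decoded))

    def test_parameter_validation(self, worked_word):
        with pytest.raises(ValueError):
            compute_maws(worked_word, min_len=1)
        with pytest.raises(ValueError):
            compute_maws(worked_word, min_len=4, max_len=3)
        with pytest.raises(ValueError):
            compute_maws("")

    def test_emit_requires_completed_sets_interface(self, worked_word):
        ix, sets, _, _ = run_passes(worked_word, AB)
        tuples = emit_maws(ix, sets, AB, worked_word)
        assert {decode_tuple(worked_word, t) for t in tuples} == {
            "AAA", "AABABB", "AABB", "BAA", "BABABA", "BBA", "BBB",
        }


class TestDecodeTuple:
    def test_worked_example_tuples(self, worked_word):
        assert decode_tuple(worked_word, MawTuple("A", 5, 7)) == "AABB"
        assert decode_tuple(worked_word, MawTuple("B", 6, 7)) == "BBB"
        assert decode_tuple(worked_word, MawTuple("A", 2, 2)) == "AB"

    def test_out_of_bounds_interval_rejected(self):
        with pytest.raises(IndexError):
            decode_tuple("AB", MawTuple("A", 1, 2))


class TestEquivalenceWithOracle:
    def test_exhaustive_binary_words(self):
        for length in range(1, 11):
            for tup in itertools.product("AB", repeat=length):
                text = "".join(tup)
                assert set(compute_maw_strings(text, AB)) == brute_force_maws(text, AB), text

    @pytest.mark.parametrize("sigma", [1, 2, 3, 4])
    def test_random_words(self, sigma):
        spec = RandomWordSpec(sigma=sigma, min_len=1, max_len=150, seed=30 + sigma, count=50)
        for text in random_words(spec):
            assert set(compute_maw_strings(text)) == brute_force_maws(text), text

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(st.text(alphabet="ABC", min_size=1, max_size=50))
    def test_property_equivalence(self, text):
        assert set(compute_maw_strings(text)) == brute_force_maws(text)


class TestGlobalProperties:
    def test_soundness_every_output_is_a_maw(self):
        spec = RandomWordSpec(sigma=4, min_len=2, max_len=200, seed=44, count=25)
        for text in random_words(spec):
            for x in compute_maw_strings(text):
                assert x not in text
                assert x[:-1] in text and x[1:] in text

    def test_cardinality_bound(self):
        spec = RandomWordSpec(sigma=4, min_len=1, max_len=300, seed=45, count=25)
        for text in random_words(spec):
            sigma = len(set(text))
            assert len(compute_maws(text)) <= sigma * (len(text) + 1)

    def test_strand_symmetry(self):
        alphabet = Alphabet(("A", "C", "G", "T"))
        spec = RandomWordSpec(sigma=4, min_len=2, max_len=200, seed=46, count=25)
        for text in random_words(spec):
            dna = text.translate(str.maketrans("ABCD", "ACGT"))
            fwd = set(compute_maw_strings(dna, alphabet))
            rev = set(compute_maw_strings(reverse_complement(dna), alphabet))
            assert {reverse_complement(x) for x in fwd} == rev

    def test_determinism(self, worked_word):
        assert compute_maws(worked_word) == compute_maws(worked_word)
        a = compute_maw_strings("ACGGTACCGTTAAC")
        b = compute_maw_strings("ACGGTACCGTTAAC")
        assert a == b
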