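"""Pattern doubling, rotations and the pigeonhole fragment partition."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circmatch.core import (
    InvalidInputError,
    Sequence,
    ThresholdTooLargeError,
    double_pattern,
    min_intact_fragments,
    pigeonhole_fragment_count,
    rotations,
    split_fragments,
)

patterns = st.text(alphabet="ab", min_size=1, max_size=30)


@pytest.mark.parametrize("x, expected", [
    ("GGGTCTA", "GGGTCTAGGGTCT"),
    ("a", "a"),
    ("abc", "abcab"),
])
def test_double_pattern(x, expected):
    assert double_pattern(Sequence(x)).doubled == expected


def test_double_pattern_rejects_empty():
    with pytest.raises(InvalidInputError):
        Sequence("")


def test_rotations_enumeration():
    assert rotations(Sequence("abababbc")) == [
        "abababbc", "bababbca", "ababbcab", "babbcaba",
        "abbcabab", "bbcababa", "bcababab", "cabababb"]
    assert rotations(Sequence("aaaa")) == ["aaaa"] * 4
    assert rotations(Sequence("GGGTCTA"))[4] == "CTAGGGT"


@pytest.mark.parametrize("f, expected", [
    (4, ["GGGT", "CTA", "GGG", "TCT"]),
    (6, ["GGG", "TC", "TA", "GG", "GT", "CT"]),
    (13, list("GGGTCTAGGGTCT")),
])
def test_split_fragments_worked_partitions(f, expected):
    d = split_fragments(double_pattern(Sequence("GGGTCTA")), f)
    assert [s for s, _ in d.fragment_strings()] == expected


def test_split_fragments_too_many():
    d = double_pattern(Sequence("GGGTCTA"))  # length 13
    with pytest.raises(ThresholdTooLargeError):
        split_fragments(d, 14)


@given(patterns, st.integers(min_value=1, max_value=20))
@settings(deadline=None)
def test_split_fragments_cover_and_balance(letters, f):
    d = double_pattern(Sequence(letters))
    L = len(d.doubled)
    if f > L:
        with pytest.raises(ThresholdTooLargeError):
            split_fragments(d, f)
        return
    d = split_fragments(d, f)
    pieces = [s for s, _ in d.fragment_strings()]
    assert "".join(pieces) == d.doubled
    lengths = {len(p) for p in pieces}
    assert lengths <= {L // f, -(-L // f)}
    assert all(len(p) >= 1 for p in pieces)


@given(patterns)
@settings(deadline=None)
def test_every_length_m_factor_of_doubled_is_a_rotation(letters):
    x = Sequence(letters)
    m = len(x)
    d = double_pattern(x)
    rots = set(rotations(x))
    factors = {d.doubled[i:i + m] for i in range(len(d.doubled) - m + 1)}
    assert factors == rots


def _all_patterns(sigma, m):
    alphabet = "abcd"[:sigma]
    return ("".join(p) for p in itertools.product(alphabet, repeat=m))


@pytest.mark.parametrize("sigma, m", [(2, 8), (2, 12), (4, 5)])
def test_four_fragments_pigeonhole(sigma, m):
    """Every length-m factor of x' contains one of the 4 fragments intact."""
    for letters in itertools.islice(_all_patterns(sigma, m), 300):
        d = split_fragments(double_pattern(Sequence(letters)), 4)
        for i in range(len(d.doubled) - m + 1):
            factor_span = range(i, i + m)
            assert any(f.start in factor_span and (f.end - 1) in factor_span
                       for f in d.fragments), (letters, i)


@pytest.mark.parametrize("sigma, m, k", [(2, 6, 1), (2, 10, 2), (4, 7, 1)])
def test_chosen_partition_survives_k_mismatches(sigma, m, k):
    """For any k positions struck out of any length-m factor of x', at least
    one fragment inside the factor avoids all of them."""
    f = pigeonhole_fragment_count(m, k)
    for letters in itertools.islice(_all_patterns(sigma, m), 50):
        d = split_fragments(double_pattern(Sequence(letters)), f)
        for i in range(len(d.doubled) - m + 1):
            inside = [frag for frag in d.fragments
                      if i <= frag.start and frag.end <= i + m]
            assert len(inside) >= k + 1, "pigeonhole guarantee"
            for struck in itertools.combinations(range(i, i + m), k):
                assert any(all(not (frag.start <= s < frag.end) for s in struck)
                           for frag in inside)


@pytest.mark.parametrize("m", range(4, 40))
@pytest.mark.parametrize("k", range(0, 6))
def test_fragment_count_gives_pigeonhole_budget(m, k):
    """The chosen fragment count leaves >= k+1 whole fragments in every
    length-m window of x', and never fewer fragments than 2k+4."""
    if 2 * k + 4 > 2 * m - 1:
        with pytest.raises(ThresholdTooLargeError):
            pigeonhole_fragment_count(m, k)
        return
    f = pigeonhole_fragment_count(m, k)
    assert f >= 2 * k + 4
    d = split_fragments(double_pattern(Sequence("A" * m)), f)
    assert min_intact_fragments(d) >= k + 1


def test_rounding_corner_case_needs_extra_fragments():
    # m=8, k=3: the 10 equal fragments of a 15-letter x' (lengths 2 and 1)
    # leave a window with only 3 < k+1 whole fragments, so the count must
    # grow for the filtration to stay lossless.
    d = split_fragments(double_pattern(Sequence("A" * 8)), 10)
    assert min_intact_fragments(d) < 4
    f = pigeonhole_fragment_count(8, 3)
    assert f > 10
    d2 = split_fragments(double_pattern(Sequence("A" * 8)), f)
    assert min_intact_fragments(d2) >= 4
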