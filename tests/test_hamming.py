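"""ECSMF / ACSMF / ACSMF-Simple against worked values and the brute force."""

import random

import pytest

from circmatch.automaton import FragmentOccurrence
from circmatch.core import (
    InvalidInputError,
    Sequence,
    ThresholdTooLargeError,
    double_pattern,
)
from circmatch.hamming import (
    acsmf_extensions,
    acsmf_search,
    ecsmf_search,
    extend_simple,
    report_window,
)
from circmatch.oracle import oracle_hamming
from circmatch.synth import random_text

from .conftest import PATTERN, TEXT


def _ext_for(pattern, text, k, tup, variant):
    for occ, ext in acsmf_extensions(pattern, text, k, variant=variant):
        if (occ.p_xprime, occ.length, occ.p_t) == tup:
            return occ, ext
    raise AssertionError(f"tuple {tup} not produced by filtration")


@pytest.mark.parametrize("variant", ["lce", "simple"])
def test_exact_extension_of_worked_tuple(pattern, text, variant):
    # fragment CTA at x' offset 4 hits t at 10; El = 0, Er = 4, no marks
    _, ext = _ext_for(pattern, text, 0, (4, 3, 10), variant)
    assert (ext.left, ext.right) == (0, 4)
    assert not any(ext.marks)


@pytest.mark.parametrize("variant", ["lce", "simple"])
def test_k1_extension_of_worked_tuple(pattern, text, variant):
    # fragment GT at x' offset 9 hits t at 15; El^k = 6, Er^k = 1,
    # mismatches consumed at x' offsets 3 and 11
    _, ext = _ext_for(pattern, text, 1, (9, 2, 15), variant)
    assert (ext.left, ext.right) == (6, 1)
    assert [i for i, v in enumerate(ext.marks) if v] == [3, 11]


def test_k1_worked_tuple_reports_positions_10_and_11(pattern, text):
    occ, ext = _ext_for(pattern, text, 1, (9, 2, 15), "lce")
    got = report_window(occ, ext, len(pattern), len(text), 1)
    assert [(cm.position, cm.distance) for cm in got] == [(10, 0), (11, 1)]
    assert [cm.rotation for cm in got] == [4, 5]


def test_exact_worked_tuple_reports_position_10(pattern, text):
    occ, ext = _ext_for(pattern, text, 0, (4, 3, 10), "lce")
    got = report_window(occ, ext, len(pattern), len(text), 0)
    assert [(cm.position, cm.rotation, cm.distance) for cm in got] == [(10, 4, 0)]


def test_short_extension_reports_nothing(pattern, text):
    occ, ext = _ext_for(pattern, text, 0, (0, 4, 13), "lce")
    if ext.left + occ.length + ext.right < len(pattern):
        assert report_window(occ, ext, len(pattern), len(text), 0) == []


def test_extension_capped_at_text_end():
    x = Sequence("ABCDE")
    t = Sequence("XXXXXXXXXBCDE")  # fragment occurrence touching t's end
    occ = FragmentOccurrence(p_t=9, p_xprime=1, length=4)
    ext = extend_simple(double_pattern(x).doubled, t.letters, occ, 1)
    assert ext.right == 0
    assert not any(ext.marks[occ.p_xprime + occ.length:]), \
        "a string boundary is not a mismatch"


def test_ecsmf_worked_example(pattern, text):
    got = ecsmf_search(pattern, text)
    assert [(cm.position, cm.rotation, cm.distance) for cm in got] == [(10, 4, 0)]


def test_ecsmf_overlapping_trivial_pattern():
    got = ecsmf_search(Sequence("aa"), Sequence("aaaa"))
    assert [cm.position for cm in got] == [0, 1, 2]


def test_acsmf_worked_example_k1(pattern, text):
    got = acsmf_search(pattern, text, 1)
    assert got == oracle_hamming(pattern, text, 1)
    by_pos = {cm.position: cm.distance for cm in got}
    assert by_pos[10] == 0 and by_pos[11] == 1
    assert max(by_pos) == 11


def test_acsmf_k0_equals_ecsmf(pattern, text):
    assert acsmf_search(pattern, text, 0) == ecsmf_search(pattern, text)


def test_threshold_too_large_raises():
    with pytest.raises(ThresholdTooLargeError):
        acsmf_search(Sequence("GGGTCTA"), Sequence(TEXT), 6)  # 2k+4 = 16 > 13


def test_text_shorter_than_pattern_raises():
    with pytest.raises(InvalidInputError):
        acsmf_search(Sequence("GGGTCTA"), Sequence("GGGT"), 1)


def test_tiny_pattern_falls_back_to_brute_force():
    x, t = Sequence("ab"), Sequence("abbaabz")
    assert ecsmf_search(x, t) == oracle_hamming(x, t, 0)


def _random_instance(rng, sigma, m, n):
    alphabet = "abcdefghijklmnopqrstuvwxyz"[:sigma]
    x = Sequence("".join(rng.choice(alphabet) for _ in range(m)))
    t = Sequence("".join(rng.choice(alphabet) for _ in range(n)))
    return x, t


@pytest.mark.parametrize("sigma", [2, 4])
@pytest.mark.parametrize("k", [0, 1, 2, 3])
def test_variants_and_oracle_agree_on_random_instances(sigma, k):
    rng = random.Random(1000 * sigma + k)
    for _ in range(12):
        m = rng.randint(max(4, k + 3), 20)
        if 2 * k + 4 > 2 * m - 1:
            continue
        n = rng.randint(m + 1, 200)
        x, t = _random_instance(rng, sigma, m, n)
        expected = oracle_hamming(x, t, k)
        assert acsmf_search(x, t, k, variant="simple") == expected
        assert acsmf_search(x, t, k, variant="lce") == expected


def test_all_rotations_mode_matches_oracle_triples():
    rng = random.Random(7)
    for _ in range(5):
        x, t = _random_instance(rng, 2, 6, 60)
        got = acsmf_search(x, t, 2, all_rotations=True)
        assert got == oracle_hamming(x, t, 2, all_rotations=True)


def test_match_sets_grow_with_k(pattern, text):
    prev: set[int] = set()
    for k in range(4):
        cur = {cm.position for cm in acsmf_search(pattern, text, k)}
        assert prev <= cur
        prev = cur


def test_reported_distance_is_true_window_distance():
    rng = random.Random(11)
    from circmatch.core import rotations
    from circmatch.oracle import hamming_distance
    for _ in range(10):
        x, t = _random_instance(rng, 4, 8, 120)
        for cm in acsmf_search(x, t, 2, all_rotations=True):
            window = t.letters[cm.position:cm.position + len(x)]
            assert hamming_distance(window, rotations(x)[cm.rotation]) == cm.distance


def test_simple_variant_mean_comparisons_below_three():
    """On uniform random data each extension run should inspect < 3 letters
    on average (expected matching prefix of two random strings < 2)."""
    total = attempts = 0
    for seed in range(30):
        x = random_text(9, 4, seed=seed + 500, id="x")
        t = random_text(5000, 4, seed=seed, id="t")
        for _, ext in acsmf_extensions(x, t, 1, variant="simple"):
            total += sum(ext.comparisons)
            attempts += len(ext.comparisons)
    assert attempts > 2000
    assert total / attempts < 3
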