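"""Circular string matching under the Hamming model.

Three filter-and-verify algorithms over a pattern ``x`` (length ``m``) and a
text ``t`` (length ``n``):

* ``ecsmf_search`` — exact matching.  The doubled pattern ``x'`` is cut into
  4 fragments, each fragment is located exactly in ``t`` with one
  Aho-Corasick pass, and every hit is extended left and right with
  longest-common-extension (lce) queries on suffix-array indexes of
  ``x' # t`` and of the reversed concatenation.  A hit whose full extension
  reaches length ``m`` certifies occurrences of rotations of ``x``.

* ``acsmf_search`` (``variant="lce"``) — matching with at most ``k``
  mismatches.  Same filtration with ``2k + 4`` fragments (a notch more when
  rounding would leave a window with fewer than ``k + 1`` whole fragments);
  each hit is extended ``k + 1`` times per side, each lce run followed by skipping
  (and marking) one mismatching position.  Exact per-window mismatch
  counts then come from a sliding sum over the mark array ``M``.

* ``acsmf_search`` (``variant="simple"``, the default) — identical output,
  but the extensions are plain letter-by-letter comparisons, so no suffix
  array is ever built.  On uniform random data an extension run is expected
  to inspect fewer than 3 letters, which makes this variant the practical
  choice (O(m) extra space instead of O(n)).

Both variants report, for every text position ``j`` whose window
``t[j..j+m-1]`` is within distance ``k`` of some rotation, the position,
the rotation index and the exact distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Literal

from .automaton import FragmentOccurrence, build_automaton, find_fragment_occurrences
from .core import (
    CircularMatch,
    DoubledPattern,
    InvalidInputError,
    Sequence,
    check_same_alphabet,
    dedupe_matches,
    double_pattern,
    pigeonhole_fragment_count,
    split_fragments,
)
from .index import LceIndex, build_index, lce

logger = logging.getLogger("circmatch")

Variant = Literal["lce", "simple"]


def pick_sentinel(*parts: str) -> str:
    """A single character absent from every given string.

    Concatenations are indexed with this separator between parts so that an
    lce run can never silently cross a part boundary.
    """
    for ch in "\x00\x01\x02#|$%&!~^":
        if all(ch not in p for p in parts):
            return ch
    used = set().union(*map(set, parts))
    cp = 0
    while chr(cp) in used:
        cp += 1
    return chr(cp)


@dataclass(frozen=True)
class ExtensionResult:
    """Outcome of extending one fragment occurrence.

    ``left``/``right`` are the extension lengths El/Er (exact) or El^k/Er^k
    (with up to ``k`` skipped mismatches per side), mismatches included.
    ``marks`` is the array ``M`` over x' offsets, 1 where an extension
    consumed a mismatch.  ``comparisons`` records, for the comparison-based
    variant, the number of letter comparisons of each individual extension
    run (empty for the index-based variant).
    """

    left: int
    right: int
    marks: tuple[int, ...]
    comparisons: tuple[int, ...] = ()


def _chain(run, max_both: int, k: int):
    """Up to ``k + 1`` extension runs, skipping one mismatch between runs.

    ``run(offset)`` returns ``(match_run_length, letter_comparisons)`` for
    the run starting ``offset`` letters into the extension; it must cap at
    ``max_both - offset``.  A run that reaches ``max_both`` hit a string
    boundary: the chain stops there without consuming a mismatch, because a
    boundary is not a mismatch.
    """
    total = 0
    mismatch_offsets: list[int] = []
    comparisons: list[int] = []
    for step in range(k + 1):
        if total >= max_both:
            break
        r, c = run(total)
        comparisons.append(c)
        total += r
        if total >= max_both or step == k:
            break
        mismatch_offsets.append(total)
        total += 1
    return total, mismatch_offsets, comparisons


def _make_result(occ: FragmentOccurrence, two_m_minus_1: int,
                 left: int, left_mis: list[int],
                 right: int, right_mis: list[int],
                 comparisons: tuple[int, ...] = ()) -> ExtensionResult:
    marks = [0] * two_m_minus_1
    for off in left_mis:
        marks[occ.p_xprime - off - 1] = 1
    for off in right_mis:
        marks[occ.p_xprime + occ.length + off] = 1
    return ExtensionResult(left=left, right=right, marks=tuple(marks),
                           comparisons=comparisons)


def extend_lce(idx_f: LceIndex, idx_r: LceIndex, occ: FragmentOccurrence,
               k: int, *, m: int, n: int) -> ExtensionResult:
    """Extend a fragment occurrence with chained lce queries.

    ``idx_f`` indexes ``x' # t`` and ``idx_r`` indexes
    ``reverse(x') # reverse(t)`` (``#`` the sentinel), so with the sentinel
    the text part starts at offset ``2m`` in either concatenation.
    """
    two_m_minus_1 = 2 * m - 1
    pX, l, pT = occ.p_xprime, occ.length, occ.p_t

    max_right = min(two_m_minus_1 - (pX + l), n - (pT + l))
    right, right_mis, _ = _chain(
        lambda off: (lce(idx_f, pX + l + off, 2 * m + pT + l + off), 0),
        max_right, k)

    # x'[pX-1-off] sits at offset (2m-1)-pX+off of reverse(x');
    # t[pT-1-off] sits at offset 2m + n-pT+off of the reversed concatenation.
    max_left = min(pX, pT)
    left, left_mis, _ = _chain(
        lambda off: (lce(idx_r, two_m_minus_1 - pX + off, 2 * m + n - pT + off), 0),
        max_left, k)

    return _make_result(occ, two_m_minus_1, left, left_mis, right, right_mis)


def extend_simple(xprime: str, t: str, occ: FragmentOccurrence,
                  k: int) -> ExtensionResult:
    """Extend a fragment occurrence by direct letter comparisons.

    Behaviourally identical to :func:`extend_lce`; additionally counts the
    letter comparisons of every run (each run stops right at its first
    mismatching letter, or at a string boundary without a comparison beyond
    it).
    """
    two_m_minus_1 = len(xprime)
    pX, l, pT = occ.p_xprime, occ.length, occ.p_t

    def run_right(off: int):
        limit = max_right - off
        ax, tx = pX + l + off, pT + l + off
        i = c = 0
        while i < limit:
            c += 1
            if xprime[ax + i] != t[tx + i]:
                break
            i += 1
        return i, c

    def run_left(off: int):
        limit = max_left - off
        ax, tx = pX - 1 - off, pT - 1 - off
        i = c = 0
        while i < limit:
            c += 1
            if xprime[ax - i] != t[tx - i]:
                break
            i += 1
        return i, c

    max_right = min(two_m_minus_1 - (pX + l), len(t) - (pT + l))
    right, right_mis, comp_r = _chain(run_right, max_right, k)
    max_left = min(pX, pT)
    left, left_mis, comp_l = _chain(run_left, max_left, k)

    return _make_result(occ, two_m_minus_1, left, left_mis, right, right_mis,
                        comparisons=tuple(comp_l + comp_r))


def report_window(occ: FragmentOccurrence, ext: ExtensionResult,
                  m: int, n: int, k: int) -> list[CircularMatch]:
    """Valid starting positions certified by one extended occurrence.

    Requires the full extension to span at least ``m`` letters; candidate
    starts ``j`` run over ``max(p_t - El, p_t + l - m) .. min(p_t + l - m +
    Er, p_t)`` clamped to ``[0, n - m]``.  The window of ``t`` starting at
    ``j`` aligns with ``x'[o : o+m]`` where ``o = p_x' - (p_t - j)``, so its
    exact mismatch count is the sliding sum of the marks ``M[o : o+m]``;
    positions with at most ``k`` mismatches are reported with rotation
    index ``o``.
    """
    pX, l, pT = occ.p_xprime, occ.length, occ.p_t
    if ext.left + l + ext.right < m:
        return []
    lo = max(pT - ext.left, pT + l - m, 0)
    hi = min(pT + l - m + ext.right, pT, n - m)
    if lo > hi:
        return []
    M = ext.marks
    o = pX - (pT - lo)
    assert 0 <= o and o + m <= len(M)
    mu = sum(M[o:o + m])
    out: list[CircularMatch] = []
    for j in range(lo, hi + 1):
        if mu <= k:
            out.append(CircularMatch(position=j, rotation=o % m,
                                     distance=mu, length=m))
        if j < hi:
            mu += M[o + m] - M[o]
            o += 1
    return out


def _validated(x: Sequence, t: Sequence, k: int) -> tuple[int, int]:
    check_same_alphabet(x, t)
    m, n = len(x), len(t)
    if k < 0:
        raise InvalidInputError(f"threshold k must be non-negative, got {k}")
    if n <= m:
        raise InvalidInputError(
            f"text (n={n}) must be longer than the pattern (m={m})")
    return m, n


def acsmf_extensions(x: Sequence, t: Sequence, k: int,
                     variant: Variant = "simple",
                     ) -> Iterator[tuple[FragmentOccurrence, ExtensionResult]]:
    """Filtration + extension: yield every fragment occurrence with its
    extension result, without the reporting/deduplication step.

    Exposed separately so the verification workload (number of extension
    attempts, letter comparisons per attempt) can be measured directly.
    """
    m, n = _validated(x, t, k)
    f = pigeonhole_fragment_count(m, k)
    d = split_fragments(double_pattern(x), f)
    ac = build_automaton(d.fragment_strings())
    occs = find_fragment_occurrences(ac, t.letters)
    logger.info("filtration: m=%d n=%d k=%d fragments=%d Occ=%d",
                m, n, k, f, len(occs))
    xp = d.doubled
    if variant == "lce":
        sent = pick_sentinel(xp, t.letters)
        idx_f = build_index(xp + sent + t.letters)
        idx_r = build_index(xp[::-1] + sent + t.letters[::-1])
        for occ in occs:
            yield occ, extend_lce(idx_f, idx_r, occ, k, m=m, n=n)
    elif variant == "simple":
        for occ in occs:
            yield occ, extend_simple(xp, t.letters, occ, k)
    else:  # pragma: no cover - guarded by the Literal type
        raise InvalidInputError(f"unknown variant {variant!r}")


def acsmf_search(x: Sequence, t: Sequence, k: int,
                 variant: Variant = "simple",
                 all_rotations: bool = False) -> list[CircularMatch]:
    """All positions of ``t`` where some rotation of ``x`` occurs with at
    most ``k`` mismatches.

    Output is sorted and deduplicated by position (minimum distance;
    smallest rotation on ties), or by (position, rotation) with
    ``all_rotations=True``.  Both variants produce identical output; with
    ``k = 0`` the result equals :func:`ecsmf_search`.
    """
    m, n = _validated(x, t, k)
    raw: list[CircularMatch] = []
    for occ, ext in acsmf_extensions(x, t, k, variant=variant):
        raw.extend(report_window(occ, ext, m, n, k))
    out = dedupe_matches(raw, all_rotations=all_rotations)
    logger.info("acsmf(%s): k=%d reported %d matches", variant, k, len(out))
    return out


def ecsmf_search(x: Sequence, t: Sequence,
                 all_rotations: bool = False) -> list[CircularMatch]:
    """Exact circular matching: every position where a rotation of ``x``
    occurs verbatim in ``t``.

    Patterns of length <= 2 cannot host the 4-fragment partition
    (2m - 1 < 4); they are handled by the brute-force reference search,
    which is exact and cheap at that size.
    """
    m, n = _validated(x, t, 0)
    if 2 * m - 1 < 4:
        from .oracle import oracle_hamming

        logger.info("pattern too short for 4 fragments (m=%d); using the "
                    "brute-force search", m)
        return oracle_hamming(x, t, 0, all_rotations=all_rotations)
    return acsmf_search(x, t, 0, variant="lce", all_rotations=all_rotations)
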