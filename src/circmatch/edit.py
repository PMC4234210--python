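"""Approximate circular matching under the edit distance model.

The pigeonhole filtration carries over unchanged: each of at most ``k``
single-letter edits can break at most one of the ``2k + 4`` fragments of the
doubled pattern, so every occurrence of a rotation within edit distance
``k`` still contains at least one fragment verbatim.  Verification replaces
the mismatch-counting extension with semi-global dynamic programming over a
length-O(m) region of the text around each fragment hit.

A match is reported at the START of the matching factor of ``t``; factor
lengths range over ``m-k .. m+k`` and the minimal distance per (position,
rotation) is kept.  End positions come from a forward semi-global DP with
two rolling rows; the start for each qualifying end is recovered by a
second, reversed DP (space stays O(m)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .automaton import FragmentOccurrence, build_automaton, find_fragment_occurrences
from .core import (
    CircularMatch,
    InvalidInputError,
    Sequence,
    check_same_alphabet,
    dedupe_matches,
    double_pattern,
    pigeonhole_fragment_count,
    rotations,
    split_fragments,
)

logger = logging.getLogger("circmatch")


@dataclass(frozen=True, order=True)
class EditRegion:
    """Half-open window ``[start, end)`` of the text to be DP-verified."""

    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start


def edit_region_for(occ: FragmentOccurrence, m: int, k: int, n: int) -> EditRegion:
    """The text region that can contain a <=k-edit occurrence of a rotation
    embedding this fragment hit.

    A qualifying factor has length at most ``m + k``, contains
    ``t[p_t : p_t+l]`` intact, and therefore starts no earlier than
    ``p_t + l - m - k`` and ends no later than ``p_t + m + k``.
    """
    lo = max(0, occ.p_t + occ.length - m - k)
    hi = min(n, occ.p_t + m + k)
    return EditRegion(start=lo, end=hi)


def _forward_ends(rot: str, region: str) -> list[int]:
    """Semi-global DP: for each end ``e`` the minimum edit distance between
    ``rot`` and any factor of ``region`` ending at ``e`` (free start)."""
    m = len(rot)
    w = len(region)
    prev = [0] * (w + 1)
    for i in range(1, m + 1):
        cur = [i] + [0] * w
        ri = rot[i - 1]
        for c in range(1, w + 1):
            cur[c] = min(prev[c - 1] + (ri != region[c - 1]),
                         prev[c] + 1,
                         cur[c - 1] + 1)
        prev = cur
    return prev


def _starts_for_end(rot: str, region: str, e: int, k: int) -> list[tuple[int, int]]:
    """Exact distances by start for a fixed end: pairs ``(s, d)`` with
    ``d = dist(rot, region[s:e]) <= k``, via a reversed global DP."""
    m = len(rot)
    b = region[max(0, e - m - k):e][::-1]
    rr = rot[::-1]
    w = len(b)
    prev = list(range(w + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * w
        ri = rr[i - 1]
        for c in range(1, w + 1):
            cur[c] = min(prev[c - 1] + (ri != b[c - 1]),
                         prev[c] + 1,
                         cur[c - 1] + 1)
        prev = cur
    out = []
    for L in range(max(1, m - k), w + 1):
        if prev[L] <= k:
            out.append((e - L, prev[L]))
    return out


def verify_region_edit(x: Sequence, region_text: str,
                       k: int) -> list[tuple[int, int, int]]:
    """All ``(region-relative start, rotation index, distance)`` triples with
    distance at most ``k``, minimal per (start, rotation)."""
    if not region_text:
        raise InvalidInputError("empty verification region")
    best: dict[tuple[int, int], int] = {}
    for i, rot in enumerate(rotations(x)):
        ends = _forward_ends(rot, region_text)
        for e in range(1, len(region_text) + 1):
            if ends[e] <= k:
                for s, d in _starts_for_end(rot, region_text, e, k):
                    key = (s, i)
                    if d < best.get(key, k + 1):
                        best[key] = d
    return sorted((s, i, d) for (s, i), d in best.items())


def _merged_regions(regions: list[EditRegion]) -> list[EditRegion]:
    merged: list[EditRegion] = []
    for r in sorted(regions):
        if merged and r.start <= merged[-1].end:
            if r.end > merged[-1].end:
                merged[-1] = EditRegion(merged[-1].start, r.end)
        else:
            merged.append(r)
    return merged


def edit_search(x: Sequence, t: Sequence, k: int,
                all_rotations: bool = False) -> list[CircularMatch]:
    """Circular matching with at most ``k`` edits: filtration with ``2k + 4``
    fragments, then DP verification of the merged candidate regions."""
    check_same_alphabet(x, t)
    m, n = len(x), len(t)
    if k < 0:
        raise InvalidInputError(f"threshold k must be non-negative, got {k}")
    if n <= m:
        raise InvalidInputError(
            f"text (n={n}) must be longer than the pattern (m={m})")
    d = split_fragments(double_pattern(x), pigeonhole_fragment_count(m, k))
    ac = build_automaton(d.fragment_strings())
    occs = find_fragment_occurrences(ac, t.letters)
    regions = _merged_regions([edit_region_for(o, m, k, n) for o in occs])
    logger.info("edit filtration: m=%d n=%d k=%d Occ=%d regions=%d",
                m, n, k, len(occs), len(regions))
    raw: list[CircularMatch] = []
    for reg in regions:
        for s, i, dist in verify_region_edit(x, t.letters[reg.start:reg.end], k):
            raw.append(CircularMatch(position=reg.start + s, rotation=i,
                                     distance=dist, length=m))
    out = dedupe_matches(raw, all_rotations=all_rotations)
    logger.info("edit: k=%d reported %d matches", k, len(out))
    return out
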