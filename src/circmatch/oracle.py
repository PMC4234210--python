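"""Brute-force reference searches.

These realise the two problem statements directly — every window of the
text against every rotation of the pattern — and serve as ground truth for
the filter-and-verify algorithms, as well as a selectable (slow) algorithm
in the CLI.  Window/rotation comparison is vectorised with numpy; the cost
is still O(n m) per rotation, O(n m^2)-ish overall, which is fine at test
scale.
"""

from __future__ import annotations

import numpy as np

from .core import (
    CircularMatch,
    InvalidInputError,
    Sequence,
    check_same_alphabet,
    dedupe_matches,
    rotations,
)


def hamming_distance(a: str, b: str) -> int:
    """Number of positions at which two equal-length strings differ."""
    if len(a) != len(b):
        raise InvalidInputError(
            f"Hamming distance requires equal lengths, got {len(a)} and {len(b)}")
    return sum(ca != cb for ca, cb in zip(a, b))


def _as_codes(s: str) -> np.ndarray:
    return np.frombuffer(np.array([s], dtype=f"<U{len(s)}").tobytes(),
                         dtype=np.uint32)


def oracle_hamming(x: Sequence, t: Sequence, k: int,
                   all_rotations: bool = False) -> list[CircularMatch]:
    """Every (position, rotation, distance <= k) triple, by enumeration."""
    check_same_alphabet(x, t)
    m, n = len(x), len(t)
    if k < 0:
        raise InvalidInputError(f"threshold k must be non-negative, got {k}")
    if n < m:
        return []
    tarr = _as_codes(t.letters)
    windows = np.lib.stride_tricks.sliding_window_view(tarr, m)
    raw: list[CircularMatch] = []
    for i, rot in enumerate(rotations(x)):
        dist = (windows != _as_codes(rot)).sum(axis=1)
        for j in np.flatnonzero(dist <= k):
            raw.append(CircularMatch(position=int(j), rotation=i,
                                     distance=int(dist[j]), length=m))
    return dedupe_matches(raw, all_rotations=all_rotations)


def _edit_distances_fixed_start(rot: np.ndarray, windows: np.ndarray,
                                m: int, k: int) -> np.ndarray:
    """For every window (a start of t, padded to length m+k), the minimum
    edit distance between ``rot`` and any window prefix of length m-k..m+k.

    Classic (m+1) x (W+1) dynamic-programming table, with the start column
    vectorised across all windows at once.  Padding characters never match,
    so alignments that would run past the end of the text can only cost
    more than stopping at it.
    """
    S, W = windows.shape
    prev = np.empty((S, W + 1), dtype=np.int32)
    prev[:] = np.arange(W + 1, dtype=np.int32)
    cur = np.empty_like(prev)
    for i in range(1, m + 1):
        cur[:, 0] = i
        sub = (windows != rot[i - 1]).astype(np.int32)
        for c in range(1, W + 1):
            cur[:, c] = np.minimum(
                prev[:, c - 1] + sub[:, c - 1],
                np.minimum(prev[:, c] + 1, cur[:, c - 1] + 1))
        prev, cur = cur, prev
    lo = max(0, m - k)
    return prev[:, lo:W + 1].min(axis=1)


def oracle_edit(x: Sequence, t: Sequence, k: int,
                all_rotations: bool = False) -> list[CircularMatch]:
    """Every text position where a factor starting there is within edit
    distance ``k`` of some rotation, with the minimal distance.

    For each rotation and each start ``j``, a full DP table against
    ``t[j : j+m+k]`` gives the minimum distance over factor lengths
    ``m-k .. m+k``; length information is not retained (matches carry the
    nominal length ``m``).
    """
    check_same_alphabet(x, t)
    m, n = len(x), len(t)
    if k < 0:
        raise InvalidInputError(f"threshold k must be non-negative, got {k}")
    if n < m - k:
        return []
    W = m + k
    n_starts = n - max(1, m - k) + 1
    if n_starts <= 0:
        return []
    pad = np.uint32(0xFFFFFFFF)  # matches no real letter
    tarr = np.concatenate([_as_codes(t.letters), np.full(W, pad, np.uint32)])
    windows = np.lib.stride_tricks.sliding_window_view(tarr, W)[:n_starts]
    raw: list[CircularMatch] = []
    for i, rot in enumerate(rotations(x)):
        dist = _edit_distances_fixed_start(_as_codes(rot), windows, m, k)
        for j in np.flatnonzero(dist <= k):
            raw.append(CircularMatch(position=int(j), rotation=i,
                                     distance=int(dist[j]), length=m))
    return dedupe_matches(raw, all_rotations=all_rotations)
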