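"""Suffix array / LCP / RMQ index answering longest-common-extension queries.

The longest common extension (lce) of two suffixes of a string ``T`` is the
length of their longest common prefix.  After computing the suffix array
``SA``, its inverse ``iSA`` and the LCP array (``LCP[r]`` = lcp of the
suffixes ranked ``r-1`` and ``r``), any lce reduces to a range-minimum query
over LCP:

    lce(p, q) = min LCP[r]  for  r in (min(iSA[p], iSA[q]), max(iSA[p], iSA[q])]

and ``lce(p, p) = N - p``.  A sparse table makes each query O(1).

Construction here is prefix-doubling (O(N log^2 N)) plus Kasai's LCP
algorithm; the intended scale is verification work over ``x' + t``
concatenations, where this is more than fast enough.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import InvalidInputError


def _suffix_array(s: str) -> list[int]:
    # prefix doubling on integer ranks
    n = len(s)
    sa = sorted(range(n), key=lambda i: s[i])
    rank = [0] * n
    for idx in range(1, n):
        rank[sa[idx]] = rank[sa[idx - 1]] + (s[sa[idx]] != s[sa[idx - 1]])
    k = 1
    tmp = [0] * n
    while k < n and rank[sa[-1]] < n - 1:
        key = lambda i: (rank[i], rank[i + k] if i + k < n else -1)
        sa.sort(key=key)
        tmp[sa[0]] = 0
        for idx in range(1, n):
            tmp[sa[idx]] = tmp[sa[idx - 1]] + (key(sa[idx]) != key(sa[idx - 1]))
        rank = tmp[:]
        k *= 2
    return sa


def _kasai_lcp(s: str, sa: list[int], isa: list[int]) -> list[int]:
    # LCP[r] = lcp(suffix at SA[r-1], suffix at SA[r]); LCP[0] = 0
    n = len(s)
    lcp = [0] * n
    h = 0
    for i in range(n):
        r = isa[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and s[i + h] == s[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


class _SparseTable:
    """Static range-minimum structure: O(N log N) build, O(1) query."""

    def __init__(self, a: list[int]):
        self.logs = [0] * (len(a) + 1)
        for i in range(2, len(a) + 1):
            self.logs[i] = self.logs[i // 2] + 1
        self.table = [a[:]]
        j = 1
        while (1 << j) <= len(a):
            prev = self.table[j - 1]
            span = 1 << (j - 1)
            self.table.append(
                [min(prev[i], prev[i + span])
                 for i in range(len(a) - (1 << j) + 1)]
            )
            j += 1

    def min(self, lo: int, hi: int) -> int:
        """Minimum of a[lo..hi] inclusive; lo <= hi required."""
        j = self.logs[hi - lo + 1]
        row = self.table[j]
        return min(row[lo], row[hi - (1 << j) + 1])


@dataclass(frozen=True)
class LceIndex:
    """SA + inverse SA + LCP + RMQ over a string ``T``."""

    text: str
    sa: list[int]
    isa: list[int]
    lcp: list[int]
    rmq: _SparseTable

    def __len__(self) -> int:
        return len(self.text)


def build_index(T: str) -> LceIndex:
    """Build the lce index over ``T`` (non-empty)."""
    if not T:
        raise InvalidInputError("cannot index an empty string")
    sa = _suffix_array(T)
    isa = [0] * len(T)
    for r, p in enumerate(sa):
        isa[p] = r
    lcp = _kasai_lcp(T, sa, isa)
    return LceIndex(text=T, sa=sa, isa=isa, lcp=lcp, rmq=_SparseTable(lcp))


def lce(idx: LceIndex, p: int, q: int) -> int:
    """Longest common prefix length of the suffixes ``T[p:]`` and ``T[q:]``."""
    n = len(idx.text)
    if not (0 <= p < n and 0 <= q < n):
        raise InvalidInputError(f"suffix positions ({p}, {q}) out of range [0, {n})")
    if p == q:
        return n - p
    rp, rq = idx.isa[p], idx.isa[q]
    if rp > rq:
        rp, rq = rq, rp
    return idx.rmq.min(rp + 1, rq)
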