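"""Domain types and the pattern-doubling / fragment-partition primitives.

A circular pattern of length ``m`` is the equivalence class of the ``m``
rotations of a linear string ``x``.  Every rotation of ``x`` is a length-``m``
factor of the doubled string ``x' = x[0..m-1] x[0..m-2]`` (of length
``2m - 1``) and vice versa, so searching for a circular pattern reduces to
searching for length-``m`` factors of ``x'``.

The filtration step rests on a pigeonhole argument: if ``x'`` is cut into
``f`` contiguous fragments of (near-)equal length, then

* with ``f = 4`` every length-``m`` factor of ``x'`` contains at least one
  fragment intact (exact matching), and
* with ``f = 2k + 4`` every length-``m`` factor contains at least ``k + 1``
  intact fragments, so an occurrence with at most ``k`` mismatches still
  contains one fragment exactly.

Only exact fragment hits in the text therefore need verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class InvalidInputError(ValueError):
    """Raised when an input violates a precondition of the algorithms."""


class ThresholdTooLargeError(InvalidInputError):
    """Raised when 2k+4 fragments do not fit in the doubled pattern.

    The pigeonhole partition requires ``f <= 2m - 1`` non-empty fragments;
    a threshold ``k`` with ``2k + 4 > 2m - 1`` is too large for the pattern.
    """


@dataclass(frozen=True)
class Sequence:
    """A string over a finite alphabet, with an optional declared alphabet.

    Parameters
    ----------
    letters:
        The sequence itself.  Letters are opaque symbols; no case folding
        or reverse-complementing is applied.
    id:
        A free-text label (FASTA record id).
    alphabet:
        Optional declared alphabet.  When given, every letter must belong
        to it; when omitted, the alphabet is taken to be the set of
        distinct letters observed.
    """

    letters: str
    id: str = ""
    alphabet: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not self.letters:
            raise InvalidInputError(f"sequence {self.id!r} is empty")
        if self.alphabet is not None:
            extra = set(self.letters) - set(self.alphabet)
            if extra:
                raise InvalidInputError(
                    f"sequence {self.id!r} contains letters {sorted(extra)} "
                    f"outside its declared alphabet"
                )

    def __len__(self) -> int:
        return len(self.letters)

    @property
    def sigma(self) -> int:
        """Alphabet size: declared if available, observed otherwise."""
        if self.alphabet is not None:
            return len(self.alphabet)
        return len(set(self.letters))


@dataclass(frozen=True)
class Fragment:
    """One contiguous piece of the doubled pattern: ``x'[start:start+length]``."""

    start: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class DoubledPattern:
    """The doubled pattern ``x'`` together with its fragment partition."""

    source: Sequence
    doubled: str
    fragments: tuple[Fragment, ...] = ()

    @property
    def m(self) -> int:
        return len(self.source)

    def fragment_strings(self) -> list[tuple[str, int]]:
        """Fragments as ``(string, start offset in x')`` pairs."""
        return [(self.doubled[f.start:f.end], f.start) for f in self.fragments]


@dataclass(frozen=True, order=True)
class CircularMatch:
    """An occurrence of some rotation of the pattern in the text.

    ``position`` is the 0-based start of the matching factor of ``t``,
    ``rotation`` the index ``i`` of the matching rotation ``x^i`` and
    ``distance`` the Hamming (or edit) distance of the factor to that
    rotation.  ``length`` is the factor length (always ``m`` under the
    Hamming model; ``m-k .. m+k`` under edit distance).
    """

    position: int
    rotation: int
    distance: int
    length: int = 0


def double_pattern(x: Sequence) -> DoubledPattern:
    """Return ``x' = x[0..m-1] x[0..m-2]`` of length ``2m - 1``.

    For ``m = 1`` the definition collapses and ``x' = x``.
    """
    s = x.letters
    return DoubledPattern(source=x, doubled=s + s[:-1])


def rotations(x: Sequence | str) -> list[str]:
    """All rotations of ``x`` in order: element ``i`` is ``x[i:] + x[:i]``."""
    s = x.letters if isinstance(x, Sequence) else x
    if not s:
        raise InvalidInputError("cannot rotate an empty string")
    return [s[i:] + s[:i] for i in range(len(s))]


def split_fragments(d: DoubledPattern, f: int) -> DoubledPattern:
    """Partition ``x'`` into ``f`` contiguous fragments of near-equal length.

    Fragment lengths are ``floor((2m-1)/f)`` or ``ceil((2m-1)/f)``; the
    first ``(2m-1) mod f`` fragments take the ceiling length, the rest the
    floor (this ordering reproduces the canonical worked partitions, e.g.
    GGGTCTAGGGTCT with f=4 -> GGGT | CTA | GGG | TCT).
    """
    L = len(d.doubled)
    if f < 1:
        raise InvalidInputError(f"fragment count must be positive, got {f}")
    if f > L:
        raise ThresholdTooLargeError(
            f"cannot cut a doubled pattern of length {L} into {f} non-empty "
            f"fragments; the mismatch threshold is too large for this pattern"
        )
    q, r = divmod(L, f)
    frags: list[Fragment] = []
    pos = 0
    for i in range(f):
        length = q + 1 if i < r else q
        frags.append(Fragment(start=pos, length=length))
        pos += length
    assert pos == L
    return DoubledPattern(source=d.source, doubled=d.doubled,
                          fragments=tuple(frags))


def min_intact_fragments(d: DoubledPattern) -> int:
    """Minimum, over all length-``m`` windows of ``x'``, of the number of
    fragments fully contained in the window.

    This is the pigeonhole budget: with ``c`` whole fragments in a window,
    up to ``c - 1`` mismatches can be tolerated while still leaving one
    fragment intact.
    """
    m = len(d.source)
    best = len(d.fragments)
    for s in range(m):  # windows [s, s + m) of x', s in 0..m-1
        count = sum(1 for f in d.fragments if f.start >= s and f.end <= s + m)
        best = min(best, count)
    return best


def pigeonhole_fragment_count(m: int, k: int) -> int:
    """Smallest fragment count ``f >= 2k + 4`` whose equal partition leaves
    at least ``k + 1`` whole fragments in every length-``m`` window of ``x'``.

    ``2k + 4`` almost always suffices; when ``(2m-1) mod (2k+4) != 0`` the
    ceiling-length fragments can exceed ``(2m-1)/(2k+4)`` and a window may
    contain fewer than ``k + 1`` whole fragments, so the count is verified
    explicitly and increased if needed.  ``f = 2m - 1`` (single letters)
    always satisfies the requirement for ``k <= m - 2``, so the search
    terminates.  The partition geometry depends only on lengths, so a
    placeholder pattern is used for the check.
    """
    if 2 * k + 4 > 2 * m - 1:
        raise ThresholdTooLargeError(
            f"threshold k={k} needs 2k+4={2 * k + 4} fragments but the "
            f"doubled pattern has only {2 * m - 1} letters")
    skeleton = double_pattern(Sequence("A" * m))
    for f in range(2 * k + 4, 2 * m):
        if min_intact_fragments(split_fragments(skeleton, f)) >= k + 1:
            return f
    raise AssertionError("unreachable: single-letter fragments always suffice")


def check_same_alphabet(x: Sequence, t: Sequence) -> None:
    """Reject explicitly declared, incompatible alphabets."""
    if x.alphabet is not None and t.alphabet is not None \
            and x.alphabet != t.alphabet:
        raise InvalidInputError(
            "pattern and text declare different alphabets"
        )


def dedupe_matches(matches: list[CircularMatch],
                   all_rotations: bool = False) -> list[CircularMatch]:
    """Canonicalise a raw match list.

    Default: one match per text position, keeping the minimum distance and,
    among equal distances, the smallest rotation index.  With
    ``all_rotations=True`` every distinct (position, rotation) pair is kept
    at its minimal distance.
    """
    if all_rotations:
        best: dict[tuple[int, int], CircularMatch] = {}
        for cm in matches:
            key = (cm.position, cm.rotation)
            if key not in best or cm.distance < best[key].distance:
                best[key] = cm
        return sorted(best.values())
    best_pos: dict[int, CircularMatch] = {}
    for cm in matches:
        old = best_pos.get(cm.position)
        if old is None or (cm.distance, cm.rotation) < (old.distance, old.rotation):
            best_pos[cm.position] = cm
    return sorted(best_pos.values())
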