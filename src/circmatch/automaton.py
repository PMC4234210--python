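"""Aho-Corasick multi-pattern search of the fragments against the text.

The filtration step needs every exact occurrence of every fragment of the
doubled pattern ``x'`` in the text ``t``, as 3-tuples ``(p_x', l, p_t)``
(fragment start in ``x'``, fragment length, occurrence start in ``t``) —
the candidate list that verification then extends.  A single automaton pass
over ``t`` finds them all, including overlapping and nested hits; identical
fragment strings cut from different offsets of ``x'`` each yield their own
tuple per text hit.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import deque


@dataclass(frozen=True, order=True)
class FragmentOccurrence:
    """One exact hit of fragment ``x'[p_xprime : p_xprime+length]`` at ``t[p_t]``."""

    p_t: int
    p_xprime: int
    length: int


class AcAutomaton:
    """Classic goto/fail/output automaton over a fixed fragment set."""

    def __init__(self, fragments: list[tuple[str, int]]):
        from .core import InvalidInputError

        if not fragments:
            raise InvalidInputError("fragment set is empty")
        for s, _ in fragments:
            if not s:
                raise InvalidInputError("empty fragment string")
        # group duplicate strings: one trie terminal -> many (offset, length)
        self._entries: dict[str, list[tuple[int, int]]] = {}
        for s, off in fragments:
            self._entries.setdefault(s, []).append((off, len(s)))
        self.n_patterns = len(fragments)

        self._goto: list[dict[str, int]] = [{}]
        self._out: list[list[str]] = [[]]
        for s in self._entries:
            node = 0
            for ch in s:
                nxt = self._goto[node].get(ch)
                if nxt is None:
                    self._goto.append({})
                    self._out.append([])
                    nxt = len(self._goto) - 1
                    self._goto[node][ch] = nxt
                node = nxt
            self._out[node].append(s)

        self._fail = [0] * len(self._goto)
        queue: deque[int] = deque()
        for child in self._goto[0].values():
            queue.append(child)
        while queue:
            node = queue.popleft()
            for ch, child in self._goto[node].items():
                queue.append(child)
                f = self._fail[node]
                while f and ch not in self._goto[f]:
                    f = self._fail[f]
                self._fail[child] = self._goto[f].get(ch, 0)
                if self._fail[child] == child:
                    self._fail[child] = 0
                self._out[child] = self._out[child] + self._out[self._fail[child]]

    def scan(self, text: str):
        """Yield ``(end_position, matched_string)`` for every hit."""
        node = 0
        goto = self._goto
        fail = self._fail
        out = self._out
        for i, ch in enumerate(text):
            while node and ch not in goto[node]:
                node = fail[node]
            node = goto[node].get(ch, 0)
            if out[node]:
                for s in out[node]:
                    yield i, s


def build_automaton(fragments: list[tuple[str, int]]) -> AcAutomaton:
    """Build the automaton from ``(fragment string, offset in x')`` pairs."""
    return AcAutomaton(fragments)


def find_fragment_occurrences(ac: AcAutomaton, text: str) -> list[FragmentOccurrence]:
    """All fragment occurrences in ``text``, sorted by (p_t, p_xprime).

    Aho-Corasick reports hit END positions; tuples use start positions
    (``p_t = end - length + 1``).
    """
    occs: list[FragmentOccurrence] = []
    entries = ac._entries
    for end, s in ac.scan(text):
        for off, length in entries[s]:
            occs.append(FragmentOccurrence(p_t=end - length + 1,
                                           p_xprime=off, length=length))
    occs.sort()
    return occs
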