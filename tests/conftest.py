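import pytest
from hypothesis import settings

from circmatch.core import Sequence

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# The worked DNA example used throughout: pattern GGGTCTA (m=7) searched in
# a 27-letter text; rotation x^4 = CTAGGGT occurs exactly at position 10.
PATTERN = "GGGTCTA"
TEXT = "GATACGATACCTAGGGTGATAGAATAG"


@pytest.fixture
def pattern() -> Sequence:
    return Sequence(PATTERN, id="pat")


@pytest.fixture
def text() -> Sequence:
    return Sequence(TEXT, id="txt")


def naive_suffix_array(s: str) -> list[int]:
    return sorted(range(len(s)), key=lambda i: s[i:])


def naive_lcp(a: str, b: str) -> int:
    n = 0
    for ca, cb in zip(a, b):
        if ca != cb:
            break
        n += 1
    return n
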