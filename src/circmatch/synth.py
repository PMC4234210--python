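"""Seeded synthetic data: uniform random texts with implanted rotations.

The generator emulates the setting the matching algorithms are analysed in:
an i.i.d. uniform text over an alphabet of size ``sigma`` (DNA by default),
into which rotated copies of a pattern are implanted at known positions
with a controlled number of substitutions (Hamming model) or single-letter
edits (edit model).  The returned :class:`ImplantRecord` list is the ground
truth used to measure recall of the filtration.

Substitutions always change the letter (resampled from the rest of the
alphabet), so a Hamming-model record's ``distance`` is exact, not an upper
bound.  Implants are kept at least ``m`` letters apart so that ground truth
windows never interact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import InvalidInputError, Sequence, rotations

DNA = "ACGT"


@dataclass(frozen=True)
class ImplantRecord:
    """Ground truth for one implanted rotated copy of the pattern."""

    position: int
    rotation: int
    distance: int
    model: str = "hamming"


def _alphabet(sigma_or_letters) -> str:
    if isinstance(sigma_or_letters, str):
        letters = sigma_or_letters
    else:
        sigma = int(sigma_or_letters)
        if sigma <= len(DNA):
            letters = DNA[:sigma]
        else:
            letters = "".join(chr(ord("A") + i) for i in range(sigma))
    if not letters:
        raise InvalidInputError("alphabet is empty")
    return letters


def random_text(n: int, alphabet="ACGT", seed: int | np.random.Generator = 0,
                id: str = "random") -> Sequence:
    """A length-``n`` string with letters i.i.d. uniform over ``alphabet``.

    ``alphabet`` may be a string of letters or an alphabet size (DNA letters
    are used for sizes up to 4).  Deterministic given the seed.
    """
    if n < 1:
        raise InvalidInputError(f"text length must be positive, got {n}")
    letters = _alphabet(alphabet)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.integers(0, len(letters), size=n)
    arr = np.array(list(letters))
    return Sequence(letters="".join(arr[draws]), id=id,
                    alphabet=frozenset(letters))


def _mutate_hamming(s: str, num_errors: int, alphabet: str,
                    rng: np.random.Generator) -> str:
    if num_errors > len(s):
        raise InvalidInputError("more substitutions than letters")
    pos = rng.choice(len(s), size=num_errors, replace=False)
    out = list(s)
    for p in pos:
        choices = [c for c in alphabet if c != out[p]]
        if not choices:
            raise InvalidInputError(
                "cannot substitute over a single-letter alphabet")
        out[p] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _mutate_edit(s: str, num_errors: int, alphabet: str,
                 rng: np.random.Generator) -> str:
    out = list(s)
    for _ in range(num_errors):
        op = rng.integers(0, 3)
        if op == 0 and len(out) > 1:  # deletion
            del out[rng.integers(0, len(out))]
        elif op == 1:  # insertion
            p = rng.integers(0, len(out) + 1)
            out.insert(p, alphabet[rng.integers(0, len(alphabet))])
        else:  # substitution to a different letter
            p = rng.integers(0, len(out))
            choices = [c for c in alphabet if c != out[p]]
            if choices:
                out[p] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def implant_rotation(t: Sequence, x: Sequence, position: int, rotation: int,
                     num_errors: int = 0, model: str = "hamming",
                     seed: int | np.random.Generator = 0,
                     ) -> tuple[Sequence, ImplantRecord]:
    """Overwrite a window of ``t`` with a mutated copy of ``x^rotation``.

    Under the Hamming model the window keeps length ``m`` and receives
    exactly ``num_errors`` substitutions.  Under the edit model the rotation
    is transformed by ``num_errors`` random single-letter edits before being
    spliced in (the text keeps its total length; the record's ``distance``
    is the number of edits applied, an upper bound on the true distance).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m, n = len(x), len(t)
    if not 0 <= rotation < m:
        raise InvalidInputError(f"rotation {rotation} out of range [0, {m})")
    alphabet = "".join(sorted(t.alphabet or set(t.letters) | set(x.letters)))
    rot = rotations(x)[rotation]
    if model == "hamming":
        implant = _mutate_hamming(rot, num_errors, alphabet, rng)
    elif model == "edit":
        implant = _mutate_edit(rot, num_errors, alphabet, rng)
    else:
        raise InvalidInputError(f"unknown model {model!r}")
    if position < 0 or position + len(implant) > n:
        raise InvalidInputError(
            f"implant window [{position}, {position + len(implant)}) does not "
            f"fit in a text of length {n}")
    letters = t.letters[:position] + implant + t.letters[position + len(implant):]
    rec = ImplantRecord(position=position, rotation=rotation,
                        distance=num_errors, model=model)
    return Sequence(letters=letters, id=t.id, alphabet=t.alphabet), rec


def generate_dataset(n: int, m: int, sigma=4, num_implants: int = 0,
                     errors_per_implant: int = 0, model: str = "hamming",
                     seed: int = 0,
                     ) -> tuple[Sequence, Sequence, list[ImplantRecord]]:
    """A random pattern, a random text with ``num_implants`` implanted
    rotated copies, and the ground-truth records.

    Implant windows are non-overlapping and separated by at least ``m``
    letters.  Raises if that packing cannot fit in ``n`` letters.
    """
    rng = np.random.default_rng(seed)
    alphabet = _alphabet(sigma)
    x = random_text(m, alphabet, rng, id=f"pattern_m{m}")
    t = random_text(n, alphabet, rng, id=f"text_n{n}")
    if num_implants == 0:
        return x, t, []
    # one implant per slot; slot size leaves >= m letters between windows
    slot = 3 * m + errors_per_implant
    if num_implants * slot > n:
        raise InvalidInputError(
            f"{num_implants} implants of pattern length {m} do not fit in a "
            f"text of length {n} with the required spacing")
    anchors = np.sort(rng.choice(n // slot, size=num_implants, replace=False))
    records: list[ImplantRecord] = []
    for a in anchors:
        position = int(a) * slot + int(rng.integers(0, m))
        rotation = int(rng.integers(0, m))
        t, rec = implant_rotation(t, x, position, rotation,
                                  num_errors=errors_per_implant,
                                  model=model, seed=rng)
        records.append(rec)
    return x, t, records
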