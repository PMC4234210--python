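"""FASTA input and tabular match output.

FASTA parsing is delegated to Biopython's ``SeqIO``; a light pre-scan adds
line-numbered diagnostics for the malformed inputs SeqIO is lenient about
(empty files, leading junk before the first header).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields
from pathlib import Path
from typing import IO, Iterable

from Bio import SeqIO

from .core import CircularMatch, InvalidInputError, Sequence


class FastaParseError(InvalidInputError):
    """Raised for files that are not usable FASTA."""


@dataclass(frozen=True)
class MatchRecord:
    """One serialised match row (TSV columns, in order)."""

    text_id: str
    pattern_id: str
    position: int
    rotation: int
    distance: int
    model: str


TSV_COLUMNS = [f.name for f in fields(MatchRecord)]


def read_fasta(path: str | Path) -> list[Sequence]:
    """All records of a FASTA file as :class:`Sequence` objects.

    Multi-line records are joined; letter case is preserved.  Raises
    :class:`FastaParseError` (with a line number where possible) on empty
    or malformed input.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: expected a '>' header, got {line.strip()[:30]!r}")
            break
        else:
            raise FastaParseError(f"{path}: empty FASTA file")
    seqs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FastaParseError(f"{path}: record {rec.id!r} has no sequence")
        seqs.append(Sequence(letters=str(rec.seq), id=rec.id))
    if not seqs:
        raise FastaParseError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seq: Sequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{seq.id or 'seq'}\n")
        for i in range(0, len(seq.letters), width):
            fh.write(seq.letters[i:i + width] + "\n")


def matches_to_records(matches: Iterable[CircularMatch], text_id: str,
                       pattern_id: str, model: str) -> list[MatchRecord]:
    return [MatchRecord(text_id=text_id, pattern_id=pattern_id,
                        position=cm.position, rotation=cm.rotation,
                        distance=cm.distance, model=model)
            for cm in matches]


def write_matches(records: Iterable[MatchRecord], stream: IO[str],
                  format: str = "tsv", match_length: int = 0,
                  one_based: bool = False) -> None:
    """Write match rows as TSV (with header) or 6-column BED.

    BED intervals are 0-based half-open ``[position, position + match
    length)``; the name column carries the rotation index and the score
    column the distance.  ``one_based`` shifts TSV positions (only) for
    display.
    """
    if format == "tsv":
        w = csv.writer(stream, delimiter="\t", lineterminator="\n")
        w.writerow(TSV_COLUMNS)
        for r in records:
            w.writerow([r.text_id, r.pattern_id,
                        r.position + (1 if one_based else 0),
                        r.rotation, r.distance, r.model])
    elif format == "bed":
        w = csv.writer(stream, delimiter="\t", lineterminator="\n")
        for r in records:
            w.writerow([r.text_id, r.position, r.position + match_length,
                        f"rot{r.rotation}", r.distance, "+"])
    else:
        raise InvalidInputError(f"unknown output format {format!r}")


def read_matches(stream: IO[str]) -> list[MatchRecord]:
    """Read back a TSV written by :func:`write_matches` (lossless)."""
    rd = csv.reader(stream, delimiter="\t")
    header = next(rd)
    if header != TSV_COLUMNS:
        raise InvalidInputError(f"unexpected TSV header {header!r}")
    return [MatchRecord(text_id=row[0], pattern_id=row[1], position=int(row[2]),
                        rotation=int(row[3]), distance=int(row[4]), model=row[5])
            for row in rd]
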