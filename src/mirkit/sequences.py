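"""Nucleotide sequences, alphabet handling, and strict FASTA I/O.

Every other module builds on :class:`NucSequence`, a small validated record
holding an id, an uppercase residue string over {A,C,G,T/U,N}, and a declared
DNA or RNA alphabet.  The ambiguity code N is accepted everywhere but is
treated conservatively downstream (it never satisfies a seed match).

Coordinate convention used throughout the package: positions are 1-based and
inclusive on the given (sense) strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Alphabet",
    "NucSequence",
    "AlphabetError",
    "FastaParseError",
    "reverse_complement",
    "coerce_alphabet",
    "read_fasta",
    "write_fasta",
]


class Alphabet(str, Enum):
    DNA = "DNA"
    RNA = "RNA"


class AlphabetError(ValueError):
    """Residues incompatible with the declared alphabet."""


class FastaParseError(ValueError):
    """Malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


_SYMBOLS = {Alphabet.DNA: frozenset("ACGTN"), Alphabet.RNA: frozenset("ACGUN")}
_COMPLEMENT = {
    Alphabet.DNA: str.maketrans("ACGTN", "TGCAN"),
    Alphabet.RNA: str.maketrans("ACGUN", "UGCAN"),
}


@dataclass(frozen=True)
class NucSequence:
    """An id-labelled DNA or RNA sequence.

    Lowercase input (soft-masking in UTR databases) is uppercased with a
    warning; masking information is intentionally discarded.
    """

    id: str
    residues: str
    alphabet: Alphabet = Alphabet.DNA

    def __post_init__(self) -> None:
        alphabet = Alphabet(self.alphabet)
        object.__setattr__(self, "alphabet", alphabet)
        residues = self.residues
        if residues != residues.upper():
            warnings.warn(
                f"sequence {self.id!r}: lowercase residues uppercased (masking ignored)",
                stacklevel=2,
            )
            residues = residues.upper()
            object.__setattr__(self, "residues", residues)
        bad = set(residues) - _SYMBOLS[alphabet]
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r}: symbols {sorted(bad)} invalid for {alphabet.value}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def slice1(self, start: int, end: int) -> str:
        """Residues over the 1-based inclusive span [start, end]."""
        if start < 1 or end > len(self.residues) or start > end:
            raise ValueError(
                f"span ({start}, {end}) outside sequence {self.id!r} of length {len(self)}"
            )
        return self.residues[start - 1 : end]


def reverse_complement(seq: NucSequence) -> NucSequence:
    """Reverse complement preserving the alphabet; N maps to N."""
    rc = seq.residues.translate(_COMPLEMENT[seq.alphabet])[::-1]
    return NucSequence(seq.id, rc, seq.alphabet)


def coerce_alphabet(seq: NucSequence, target: Alphabet | str) -> NucSequence:
    """Re-express a sequence in the target alphabet (T<->U); idempotent."""
    target = Alphabet(target)
    if target is seq.alphabet:
        return seq
    if target is Alphabet.RNA:
        residues = seq.residues.replace("T", "U")
    else:
        residues = seq.residues.replace("U", "T")
    return NucSequence(seq.id, residues, target)


def _iter_fasta(lines: Iterable[str]) -> Iterator[tuple[str, str, int]]:
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    lineno = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            if header is not None:
                yield header, "".join(chunks), header_line
            header = line[1:].split()[0] if line[1:].split() else ""
            if not header:
                raise FastaParseError("empty FASTA header", lineno)
            header_line = lineno
            chunks = []
        else:
            if header is None:
                raise FastaParseError("sequence data before first '>' header", lineno)
            chunks.append(line.strip())
    if header is not None:
        yield header, "".join(chunks), header_line


def read_fasta(path: str | Path, alphabet: Alphabet | str = Alphabet.DNA) -> list[NucSequence]:
    """Read a multi-record FASTA file into :class:`NucSequence` records.

    Order is preserved; duplicate ids and empty records are rejected with the
    offending line number.
    """
    alphabet = Alphabet(alphabet)
    records: list[NucSequence] = []
    seen: set[str] = set()
    with open(path) as handle:
        for name, residues, lineno in _iter_fasta(handle):
            if not residues:
                raise FastaParseError(f"record {name!r} has no sequence", lineno)
            if name in seen:
                raise FastaParseError(f"duplicate record id {name!r}", lineno)
            seen.add(name)
            records.append(NucSequence(name, residues, alphabet))
    return records


def write_fasta(records: Sequence[NucSequence], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapped at ``width`` columns (default 60)."""
    with open(path, "w") as handle:
        for rec in records:
            if not rec.id:
                raise ValueError("cannot write a record with an empty id")
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i : i + width] + "\n")
            if not rec.residues:
                handle.write("\n")
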