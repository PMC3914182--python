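"""Antisense (LNA-style) inhibitor design and verification for isomiR families.

IsomiRs of one miRNA share the 5' seed-bearing core but vary at the 3' end,
so a short inhibitor anchored at the seed (mature position 2 by default)
silences the whole family without discriminating between 3' variants.  The
design rule is pure Watson-Crick complementarity on the DNA representation
(T pairs U); no wobble pairing and no LNA chemistry modelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .sequences import Alphabet, NucSequence, coerce_alphabet, reverse_complement
from .target_prediction import MatureMirna

__all__ = [
    "IsomirFamily",
    "InhibitorReport",
    "design_inhibitor",
    "verify_inhibitor",
    "offtarget_screen",
]


@dataclass(frozen=True)
class IsomirFamily:
    """Mature isomiR variants sharing an identical 5' core span (1-based)."""

    id: str
    members: tuple[MatureMirna, ...]
    core_span: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("an isomiR family needs at least one member")
        start, end = self.core_span
        if start < 1 or start > end:
            raise ValueError(f"invalid core span {self.core_span}")
        reference = None
        for m in self.members:
            if end > len(m.sequence):
                raise ValueError(
                    f"core span {self.core_span} exceeds member {m.id!r} of length {len(m.sequence)}"
                )
            core = m.sequence.slice1(start, end)
            if reference is None:
                reference = core
            elif core != reference:
                raise ValueError(f"member {m.id!r} differs from the family core over {self.core_span}")


@dataclass(frozen=True)
class InhibitorReport:
    """Complementarity of one oligo against one mature sequence."""

    oligo: str
    mirna_id: str
    match_start: int  # 1-based on the mature sequence
    match_len: int
    covers_seed: bool
    full_match: bool


def _revcomp_dna(rna_fragment: str) -> str:
    frag = NucSequence("frag", rna_fragment, Alphabet.RNA if "U" in rna_fragment else Alphabet.DNA)
    return coerce_alphabet(reverse_complement(frag), Alphabet.DNA).residues


def design_inhibitor(family: IsomirFamily, length: int = 13, anchor_start: int = 2) -> NucSequence:
    """DNA reverse complement of mature positions [anchor, anchor+length-1].

    The span must sit inside the family's shared core so the oligo is
    identical against every member; the error names the first member whose
    core the span exits.
    """
    if length < 1:
        raise ValueError("inhibitor length must be positive")
    span_end = anchor_start + length - 1
    core_start, core_end = family.core_span
    if anchor_start < core_start or span_end > core_end:
        for m in family.members:
            if span_end > len(m.sequence):
                raise ValueError(
                    f"span ({anchor_start}, {span_end}) exits member {m.id!r} (length {len(m.sequence)})"
                )
        raise ValueError(
            f"span ({anchor_start}, {span_end}) exits the shared core {family.core_span} "
            f"of family {family.id!r}"
        )
    mature = family.members[0].sequence
    oligo = _revcomp_dna(mature.slice1(anchor_start, span_end))
    return NucSequence(f"{family.id}-inhibitor", oligo, Alphabet.DNA)


def verify_inhibitor(oligo: NucSequence | str, mirna: MatureMirna) -> InhibitorReport:
    """Longest contiguous mature stretch complementary to a window of the oligo.

    All (start, length) substrings of the mature sequence are tested; a
    stretch counts when its DNA reverse complement occurs contiguously inside
    the oligo.  The longest match wins (smallest start on ties), and the
    full-match flag is set when the entire oligo is the complement of the
    matched stretch.  ``covers_seed`` reports whether the matched mature span
    contains the seed (mirna.seed_span).
    """
    oligo_str = str(oligo).upper().replace("U", "T")
    if not oligo_str:
        raise ValueError("empty oligo")
    mature = mirna.sequence.residues
    best_start, best_len = 0, 0
    for start in range(1, len(mature) + 1):
        for end in range(start, len(mature) + 1):
            length = end - start + 1
            if length <= best_len or length > len(oligo_str):
                continue
            if _revcomp_dna(mature[start - 1 : end]) in oligo_str:
                best_start, best_len = start, length
    seed_start, seed_end = mirna.seed_span
    covers_seed = best_len > 0 and best_start <= seed_start and best_start + best_len - 1 >= seed_end
    full_match = best_len == len(oligo_str)
    return InhibitorReport(oligo_str, mirna.id, best_start, best_len, covers_seed, full_match)


def offtarget_screen(oligo: NucSequence | str, panel: Sequence[MatureMirna]) -> list[str]:
    """Panel members whose seed is fully complementary to some oligo window.

    Returns ids in panel order; a miRNA hits when the DNA reverse complement
    of its seed region occurs contiguously in the oligo.  The cognate miRNA
    of a seed-anchored inhibitor always appears.
    """
    if not panel:
        raise ValueError("empty miRNA panel")
    oligo_str = str(oligo).upper().replace("U", "T")
    hits: list[str] = []
    for mirna in panel:
        seed = mirna.sequence.slice1(*mirna.seed_span)
        if _revcomp_dna(seed) in oligo_str:
            hits.append(mirna.id)
    return hits
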