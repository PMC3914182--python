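"""Seed-match miRNA target prediction on 3'UTR pools.

A UTR is called a target when it carries at least one perfect match to the
reverse complement of the miRNA seed (mature nucleotides 2-7).  The default
and canonical site class is the plain 6mer; 7mer-m8 (pairing extended to
mature position 8), 7mer-A1 (an A opposite mature position 1), and 8mer
(both) are available as stricter extensions.  Ambiguous bases (N) never
match.  Ortholog mapping and the conserved-target fraction against a
reference list round out the stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .sequences import Alphabet, NucSequence, coerce_alphabet, reverse_complement

__all__ = [
    "SITE_TYPES",
    "MatureMirna",
    "SeedSite",
    "TargetSet",
    "OrthologMap",
    "ConservedFraction",
    "site_sequence",
    "scan_utrs",
    "map_orthologs",
    "conserved_fraction",
]

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")


@dataclass(frozen=True)
class MatureMirna:
    """A mature miRNA with its seed span (1-based on the mature, default 2-7)."""

    id: str
    sequence: NucSequence
    seed_span: tuple[int, int] = (2, 7)

    def __post_init__(self) -> None:
        start, end = self.seed_span
        if start < 1 or end > len(self.sequence) or start > end:
            raise ValueError(
                f"seed span {self.seed_span} outside mature sequence of length {len(self.sequence)}"
            )

    @classmethod
    def from_sequence(cls, id: str, residues: str, seed_span: tuple[int, int] = (2, 7)) -> "MatureMirna":
        seq = NucSequence(id, residues, Alphabet.RNA if "U" in residues else Alphabet.DNA)
        return cls(id, coerce_alphabet(seq, Alphabet.RNA), seed_span)


@dataclass(frozen=True)
class SeedSite:
    utr_id: str
    start: int  # 1-based position of the first matched base on the UTR
    site_type: str
    matched_seq: str


@dataclass
class TargetSet:
    """Seed sites per UTR and the derived target set (UTRs with >= 1 site)."""

    scanned_ids: list[str]
    sites: list[SeedSite]
    site_types: tuple[str, ...]

    @property
    def n_scanned(self) -> int:
        return len(self.scanned_ids)

    @property
    def sites_by_utr(self) -> dict[str, list[SeedSite]]:
        out: dict[str, list[SeedSite]] = {u: [] for u in self.scanned_ids}
        for s in self.sites:
            out[s.utr_id].append(s)
        return out

    @property
    def target_ids(self) -> list[str]:
        hit = {s.utr_id for s in self.sites}
        return [u for u in self.scanned_ids if u in hit]

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)


@dataclass
class OrthologMap:
    """source_id -> ortholog_id mapping; first occurrence wins on duplicates."""

    mapping: dict[str, str]
    duplicates: list[str] = field(default_factory=list)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str]]) -> "OrthologMap":
        mapping: dict[str, str] = {}
        duplicates: list[str] = []
        for source, ortholog in rows:
            if source in mapping:
                duplicates.append(source)
                continue
            mapping[source] = ortholog
        return cls(mapping, duplicates)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthologMap":
        rows = []
        with open(path) as handle:
            for line in handle:
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"ortholog map row needs two columns: {line!r}")
                rows.append((parts[0].strip(), parts[1].strip()))
        return cls.from_rows(rows)


@dataclass(frozen=True)
class ConservedFraction:
    overlap: int
    denominator: int
    percent: float  # unrounded
    percent_rounded: int  # half-up to the nearest whole percent
    overlapping_ids: tuple[str, ...] = ()


def site_sequence(mirna: MatureMirna, site_type: str = "6mer") -> NucSequence:
    """The UTR-strand (DNA) match string for a seed-site class.

    The 6mer is the reverse complement of mature seed positions (default
    2-7); 7mer-m8 extends complementary pairing to mature position 8;
    7mer-A1 and 8mer append an A opposite mature position 1 (the 3' end of
    the site on the UTR).
    """
    if site_type not in SITE_TYPES:
        raise ValueError(f"unknown site type {site_type!r}; expected one of {SITE_TYPES}")
    start, end = mirna.seed_span
    pair_end = end + 1 if site_type in ("7mer-m8", "8mer") else end
    if pair_end > len(mirna.sequence):
        raise ValueError(f"site type {site_type!r} needs mature position {pair_end}")
    core = NucSequence(mirna.id, mirna.sequence.slice1(start, pair_end), mirna.sequence.alphabet)
    match = coerce_alphabet(reverse_complement(core), Alphabet.DNA).residues
    if site_type in ("7mer-A1", "8mer"):
        match = match + "A"
    return NucSequence(f"{mirna.id}|{site_type}", match, Alphabet.DNA)


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) 0-based occurrence starts."""
    hits = []
    pos = haystack.find(needle)
    while pos != -1:
        hits.append(pos)
        pos = haystack.find(needle, pos + 1)
    return hits


def scan_utrs(
    utrs: Sequence[NucSequence],
    mirna: MatureMirna,
    site_types: Sequence[str] = ("6mer",),
) -> TargetSet:
    """Scan UTRs (sense strand only) for seed sites of the requested classes.

    Every occurrence is reported, including overlapping ones; output order is
    UTR order, then position, then site-type order as requested.
    """
    if not utrs:
        raise ValueError("empty UTR set")
    if not site_types:
        raise ValueError("at least one site type must be requested")
    site_strings = [(t, site_sequence(mirna, t).residues) for t in site_types]
    sites: list[SeedSite] = []
    for utr in utrs:
        residues = coerce_alphabet(utr, Alphabet.DNA).residues
        found: list[SeedSite] = []
        for site_type, needle in site_strings:
            for pos in _find_all(residues, needle):
                found.append(SeedSite(utr.id, pos + 1, site_type, needle))
        found.sort(key=lambda s: (s.start, site_types.index(s.site_type)))
        sites.extend(found)
    return TargetSet([u.id for u in utrs], sites, tuple(site_types))


def map_orthologs(targets: TargetSet | Sequence[str], omap: OrthologMap) -> tuple[list[str], list[str]]:
    """Map target ids through an ortholog table.

    Returns (mapped ortholog ids in target order, unmapped source ids).
    Missing mappings are data, not errors.
    """
    ids = targets.target_ids if isinstance(targets, TargetSet) else list(targets)
    mapped: list[str] = []
    unmapped: list[str] = []
    for src in ids:
        if src in omap.mapping:
            mapped.append(omap.mapping[src])
        else:
            unmapped.append(src)
    return mapped, unmapped


def _norm(gene_id: str) -> str:
    return gene_id.strip().lower()


def conserved_fraction(
    targets: TargetSet | Sequence[str] | int,
    reference_list: Sequence[str] | None = None,
    denominator: int | None = None,
) -> ConservedFraction:
    """Overlap with a reference conserved-target list, as a whole percent.

    ``targets`` may be a :class:`TargetSet`, an explicit id list (matched to
    the reference case-insensitively), or an already-counted overlap (int,
    requiring ``denominator``).  The percentage is 100 * overlap/denominator
    with half-up rounding; the unrounded value is also returned.
    """
    if isinstance(targets, int):
        if denominator is None:
            raise ValueError("an explicit overlap count needs an explicit denominator")
        overlap, overlap_ids = targets, ()
    else:
        ids = targets.target_ids if isinstance(targets, TargetSet) else list(targets)
        if reference_list is None:
            raise ValueError("a reference conserved-target list is required")
        if denominator is None:
            denominator = len(ids)
        ref = {_norm(r) for r in reference_list}
        overlap_ids = tuple(i for i in ids if _norm(i) in ref)
        overlap = len(overlap_ids)
    if denominator <= 0:
        raise ValueError("conserved fraction needs a positive denominator")
    percent = 100.0 * overlap / denominator
    import math

    rounded = int(math.floor(percent + 0.5))
    return ConservedFraction(overlap, denominator, percent, rounded, overlap_ids)
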