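"""Ortholog pre-miRNA alignment and region-wise conservation profiling.

A family of pre-miRNA hairpin orthologs (70-90 nt, typically <= 20 species) is
aligned with a center-star progressive strategy built on a Needleman-Wunsch
pairwise core, and conservation is summarised per alignment column and per
annotated hairpin region (mature strand, star strand, loop).  The expected
biological signature is complete conservation of the mature strand, high
conservation of the star strand, and weak conservation of the loop.

The aligner is deliberately small: global alignment with linear gap costs and
a fixed traceback preference (diagonal, then up, then left) so results are
deterministic.  Heavyweight aligners buy nothing at these sequence lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .sequences import NucSequence

__all__ = [
    "RegionAnnotation",
    "Msa",
    "ConservationProfile",
    "pairwise_align",
    "progressive_msa",
    "conservation_profile",
    "region_conservation",
]

GAP = "-"


@dataclass(frozen=True)
class RegionAnnotation:
    """Hairpin regions on one reference sequence, 1-based inclusive."""

    reference_id: str
    regions: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        spans = sorted(self.regions.items(), key=lambda kv: kv[1])
        for name, (start, end) in spans:
            if start < 1 or start > end:
                raise ValueError(f"region {name!r}: invalid span ({start}, {end})")
        for (na, (_, ea)), (nb, (sb, _)) in zip(spans, spans[1:]):
            if sb <= ea:
                raise ValueError(f"regions {na!r} and {nb!r} overlap")
        if "mature" in self.regions:
            s, e = self.regions["mature"]
            if e - s + 1 < 18:
                raise ValueError("mature region shorter than 18 nt")


@dataclass(frozen=True)
class Msa:
    """A gapped multiple sequence alignment; all rows equal length."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    alphabet: str = "DNA"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def ncol(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, row_id: str) -> str:
        return self.rows[self.ids.index(row_id)].replace(GAP, "")


@dataclass
class ConservationProfile:
    """Per-column conservation scores and gap statistics.

    ``scores`` holds the modal-residue fraction (or an entropy-based score) in
    [0, 1]; columns that are entirely gaps carry NaN and are flagged.
    ``flagged`` marks columns with gap fraction > 0.5 or no residues at all.
    """

    scores: np.ndarray
    gap_fraction: np.ndarray
    flagged: np.ndarray
    metric: str = "modal"
    region_means: dict[str, float] = field(default_factory=dict)


def pairwise_align(
    a: NucSequence,
    b: NucSequence,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> tuple[str, str, float]:
    """Optimal global (Needleman-Wunsch) alignment of two sequences.

    Returns the two gapped strings and the optimal score.  Traceback ties are
    broken diagonal > up > left for determinism.
    """
    sa, sb = a.residues, b.residues
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    for p in (match, mismatch, gap):
        if not np.isfinite(p):
            raise ValueError("alignment score parameters must be finite")
    n, m = len(sa), len(sb)
    F = np.empty((n + 1, m + 1))
    F[0, :] = gap * np.arange(m + 1)
    F[:, 0] = gap * np.arange(n + 1)
    for i in range(1, n + 1):
        ci = sa[i - 1]
        prev, cur = F[i - 1], F[i]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match if ci == sb[j - 1] else mismatch)
            up = prev[j] + gap
            left = cur[j - 1] + gap
            cur[j] = diag if diag >= up and diag >= left else (up if up >= left else left)
    # traceback, preferring diagonal, then up (gap in b), then left (gap in a)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            diag = F[i - 1, j - 1] + (match if sa[i - 1] == sb[j - 1] else mismatch)
            if F[i, j] == diag:
                out_a.append(sa[i - 1])
                out_b.append(sb[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and F[i, j] == F[i - 1, j] + gap:
            out_a.append(sa[i - 1])
            out_b.append(GAP)
            i -= 1
            continue
        out_a.append(GAP)
        out_b.append(sb[j - 1])
        j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(F[n, m])


def _kmer_set(s: str, k: int = 3) -> set[str]:
    return {s[i : i + k] for i in range(len(s) - k + 1)}


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka, kb = _kmer_set(a, k), _kmer_set(b, k)
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def progressive_msa(
    family: Sequence[NucSequence],
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> Msa:
    """Center-star progressive alignment of an ortholog family.

    The center is the sequence minimising the summed k-mer distance to all
    others (ties broken by input order); every other sequence is aligned to
    the center pairwise and merged under "once a gap, always a gap".
    Deterministic given input order.
    """
    if len(family) < 2:
        raise ValueError("progressive alignment needs at least two sequences")
    alphabets = {s.alphabet for s in family}
    if len(alphabets) > 1:
        raise ValueError("family sequences must share one alphabet")
    dist = np.zeros((len(family), len(family)))
    for i in range(len(family)):
        for j in range(i + 1, len(family)):
            d = _kmer_distance(family[i].residues, family[j].residues)
            dist[i, j] = dist[j, i] = d
    center_idx = int(np.argmin(dist.sum(axis=1)))
    center = family[center_idx]
    others = [s for k, s in enumerate(family) if k != center_idx]

    # Merge pairwise alignments against the center under "once a gap, always
    # a gap": walk the master center row and the freshly aligned center row
    # together, inserting gap columns wherever one has a gap the other lacks.
    master_center = center.residues
    aligned_rows: list[str] = []  # rows for `others`, in their order
    for seq in others:
        c_aln, s_aln, _ = pairwise_align(center, seq, match, mismatch, gap)
        new_master: list[str] = []
        new_old = [list() for _ in aligned_rows]  # type: list[list[str]]
        new_row: list[str] = []
        i = j = 0
        while i < len(master_center) or j < len(c_aln):
            mc = master_center[i] if i < len(master_center) else None
            pc = c_aln[j] if j < len(c_aln) else None
            if mc is not None and pc is not None and mc != GAP and pc != GAP:
                new_master.append(mc)
                for r, acc in zip(aligned_rows, new_old):
                    acc.append(r[i])
                new_row.append(s_aln[j])
                i += 1
                j += 1
            elif mc == GAP and pc == GAP:
                new_master.append(GAP)
                for r, acc in zip(aligned_rows, new_old):
                    acc.append(r[i])
                new_row.append(s_aln[j])
                i += 1
                j += 1
            elif mc == GAP:  # gap only in the master: new sequence gets a gap
                new_master.append(GAP)
                for r, acc in zip(aligned_rows, new_old):
                    acc.append(r[i])
                new_row.append(GAP)
                i += 1
            else:  # gap only in the pairwise row: existing rows get a gap
                new_master.append(GAP)
                for acc in new_old:
                    acc.append(GAP)
                new_row.append(s_aln[j])
                j += 1
        master_center = "".join(new_master)
        aligned_rows = ["".join(acc) for acc in new_old]
        aligned_rows.append("".join(new_row))

    ids = [center.id] + [s.id for s in others]
    rows = [master_center] + aligned_rows
    order = {s.id: k for k, s in enumerate(family)}
    paired = sorted(zip(ids, rows), key=lambda t: order[t[0]])
    msa = Msa(tuple(i for i, _ in paired), tuple(r for _, r in paired), family[0].alphabet.value)
    for seq in family:  # degap invariant, cheap at these sizes
        if msa.degapped(seq.id) != seq.residues:
            raise AssertionError(f"alignment corrupted sequence {seq.id!r}")
    return msa


def conservation_profile(msa: Msa, metric: str = "modal") -> ConservationProfile:
    """Column-wise conservation of an alignment.

    ``modal`` (default): fraction of non-gap residues equal to the modal
    residue, matching a conserved/not-conserved presentation.  ``entropy``:
    1 - H/2 with H the Shannon entropy (bits) of the non-gap residues.
    All-gap columns score NaN and are flagged, as are columns with gap
    fraction above 0.5.
    """
    if metric not in ("modal", "entropy"):
        raise ValueError(f"unknown conservation metric {metric!r}")
    nrow, ncol = len(msa.rows), msa.ncol
    scores = np.full(ncol, np.nan)
    gap_fraction = np.zeros(ncol)
    flagged = np.zeros(ncol, dtype=bool)
    for c in range(ncol):
        column = [row[c] for row in msa.rows]
        residues = [x for x in column if x != GAP]
        gap_fraction[c] = 1.0 - len(residues) / nrow
        if not residues:
            flagged[c] = True
            continue
        if gap_fraction[c] > 0.5:
            flagged[c] = True
        counts = np.array([residues.count(x) for x in sorted(set(residues))], dtype=float)
        if metric == "modal":
            scores[c] = counts.max() / counts.sum()
        else:
            p = counts / counts.sum()
            h = float(-(p * np.log2(p)).sum())
            scores[c] = max(0.0, 1.0 - h / 2.0)
    return ConservationProfile(scores, gap_fraction, flagged, metric)


def region_conservation(
    msa: Msa,
    profile: ConservationProfile,
    annot: RegionAnnotation,
) -> tuple[dict[str, float], list[str]]:
    """Mean conservation per annotated region, plus regions ranked high-to-low.

    Region coordinates live on the (ungapped) reference sequence and are
    projected through its aligned row onto alignment columns.  All-gap
    columns (flagged NaN) are excluded from the means.
    """
    if annot.reference_id not in msa.ids:
        raise ValueError(f"reference {annot.reference_id!r} not in alignment")
    ref_row = msa.rows[msa.ids.index(annot.reference_id)]
    ref_len = len(ref_row) - ref_row.count(GAP)
    pos_to_col: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(ref_row):
        if ch != GAP:
            pos += 1
            pos_to_col[pos] = col
    means: dict[str, float] = {}
    for name, (start, end) in annot.regions.items():
        if start < 1 or end > ref_len:
            raise ValueError(
                f"region {name!r} span ({start}, {end}) outside reference length {ref_len}"
            )
        cols = [pos_to_col[p] for p in range(start, end + 1)]
        vals = profile.scores[cols]
        vals = vals[~np.isnan(vals)]
        means[name] = float(vals.mean()) if len(vals) else float("nan")
    profile.region_means = dict(means)
    ranking = sorted(means, key=lambda k: (-means[k], k))
    return means, ranking
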