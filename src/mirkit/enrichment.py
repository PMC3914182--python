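"""Gene-set (sub-network) enrichment against a background score distribution.

Each gene set is compared to the rest of the gene universe with a two-sided
Mann-Whitney U test on the per-gene scores (exact by enumeration for small,
tie-free problems; tie-corrected normal approximation otherwise), with a
hypergeometric over-representation p-value alongside when scores are binary
target membership.  Sets are ranked by the U-test p-value; the significance
flag uses the raw p-value at alpha (the customary sub-network-enrichment
filter), with Benjamini-Hochberg q-values reported alongside.

Gene identifiers are matched case-insensitively after whitespace trimming,
which absorbs most of the noise in cross-species symbol mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneUniverse",
    "GeneSet",
    "GeneSetCollection",
    "EnrichmentResult",
    "mwu_test",
    "hypergeom_test",
    "bh_adjust",
    "snea",
]

EXACT_MWU_MAX_N = 12  # full enumeration below this combined group size


def _norm(gene_id: str) -> str:
    return gene_id.strip().lower()


@dataclass
class GeneUniverse:
    """Gene ids with a per-gene score (binary membership or continuous)."""

    ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.ids) != len(self.scores):
            raise ValueError("ids and scores differ in length")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("universe scores must be finite")
        normed = [_norm(i) for i in self.ids]
        if len(set(normed)) != len(normed):
            raise ValueError("duplicate gene ids in universe (after normalization)")
        self._index = {n: k for k, n in enumerate(normed)}

    def __len__(self) -> int:
        return len(self.ids)

    def lookup(self, gene_id: str) -> int | None:
        return self._index.get(_norm(gene_id))

    @property
    def is_binary(self) -> bool:
        return bool(np.all(np.isin(self.scores, (0.0, 1.0))))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneUniverse":
        ids, scores = [], []
        with open(path) as handle:
            for line in handle:
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                gene, score = line.split("\t")[:2]
                ids.append(gene.strip())
                scores.append(float(score))
        return cls(ids, np.array(scores))


@dataclass(frozen=True)
class GeneSet:
    id: str
    description: str
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        sets = []
        with open(path) as handle:
            for line in handle:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"GMT row needs id, description, members: {line!r}")
                sets.append(GeneSet(parts[0], parts[1], tuple(p for p in parts[2:] if p.strip())))
        return cls(sets)

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for s in self.sets:
                handle.write("\t".join([s.id, s.description, *s.members]) + "\n")


@dataclass
class EnrichmentResult:
    set_id: str
    n_members: int  # members intersected with the universe
    n_background: int
    u_statistic: float  # U for the member group
    p_mwu: float
    p_hyper: float | None
    q: float = float("nan")  # BH-adjusted p_mwu
    significant: bool = False


def mwu_test(member_scores: Sequence[float], background_scores: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; U is reported for the member group.

    Exact p by enumeration of rank assignments when n1 + n2 <= 12 and the
    pooled scores are tie-free; tie-corrected normal approximation otherwise.
    Degenerate all-identical input yields U = n1*n2/2 and p = 1.
    """
    x = np.asarray(member_scores, dtype=float)
    y = np.asarray(background_scores, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return x.size * y.size / 2.0, 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= EXACT_MWU_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def hypergeom_test(k_overlap: int, set_size: int, n_targets: int, universe_size: int) -> float:
    """Upper-tail P(X >= k) under sampling without replacement."""
    if not (0 <= k_overlap <= min(set_size, n_targets)):
        raise ValueError("overlap exceeds a margin")
    if set_size > universe_size or n_targets > universe_size:
        raise ValueError("margins exceed the universe size")
    return float(stats.hypergeom.sf(k_overlap - 1, universe_size, n_targets, set_size))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def snea(
    universe: GeneUniverse,
    sets: GeneSetCollection | Iterable[GeneSet],
    alpha: float = 0.05,
    min_set_size: int = 3,
) -> tuple[list[EnrichmentResult], list[str]]:
    """Score every gene set against the background and rank by MWU p-value.

    The background for each set is the universe minus the set's members
    (disjoint competitive test).  Sets with fewer than ``min_set_size``
    members in the universe are excluded and returned in the skip list.
    Significance is the raw p_mwu < alpha; BH q-values are reported alongside.
    """
    if len(universe) == 0:
        raise ValueError("empty gene universe")
    binary = universe.is_binary
    n_targets = int(universe.scores.sum()) if binary else 0
    results: list[EnrichmentResult] = []
    skipped: list[str] = []
    for gene_set in sets:
        idx = sorted({i for g in gene_set.members if (i := universe.lookup(g)) is not None})
        if len(idx) < min_set_size:
            skipped.append(gene_set.id)
            continue
        mask = np.zeros(len(universe), dtype=bool)
        mask[idx] = True
        member_scores = universe.scores[mask]
        background_scores = universe.scores[~mask]
        if background_scores.size == 0:
            skipped.append(gene_set.id)
            continue
        u, p = mwu_test(member_scores, background_scores)
        p_hyper = (
            hypergeom_test(int(member_scores.sum()), len(idx), n_targets, len(universe))
            if binary
            else None
        )
        results.append(EnrichmentResult(gene_set.id, len(idx), int(background_scores.size), u, p, p_hyper))
    if not results:
        raise ValueError("no gene set survived the minimum-size filter")
    qs = bh_adjust([r.p_mwu for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
        r.significant = r.p_mwu < alpha
    results.sort(key=lambda r: (r.p_mwu, r.set_id))
    return results, skipped
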