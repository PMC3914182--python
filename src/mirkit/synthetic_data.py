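"""Ground-truth simulators for every input the pipeline consumes.

Each simulator is a pure function of its config (which carries the RNG seed)
and returns both the dataset and a :class:`SimTruth` record of what was
planted, so recovery can be tested exactly:

* ``simulate_utrs`` - a 3'UTR pool with a fixed fraction of target UTRs
  carrying planted seed sites; non-target UTRs are rejection-sampled to be
  site-free ("clean" background) so recall and precision are exact, or left
  as raw random sequence ("natural") for analytic background-rate checks.
  Defaults mirror the rainbow trout screen: 1059 UTRs, 83 of them targets.
* ``simulate_family`` - a star-phylogeny ortholog family of pre-miRNA
  hairpins with independent per-site substitutions at region-specific rates
  (mature 0, star low, loop high by default), emulating the conservation
  gradient of a real hairpin.
* ``simulate_geneset_universe`` - a scored gene universe plus gene sets,
  some with a planted score shift (enrichment factor 1 = null).
* ``simulate_assay`` - qPCR Ct tables and plasma-metabolite tables for a
  saline / low-dose / high-dose design (n = 6 per group) with planted
  per-gene fold changes and per-analyte percent changes; the analyte
  defaults encode the study system's reported directions (glucose +62/+67%,
  triglycerides -36% and free fatty acids -46% at the high dose,
  cholesterol -20% at both doses).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conservation import RegionAnnotation
from .sequences import Alphabet, NucSequence

__all__ = [
    "SimTruth",
    "UtrSimConfig",
    "FamilySimConfig",
    "GenesetSimConfig",
    "AssaySimConfig",
    "simulate_utrs",
    "simulate_family",
    "simulate_geneset_universe",
    "simulate_assay",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimTruth:
    """What a simulator planted, alongside the seed and a config hash."""

    kind: str
    seed: int
    config_hash: str
    payload: dict

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=2, default=_jsonable)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as handle:
            raw = json.load(handle)
        return cls(**raw)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _config_hash(cfg) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=_jsonable).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _random_seqs(rng: np.random.Generator, lengths: np.ndarray, composition: np.ndarray) -> list[str]:
    """Batch-generate random nucleotide strings with the given composition."""
    total = int(lengths.sum())
    codes = rng.choice(4, size=total, p=composition)
    blob = _BASES[codes].tobytes().decode()
    out = []
    offset = 0
    for length in lengths:
        out.append(blob[offset : offset + int(length)])
        offset += int(length)
    return out


# ---------------------------------------------------------------- UTR pools


@dataclass
class UtrSimConfig:
    """A 3'UTR pool with planted seed sites.

    Defaults reproduce the trout screen's bookkeeping: 1059 UTRs of which
    83 (fraction 83/1059) carry a site.
    """

    n_utrs: int = 1059
    length_range: tuple[int, int] = (200, 1500)
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    planted_target_fraction: float = 83 / 1059
    sites_per_target: int = 1
    background: str = "clean"  # "clean": rejection-sampled site-free; "natural": raw random
    max_retries: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.planted_target_fraction <= 1.0:
            raise ValueError("planted_target_fraction must lie in [0, 1]")
        if self.length_range[0] < 6 or self.length_range[0] > self.length_range[1]:
            raise ValueError("UTR lengths must be >= 6 with min <= max")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")
        if self.background not in ("clean", "natural"):
            raise ValueError("background must be 'clean' or 'natural'")


def simulate_utrs(cfg: UtrSimConfig, site_seq: str) -> tuple[list[NucSequence], SimTruth]:
    """Simulate a UTR pool with ``site_seq`` planted into a known subset.

    Exactly round(fraction * n_utrs) UTRs receive ``sites_per_target``
    non-overlapping planted copies at recorded 1-based positions.  With the
    "clean" background, every other UTR (and the pre-insertion backbone of
    target UTRs) is rejection-sampled to contain zero occurrences.
    """
    site = site_seq.upper()
    k = len(site)
    if k == 0 or k > cfg.length_range[0]:
        raise ValueError("site length must be in [1, min UTR length]")
    rng = np.random.default_rng(cfg.seed)
    comp = np.asarray(cfg.base_composition, dtype=float)
    lengths = rng.integers(cfg.length_range[0], cfg.length_range[1] + 1, cfg.n_utrs)
    n_targets = int(round(cfg.planted_target_fraction * cfg.n_utrs))
    if cfg.sites_per_target * (2 * k - 1) > cfg.length_range[0] and n_targets:
        raise ValueError("UTRs too short for the requested number of planted sites")
    target_idx = set(rng.choice(cfg.n_utrs, size=n_targets, replace=False).tolist())

    seqs = _random_seqs(rng, lengths, comp)
    if cfg.background == "clean":
        pending = [i for i, s in enumerate(seqs) if site in s]
        retries = 0
        while pending:
            retries += 1
            if retries > cfg.max_retries:
                raise RuntimeError(
                    f"rejection sampling failed: {len(pending)} UTRs still contain the site "
                    f"after {cfg.max_retries} rounds"
                )
            fresh = _random_seqs(rng, lengths[pending], comp)
            for i, s in zip(pending, fresh):
                seqs[i] = s
            pending = [i for i in pending if site in seqs[i]]

    width = len(str(cfg.n_utrs))
    records: list[NucSequence] = []
    planted: dict[str, list[int]] = {}
    for i, s in enumerate(seqs):
        utr_id = f"utr_{i + 1:0{width}d}"
        if i in target_idx:
            positions: list[int] = []
            length = len(s)
            attempts = 0
            while len(positions) < cfg.sites_per_target:
                attempts += 1
                if attempts > 1000 * cfg.sites_per_target:
                    raise RuntimeError(f"could not place non-overlapping sites in {utr_id}")
                pos = int(rng.integers(0, length - k + 1))
                if all(abs(pos - q) >= k for q in positions):
                    positions.append(pos)
            chars = list(s)
            for pos in positions:
                chars[pos : pos + k] = site
            s = "".join(chars)
            planted[utr_id] = sorted(p + 1 for p in positions)
        records.append(NucSequence(utr_id, s, Alphabet.DNA))

    truth = SimTruth(
        "utr_pool",
        cfg.seed,
        _config_hash(cfg),
        {
            "site_seq": site,
            "target_ids": sorted(planted),
            "planted_positions": planted,
            "n_targets": n_targets,
        },
    )
    return records, truth


# -------------------------------------------------------- ortholog families


@dataclass
class FamilySimConfig:
    """Star-phylogeny pre-miRNA hairpin family with region-specific rates.

    The default annotation lays out a 5'-arm mature strand, loop, and 3'-arm
    star strand partitioning an 80-nt hairpin; the default rates encode the
    observed conservation gradient (mature fully conserved, star nearly so,
    loop weakly).
    """

    n_species: int = 15
    ancestor_length: int = 80
    mature: tuple[int, int] = (1, 23)
    loop: tuple[int, int] = (24, 57)
    star: tuple[int, int] = (58, 80)
    mu_mature: float = 0.0
    mu_star: float = 0.05
    mu_loop: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        for mu in (self.mu_mature, self.mu_star, self.mu_loop):
            if not 0.0 <= mu < 1.0:
                raise ValueError("substitution rates must lie in [0, 1)")
        spans = sorted([self.mature, self.loop, self.star])
        if spans[0][0] != 1 or spans[-1][1] != self.ancestor_length:
            raise ValueError("regions must span the full ancestor length")
        for (_, ea), (sb, _) in zip(spans, spans[1:]):
            if sb != ea + 1:
                raise ValueError("regions must partition the ancestor without gaps or overlap")


def simulate_family(
    cfg: FamilySimConfig,
) -> tuple[list[NucSequence], RegionAnnotation, SimTruth]:
    """Simulate ortholog hairpins by i.i.d. substitution from one ancestor.

    Each species independently substitutes each site with its region's rate
    (replacement drawn uniformly from the three other bases).  The first
    species carries the region annotation (no indels are simulated, so
    ancestor coordinates hold for every species).
    """
    rng = np.random.default_rng(cfg.seed)
    length = cfg.ancestor_length
    rates = np.empty(length)
    for (start, end), mu in (
        (cfg.mature, cfg.mu_mature),
        (cfg.loop, cfg.mu_loop),
        (cfg.star, cfg.mu_star),
    ):
        rates[start - 1 : end] = mu
    ancestor = rng.choice(4, size=length)
    records: list[NucSequence] = []
    n_subs = np.zeros(cfg.n_species, dtype=int)
    for s in range(cfg.n_species):
        hit = rng.random(length) < rates
        offsets = rng.integers(1, 4, size=length)
        derived = np.where(hit, (ancestor + offsets) % 4, ancestor)
        n_subs[s] = int(hit.sum())
        records.append(
            NucSequence(f"species_{s + 1:02d}", _BASES[derived].tobytes().decode(), Alphabet.DNA)
        )
    annot = RegionAnnotation(
        records[0].id, {"mature": cfg.mature, "loop": cfg.loop, "star": cfg.star}
    )
    truth = SimTruth(
        "premirna_family",
        cfg.seed,
        _config_hash(cfg),
        {
            "ancestor": _BASES[ancestor].tobytes().decode(),
            "rates": {"mature": cfg.mu_mature, "star": cfg.mu_star, "loop": cfg.mu_loop},
            "n_substitutions": n_subs.tolist(),
        },
    )
    return records, annot, truth


# ------------------------------------------------------- gene-set universes


@dataclass
class GenesetSimConfig:
    """Scored gene universe with optionally enriched gene sets.

    ``enrichment_factor`` = 1 is the null; above 1, members of the planted
    sets get a score shift of (factor - 1) in the continuous mode, or a
    membership probability multiplied by the factor in the binary mode.
    """

    n_genes: int = 2000
    n_sets: int = 50
    set_size_range: tuple[int, int] = (10, 40)
    n_enriched: int = 5
    enrichment_factor: float = 3.0
    score_kind: str = "continuous"  # or "binary"
    baseline_target_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.enrichment_factor < 1.0:
            raise ValueError("enrichment factor must be >= 1")
        if self.n_enriched > self.n_sets:
            raise ValueError("cannot plant more enriched sets than sets")
        if self.score_kind not in ("continuous", "binary"):
            raise ValueError("score_kind must be 'continuous' or 'binary'")


def simulate_geneset_universe(cfg: GenesetSimConfig):
    """Simulate (universe, gene-set collection, truth) with planted enrichment."""
    from .enrichment import GeneSet, GeneSetCollection, GeneUniverse

    rng = np.random.default_rng(cfg.seed)
    width = len(str(max(cfg.n_genes, 1)))
    gene_ids = [f"gene{i + 1:0{width}d}" for i in range(cfg.n_genes)]
    sets: list[GeneSet] = []
    enriched_ids: list[str] = []
    member_idx: list[np.ndarray] = []
    for s in range(cfg.n_sets):
        size = int(rng.integers(cfg.set_size_range[0], cfg.set_size_range[1] + 1))
        size = min(size, cfg.n_genes)
        idx = rng.choice(cfg.n_genes, size=size, replace=False)
        member_idx.append(idx)
        set_id = f"set{s + 1:03d}"
        planted = s < cfg.n_enriched and cfg.enrichment_factor > 1.0
        if planted:
            enriched_ids.append(set_id)
        sets.append(
            GeneSet(set_id, "planted" if planted else "null", tuple(gene_ids[i] for i in idx))
        )
    if cfg.score_kind == "continuous":
        scores = rng.normal(0.0, 1.0, cfg.n_genes)
        shift = cfg.enrichment_factor - 1.0
        boosted = np.zeros(cfg.n_genes, dtype=bool)
        for set_id, idx in zip((s.id for s in sets), member_idx):
            if set_id in enriched_ids:
                boosted[idx] = True
        scores[boosted] += shift
    else:
        p = np.full(cfg.n_genes, cfg.baseline_target_prob)
        for set_id, idx in zip((s.id for s in sets), member_idx):
            if set_id in enriched_ids:
                p[idx] = np.minimum(1.0, cfg.baseline_target_prob * cfg.enrichment_factor)
        scores = (rng.random(cfg.n_genes) < p).astype(float)
    universe = GeneUniverse(gene_ids, scores)
    truth = SimTruth(
        "geneset_universe",
        cfg.seed,
        _config_hash(cfg),
        {"enriched_set_ids": enriched_ids, "enrichment_factor": cfg.enrichment_factor},
    )
    return universe, GeneSetCollection(sets), truth


# ---------------------------------------------------------------- assays


def _default_gene_effects() -> dict[str, dict[str, float]]:
    # fold changes per (gene, dose group); study-system directions: the three
    # miR-122 isomiRs knocked down at both doses, three untouched control
    # miRNAs, three de-repressed direct targets
    down = {"low-dose": 0.3, "high-dose": 0.3}
    flat = {"low-dose": 1.0, "high-dose": 1.0}
    up = {"low-dose": 2.0, "high-dose": 2.0}
    return {
        "mir122": dict(down),
        "mir122a": dict(down),
        "mir122b": dict(down),
        "mir103": dict(flat),
        "mir21": dict(flat),
        "mir33": dict(flat),
        "cyp2k5": dict(up),
        "ptgr1": dict(up),
        "arcn1": dict(up),
    }


def _default_analyte_effects() -> dict[str, dict[str, float]]:
    # percent change of the group mean vs control; reported study directions
    return {
        "glucose": {"low-dose": 62.0, "high-dose": 67.0},
        "triglycerides": {"low-dose": -10.0, "high-dose": -36.0},
        "free_fatty_acids": {"low-dose": -15.0, "high-dose": -46.0},
        "cholesterol": {"low-dose": -20.0, "high-dose": -20.0},
    }


def _default_analyte_baselines() -> dict[str, float]:
    # plausible postprandial trout plasma concentrations (mmol/L)
    return {
        "glucose": 5.0,
        "triglycerides": 2.0,
        "free_fatty_acids": 0.3,
        "cholesterol": 9.0,
    }


@dataclass
class AssaySimConfig:
    """qPCR + metabolite experiment: 3 dose groups of n = 6 by default."""

    groups: tuple[str, ...] = ("saline", "low-dose", "high-dose")
    control_group: str = "saline"
    n_per_group: int = 6
    gene_fold_changes: dict[str, dict[str, float]] = field(default_factory=_default_gene_effects)
    analyte_percent_changes: dict[str, dict[str, float]] = field(
        default_factory=_default_analyte_effects
    )
    analyte_baselines: dict[str, float] = field(default_factory=_default_analyte_baselines)
    reference_genes: tuple[str, ...] = ("u6", "ef1a")
    efficiencies: dict[str, float] = field(default_factory=dict)  # default 2.0 per gene
    baseline_ct: float = 24.0
    ct_sd: float = 0.25
    tech_rep_sd: float = 0.10
    n_tech_reps: int = 2
    cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 samples per group")
        if self.cv <= 0:
            raise ValueError("coefficient of variation must be positive")
        if self.control_group not in self.groups:
            raise ValueError("control group must be one of the groups")
        for gene, by_group in self.gene_fold_changes.items():
            for fold in by_group.values():
                if fold <= 0:
                    raise ValueError(f"fold change for {gene!r} must be positive")


def simulate_assay(cfg: AssaySimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate Ct and metabolite tables with planted group effects.

    A gene with fold change f in a group is shifted by dCt = -log_E(f)
    relative to the control baseline; biological noise is normal on the Ct
    scale (sd ``ct_sd``), technical replicates add ``tech_rep_sd``.
    Reference genes are effect-free.  Metabolites are lognormal with the
    configured CV around group means of baseline * (1 + effect/100).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = list(cfg.gene_fold_changes) + [g for g in cfg.reference_genes if g not in cfg.gene_fold_changes]
    eff = {g: cfg.efficiencies.get(g, 2.0) for g in genes}
    ct_rows = []
    sample_ids: dict[str, list[str]] = {}
    for group in cfg.groups:
        sample_ids[group] = [f"{group}_{i + 1}" for i in range(cfg.n_per_group)]
    for gene in genes:
        e = eff[gene]
        for group in cfg.groups:
            fold = 1.0
            if group != cfg.control_group and gene in cfg.gene_fold_changes:
                fold = cfg.gene_fold_changes[gene].get(group, 1.0)
            shift = -np.log(fold) / np.log(e)
            for sample in sample_ids[group]:
                bio_ct = cfg.baseline_ct + shift + rng.normal(0.0, cfg.ct_sd)
                for rep in range(1, cfg.n_tech_reps + 1):
                    ct_rows.append(
                        {
                            "sample_id": sample,
                            "group": group,
                            "gene": gene,
                            "replicate": rep,
                            "ct": bio_ct + rng.normal(0.0, cfg.tech_rep_sd),
                        }
                    )
    ct_table = pd.DataFrame(ct_rows)

    sigma = float(np.sqrt(np.log(1.0 + cfg.cv**2)))
    metab_rows = []
    for analyte, baseline in cfg.analyte_baselines.items():
        effects = cfg.analyte_percent_changes.get(analyte, {})
        for group in cfg.groups:
            pct = 0.0 if group == cfg.control_group else effects.get(group, 0.0)
            mean = baseline * (1.0 + pct / 100.0)
            mu = np.log(mean) - sigma**2 / 2.0  # arithmetic mean equals target
            values = rng.lognormal(mu, sigma, cfg.n_per_group)
            for sample, value in zip(sample_ids[group], values):
                metab_rows.append(
                    {"sample_id": sample, "group": group, "analyte": analyte, "value": value}
                )
    metab_table = pd.DataFrame(metab_rows)

    truth = SimTruth(
        "assay",
        cfg.seed,
        _config_hash(cfg),
        {
            "gene_fold_changes": cfg.gene_fold_changes,
            "analyte_percent_changes": cfg.analyte_percent_changes,
            "efficiencies": eff,
            "control_group": cfg.control_group,
        },
    )
    return ct_table, metab_table, truth
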