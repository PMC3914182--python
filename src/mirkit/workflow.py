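"""End-to-end orchestration: conserve -> scan -> map -> enrich -> stats.

A single structured config (YAML/JSON dict) names the inputs for whichever
stages are wanted; validation resolves every cross-reference up front and
aggregates all errors, and :func:`run_all` executes the stages in dependency
order, writes per-stage artifacts, and assembles one JSON report.  Reruns
with the same config and seed are identical except for the timestamp field.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import conservation as cons
from . import enrichment as enr
from . import expression_stats as xstats
from . import target_prediction as tp
from .sequences import read_fasta

__all__ = ["RunConfig", "ValidationError", "validate", "run_all", "read_region_tsv"]

log = logging.getLogger("mirkit.workflow")

STAGES = ("conservation", "scan", "enrichment", "qpcr", "metabolites")


class ValidationError(ValueError):
    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


@dataclass
class RunConfig:
    seed: int
    output_dir: Path
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)
    skip: tuple[str, ...] = ()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "RunConfig":
        base = base or Path.cwd()
        stages = {}
        for name in STAGES:
            if name in raw and raw[name] is not None:
                block = dict(raw[name])
                for key, value in block.items():
                    if isinstance(value, str) and (
                        key.endswith(("fasta", "map", "table", "file"))
                        or key in ("utrs", "mirna", "regions", "universe", "gmt", "ct",
                                   "efficiencies", "reference_targets")
                    ):
                        block[key] = str((base / value) if not Path(value).is_absolute() else value)
                stages[name] = block
        out = raw.get("output_dir", "mirkit_out")
        out_path = Path(out) if Path(out).is_absolute() else base / out
        return cls(int(raw.get("seed", 0)), out_path, stages, tuple(raw.get("skip", ())))


def read_region_tsv(path: str | Path) -> cons.RegionAnnotation:
    """Region TSV: reference_id, region_name, start, end (1-based inclusive)."""
    frame = pd.read_csv(path, sep="\t", header=None,
                        names=["reference_id", "region_name", "start", "end"], comment="#")
    refs = frame["reference_id"].unique()
    if len(refs) != 1:
        raise ValueError(f"region table must annotate exactly one reference, got {list(refs)}")
    regions = {
        str(r.region_name): (int(r.start), int(r.end)) for r in frame.itertuples(index=False)
    }
    return cons.RegionAnnotation(str(refs[0]), regions)


def validate(cfg: RunConfig) -> list[str]:
    """Resolve every cross-reference; return the aggregated error list."""
    errors: list[str] = []
    active = {k: v for k, v in cfg.stages.items() if k not in cfg.skip}
    if not active:
        errors.append("no stages configured")

    def need_file(block: dict, key: str, stage: str) -> Path | None:
        value = block.get(key)
        if value is None:
            errors.append(f"{stage}: missing required input {key!r}")
            return None
        path = Path(value)
        if not path.exists():
            errors.append(f"{stage}: {key} path does not exist: {path}")
            return None
        return path

    if "conservation" in active:
        block = active["conservation"]
        fasta = need_file(block, "fasta", "conservation")
        regions = need_file(block, "regions", "conservation")
        if fasta and regions:
            try:
                family = read_fasta(fasta)
                annot = read_region_tsv(regions)
                if annot.reference_id not in {s.id for s in family}:
                    errors.append(
                        f"conservation: regions reference {annot.reference_id!r} not in FASTA"
                    )
            except Exception as exc:  # aggregate, do not abort
                errors.append(f"conservation: {exc}")
    if "scan" in active:
        block = active["scan"]
        need_file(block, "utrs", "scan")
        mirna = need_file(block, "mirna", "scan")
        if mirna:
            try:
                if not read_fasta(mirna):
                    errors.append("scan: miRNA FASTA is empty")
            except Exception as exc:
                errors.append(f"scan: {exc}")
        for opt in ("ortholog_map", "reference_targets"):
            if block.get(opt) is not None and not Path(block[opt]).exists():
                errors.append(f"scan: {opt} path does not exist: {block[opt]}")
    if "enrichment" in active:
        block = active["enrichment"]
        need_file(block, "universe", "enrichment")
        need_file(block, "gmt", "enrichment")
    if "qpcr" in active:
        block = active["qpcr"]
        ct_path = need_file(block, "ct", "qpcr")
        eff_path = need_file(block, "efficiencies", "qpcr")
        if ct_path and eff_path:
            try:
                table = xstats.CtTable.from_tsv(ct_path, eff_path)
                genes = set(table.data["gene"])
                ref = block.get("ref_gene")
                if ref not in genes:
                    errors.append(f"qpcr: reference gene {ref!r} absent from Ct table")
                for gene in block.get("target_genes", []):
                    if gene not in genes:
                        errors.append(f"qpcr: target gene {gene!r} absent from Ct table")
                cal = block.get("calibrator")
                if cal not in set(table.data["group"]):
                    errors.append(f"qpcr: calibrator group {cal!r} absent from Ct table")
            except Exception as exc:
                errors.append(f"qpcr: {exc}")
    if "metabolites" in active:
        block = active["metabolites"]
        path = need_file(block, "table", "metabolites")
        if path:
            try:
                frame = pd.read_csv(path, sep="\t")
                if block.get("control") not in set(frame["group"]):
                    errors.append(
                        f"metabolites: control group {block.get('control')!r} absent from table"
                    )
            except Exception as exc:
                errors.append(f"metabolites: {exc}")
    return errors


def _groups_from_frame(frame: pd.DataFrame, value_col: str) -> dict[str, np.ndarray]:
    return {g: sub[value_col].to_numpy() for g, sub in frame.groupby("group", sort=False)}


def _stats_block(groups: dict[str, np.ndarray], alpha: float = 0.05) -> dict:
    checks = xstats.assumption_checks(groups, alpha)
    anova = xstats.one_way_anova(groups)
    snk = xstats.snk_posthoc(groups, alpha)
    return {
        "assumptions": {
            "shapiro_p": checks.shapiro_p,
            "levene_p": checks.levene_p,
            "passed": checks.passed,
            "log10_recommended": checks.recommend_log10,
        },
        "anova": {
            "df_between": anova.df_between,
            "df_within": anova.df_within,
            "F": anova.F,
            "p": anova.p,
        },
        "group_means": anova.group_means,
        "snk_letters": snk.letters,
    }


def run_all(cfg: RunConfig) -> dict:
    """Run the configured stages in dependency order; return the report dict.

    Artifacts land under ``cfg.output_dir``; the JSON report is also written
    there.  A stage failure raises with the stage name; artifacts of earlier
    stages are preserved.
    """
    errors = validate(cfg)
    if errors:
        raise ValidationError(errors)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": cfg.seed, "stages": {}}
    active = {k: v for k, v in cfg.stages.items() if k not in cfg.skip}

    for stage in STAGES:
        if stage not in active:
            continue
        block = active[stage]
        started = time.perf_counter()
        log.info("stage %s: starting", stage)
        try:
            if stage == "conservation":
                family = read_fasta(block["fasta"])
                annot = read_region_tsv(block["regions"])
                msa = cons.progressive_msa(family)
                profile = cons.conservation_profile(msa, block.get("metric", "modal"))
                means, ranking = cons.region_conservation(msa, profile, annot)
                with open(outdir / "alignment.fa", "w") as handle:
                    for i, r in zip(msa.ids, msa.rows):
                        handle.write(f">{i}\n{r}\n")
                pd.DataFrame(
                    {
                        "column": np.arange(1, msa.ncol + 1),
                        "score": profile.scores,
                        "gap_fraction": profile.gap_fraction,
                        "flagged": profile.flagged,
                    }
                ).to_csv(outdir / "conservation_profile.tsv", sep="\t", index=False)
                with open(outdir / "region_conservation.json", "w") as handle:
                    json.dump({"region_means": means, "ranking": ranking}, handle, indent=2)
                report["stages"]["conservation"] = {
                    "n_sequences": len(family),
                    "alignment_columns": msa.ncol,
                    "region_means": means,
                    "ranking": ranking,
                }
            elif stage == "scan":
                utrs = read_fasta(block["utrs"])
                mirna_rec = read_fasta(block["mirna"], alphabet="DNA")[0]
                mirna = tp.MatureMirna.from_sequence(mirna_rec.id, mirna_rec.residues)
                site_types = tuple(block.get("site_types", ["6mer"]))
                targets = tp.scan_utrs(utrs, mirna, site_types)
                pd.DataFrame(
                    [
                        {"utr_id": s.utr_id, "start": s.start, "site_type": s.site_type,
                         "matched_seq": s.matched_seq}
                        for s in targets.sites
                    ]
                ).to_csv(outdir / "seed_sites.tsv", sep="\t", index=False)
                (outdir / "target_ids.txt").write_text("\n".join(targets.target_ids) + "\n")
                summary: dict[str, Any] = {
                    "scanned": targets.n_scanned,
                    "targets": targets.n_targets,
                    "site_types": list(site_types),
                }
                if block.get("ortholog_map"):
                    omap = tp.OrthologMap.from_tsv(block["ortholog_map"])
                    mapped, unmapped = tp.map_orthologs(targets, omap)
                    summary["mapped"] = len(mapped)
                    summary["unmapped"] = len(unmapped)
                    summary["mapped_ids"] = mapped
                if block.get("reference_targets"):
                    reference = [
                        line.strip()
                        for line in Path(block["reference_targets"]).read_text().splitlines()
                        if line.strip()
                    ]
                    ids = summary.get("mapped_ids", targets.target_ids)
                    frac = tp.conserved_fraction(
                        ids, reference, denominator=block.get("denominator", targets.n_targets)
                    )
                    summary["conserved_count"] = frac.overlap
                    summary["conserved_pct"] = frac.percent_rounded
                    summary["conserved_pct_unrounded"] = frac.percent
                summary.pop("mapped_ids", None)
                with open(outdir / "scan_summary.json", "w") as handle:
                    json.dump(summary, handle, indent=2)
                report["stages"]["scan"] = summary
            elif stage == "enrichment":
                universe = enr.GeneUniverse.from_tsv(block["universe"])
                sets = enr.GeneSetCollection.from_gmt(block["gmt"])
                alpha = float(block.get("alpha", 0.05))
                results, skipped = enr.snea(
                    universe, sets, alpha=alpha, min_set_size=int(block.get("min_set_size", 3))
                )
                frame = pd.DataFrame(
                    [
                        {
                            "set_id": r.set_id,
                            "n_members": r.n_members,
                            "n_background": r.n_background,
                            "U": r.u_statistic,
                            "p_mwu": r.p_mwu,
                            "p_hyper": r.p_hyper,
                            "q": r.q,
                            "significant": r.significant,
                        }
                        for r in results
                    ]
                )
                frame.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
                report["stages"]["enrichment"] = {
                    "n_sets_tested": len(results),
                    "n_skipped": len(skipped),
                    "significant_sets": [r.set_id for r in results if r.significant],
                    "alpha": alpha,
                }
            elif stage == "qpcr":
                table = xstats.CtTable.from_tsv(block["ct"], block["efficiencies"])
                ref_gene = block["ref_gene"]
                calibrator = block["calibrator"]
                genes = block.get("target_genes") or sorted(
                    set(table.data["gene"]) - {ref_gene}
                )
                per_gene = {}
                ratio_frames = []
                for gene in genes:
                    ratios = xstats.relative_expression(table, gene, ref_gene, calibrator)
                    ratio_frames.append(ratios)
                    per_gene[gene] = _stats_block(_groups_from_frame(ratios, "ratio"))
                pd.concat(ratio_frames).to_csv(outdir / "expression_ratios.tsv", sep="\t", index=False)
                report["stages"]["qpcr"] = per_gene
            elif stage == "metabolites":
                frame = pd.read_csv(block["table"], sep="\t")
                control = block["control"]
                per_analyte = {}
                for analyte, sub in frame.groupby("analyte", sort=True):
                    groups = _groups_from_frame(sub, "value")
                    stats_block = _stats_block(groups)
                    stats_block["percent_change_vs_control"] = xstats.group_percent_change(
                        groups, control
                    )
                    per_analyte[analyte] = stats_block
                report["stages"]["metabolites"] = per_analyte
        except ValidationError:
            raise
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        log.info("stage %s: done in %.2f s", stage, time.perf_counter() - started)

    report["generated_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "report.json", "w") as handle:
        json.dump(report, handle, indent=2, default=_jsonable)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
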