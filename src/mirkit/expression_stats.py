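"""qPCR relative quantification and downstream group statistics.

Relative expression uses the efficiency-corrected ratio method: with per-gene
amplification factor E (2 = perfect doubling per cycle),

    ratio_s = E_t ** (Ct_cal,t - Ct_s,t) / E_ref ** (Ct_cal,ref - Ct_s,ref)

where Ct_cal is the mean Ct of the calibrator (control) group, so the
calibrator group has geometric-mean ratio 1 by construction.  A ddCt mode
(E forced to 2 for all genes) is available.  Technical replicates are
averaged at the Ct level before ratios.

Group comparisons follow the classical workflow for small-n physiology data:
Shapiro-Wilk normality and Levene homoscedasticity checks (with a log10
transform recommended and re-checked on failure), one-way ANOVA, and a
Student-Newman-Keuls stepwise post-hoc on the studentized range with a
compact-letter display (groups sharing a letter do not differ at alpha).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtTable",
    "AnovaResult",
    "AssumptionReport",
    "PosthocGrouping",
    "relative_expression",
    "assumption_checks",
    "one_way_anova",
    "snk_posthoc",
    "group_percent_change",
    "efficiency_percent",
]

CT_COLUMNS = ("sample_id", "group", "gene", "replicate", "ct")


@dataclass
class CtTable:
    """Long-format Ct measurements plus per-gene amplification factors E."""

    data: pd.DataFrame  # columns: sample_id, group, gene, replicate, ct
    efficiencies: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(CT_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        for gene, eff in self.efficiencies.items():
            if not (1.0 < eff < 3.0):
                raise ValueError(f"amplification factor for {gene!r} must lie in (1, 3), got {eff}")

    def efficiency(self, gene: str) -> float:
        try:
            return self.efficiencies[gene]
        except KeyError:
            raise KeyError(f"no amplification factor for gene {gene!r}") from None

    @classmethod
    def from_tsv(cls, ct_path, eff_path) -> "CtTable":
        data = pd.read_csv(ct_path, sep="\t")
        eff = pd.read_csv(eff_path, sep="\t")
        return cls(data, dict(zip(eff.iloc[:, 0], eff.iloc[:, 1].astype(float))))


@dataclass(frozen=True)
class AnovaResult:
    df_between: int
    df_within: int
    F: float
    p: float
    ss_between: float
    ss_within: float
    ss_total: float
    ms_within: float
    group_means: dict[str, float]
    group_ns: dict[str, int]


@dataclass(frozen=True)
class AssumptionReport:
    shapiro_p: float  # on within-group residuals
    levene_p: float
    passed: bool
    recommend_log10: bool
    shapiro_p_log10: float | None = None
    levene_p_log10: float | None = None
    passed_after_log10: bool | None = None
    constant_groups: tuple[str, ...] = ()


@dataclass
class PosthocGrouping:
    """SNK outcome: per-group means, compact letters, and rejected pairs."""

    groups: list[str]  # descending mean order
    means: dict[str, float]
    letters: dict[str, str]
    rejected: set[tuple[str, str]]  # unordered pairs stored sorted
    alpha: float

    def different(self, a: str, b: str) -> bool:
        return tuple(sorted((a, b))) in self.rejected


def relative_expression(
    ct: CtTable,
    target_gene: str,
    ref_gene: str,
    calibrator_group: str,
    mode: str = "efficiency",
) -> pd.DataFrame:
    """Efficiency-corrected expression ratios calibrated to the control group.

    Returns one row per sample: sample_id, group, gene, ratio.  ``mode``
    "efficiency" uses the per-gene E values; "ddct" forces E = 2 for both
    genes (classical ddCt).
    """
    if mode not in ("efficiency", "ddct"):
        raise ValueError(f"unknown quantification mode {mode!r}")
    e_t = 2.0 if mode == "ddct" else ct.efficiency(target_gene)
    e_r = 2.0 if mode == "ddct" else ct.efficiency(ref_gene)
    # technical replicates are averaged at the Ct level first
    mean_ct = (
        ct.data.groupby(["sample_id", "group", "gene"], sort=False)["ct"].mean().reset_index()
    )
    wide = mean_ct.pivot(index=["sample_id", "group"], columns="gene", values="ct")
    for gene in (target_gene, ref_gene):
        if gene not in wide.columns or wide[gene].isna().any():
            bad = wide.index[wide[gene].isna()].tolist() if gene in wide.columns else "all samples"
            raise ValueError(f"missing Ct rows for gene {gene!r}: {bad}")
    wide = wide.reset_index()
    cal = wide[wide["group"] == calibrator_group]
    if cal.empty:
        raise ValueError(f"calibrator group {calibrator_group!r} has no samples")
    cal_t = cal[target_gene].mean()
    cal_r = cal[ref_gene].mean()
    ratio = e_t ** (cal_t - wide[target_gene]) / e_r ** (cal_r - wide[ref_gene])
    return pd.DataFrame(
        {
            "sample_id": wide["sample_id"],
            "group": wide["group"],
            "gene": target_gene,
            "ratio": ratio,
        }
    )


def _as_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, vals in out.items():
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError(f"group {name!r} must be a nonempty 1-d array")
    return out


def assumption_checks(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> AssumptionReport:
    """Shapiro-Wilk (on pooled within-group residuals) and Levene checks.

    If either fails at ``alpha`` a log10 transform is recommended and the
    checks are repeated on the transformed data.  Constant groups make
    normality undefined and are flagged rather than tested.
    """
    g = _as_groups(groups)
    if any(v.size < 3 for v in g.values()):
        raise ValueError("assumption checks need at least 3 values per group")
    constant = tuple(name for name, v in g.items() if np.ptp(v) == 0)

    def _check(data: dict[str, np.ndarray]) -> tuple[float, float]:
        residuals = np.concatenate([v - v.mean() for v in data.values()])
        sw = float(stats.shapiro(residuals).pvalue) if np.ptp(residuals) > 0 else float("nan")
        lev = float(stats.levene(*data.values()).pvalue)
        return sw, lev

    sw, lev = _check(g)
    passed = (np.isnan(sw) or sw >= alpha) and lev >= alpha and not constant
    recommend = not passed
    sw_log = lev_log = None
    passed_log = None
    if recommend and all((v > 0).all() for v in g.values()):
        g_log = {k: np.log10(v) for k, v in g.items()}
        sw_log, lev_log = _check(g_log)
        passed_log = (np.isnan(sw_log) or sw_log >= alpha) and lev_log >= alpha
    return AssumptionReport(sw, lev, passed, recommend, sw_log, lev_log, passed_log, constant)


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA (between/within decomposition)."""
    g = _as_groups(groups)
    if len(g) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(v.size < 2 for v in g.values()):
        raise ValueError("ANOVA needs at least two values per group")
    all_values = np.concatenate(list(g.values()))
    grand = all_values.mean()
    ss_total = float(((all_values - grand) ** 2).sum())
    if ss_total == 0:
        raise ValueError("degenerate data: zero total variance")
    ss_between = float(sum(v.size * (v.mean() - grand) ** 2 for v in g.values()))
    ss_within = float(sum(((v - v.mean()) ** 2).sum() for v in g.values()))
    df_between = len(g) - 1
    df_within = all_values.size - len(g)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        f_stat = float("inf")
        p = 0.0
    else:
        f_stat = ms_between / ms_within
        p = float(stats.f.sf(f_stat, df_between, df_within))
    return AnovaResult(
        df_between,
        df_within,
        float(f_stat),
        p,
        ss_between,
        ss_within,
        ss_total,
        float(ms_within),
        {k: float(v.mean()) for k, v in g.items()},
        {k: int(v.size) for k, v in g.items()},
    )


def snk_posthoc(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> PosthocGrouping:
    """Student-Newman-Keuls stepwise post-hoc with compact letter display.

    Means are ordered descending; each pair spanning r ordered means is
    compared with q = (mean_hi - mean_lo) / sqrt(MS_within / n_h) against the
    studentized-range critical value at (r, df_within), stepping down from
    the widest range.  A range that is not rejected protects all its
    sub-ranges (no further testing inside), which makes the non-rejection
    relation interval-shaped over the ordering; letters are the maximal
    non-rejected intervals.  n_h is the harmonic mean of the two group sizes.
    """
    anova = one_way_anova(groups)
    if len(anova.group_means) < 2:
        raise ValueError("post-hoc needs at least two groups")
    ordered = sorted(anova.group_means, key=lambda k: (-anova.group_means[k], k))
    k = len(ordered)
    means = anova.group_means
    ns = anova.group_ns
    rejected: set[tuple[str, str]] = set()
    protected: set[tuple[int, int]] = set()  # index pairs inside an accepted range
    for span in range(k, 1, -1):
        crit = float(stats.studentized_range.ppf(1 - alpha, span, anova.df_within))
        for i in range(0, k - span + 1):
            j = i + span - 1
            if (i, j) in protected:
                continue
            hi, lo = ordered[i], ordered[j]
            n_h = 2.0 / (1.0 / ns[hi] + 1.0 / ns[lo])
            if anova.ms_within == 0:
                q = float("inf") if means[hi] != means[lo] else 0.0
            else:
                q = (means[hi] - means[lo]) / np.sqrt(anova.ms_within / n_h)
            if q > crit:
                rejected.add(tuple(sorted((hi, lo))))
            else:
                for a in range(i, j + 1):
                    for b in range(a + 1, j + 1):
                        protected.add((a, b))
    # compact letters: maximal intervals over the ordering whose endpoints
    # (hence all inner pairs, by the stepwise protection rule) are not rejected
    letters: dict[str, list[str]] = {g: [] for g in ordered}
    label = 0
    i = 0
    covered_up_to = -1
    while i < k:
        j = i
        while j + 1 < k and tuple(sorted((ordered[i], ordered[j + 1]))) not in rejected:
            j += 1
        if j > covered_up_to:
            symbol = _letter(label)
            label += 1
            for idx in range(i, j + 1):
                letters[ordered[idx]].append(symbol)
            covered_up_to = j
        i += 1
    return PosthocGrouping(
        ordered,
        dict(means),
        {g: "".join(v) for g, v in letters.items()},
        rejected,
        alpha,
    )


def _letter(index: int) -> str:
    out = ""
    index += 1
    while index:
        index, rem = divmod(index - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


def group_percent_change(
    values: Mapping[str, Sequence[float]], control: str
) -> dict[str, float]:
    """Per-group percent change of the mean relative to the control group."""
    g = _as_groups(values)
    if control not in g:
        raise ValueError(f"control group {control!r} absent")
    base = g[control].mean()
    if base == 0:
        raise ValueError("control mean is zero")
    return {name: float(100.0 * (v.mean() / base - 1.0)) for name, v in g.items()}


def efficiency_percent(e: float, convention: str = "ratio") -> float:
    """Amplification factor E as a percent efficiency.

    "ratio": 100 * E / 2 (E = 1.8-2.2 maps to 90-110%); "gain": the common
    100 * (E - 1).
    """
    if convention == "ratio":
        return 100.0 * e / 2.0
    if convention == "gain":
        return 100.0 * (e - 1.0)
    raise ValueError(f"unknown efficiency convention {convention!r}")
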