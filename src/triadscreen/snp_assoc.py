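"""Allele-group trait association: t-test / one-way ANOVA with Fisher LSD.

Each SNP partitions the cohort into its called genotype classes (ref-hom,
het, alt-hom).  Two populated classes are compared with a two-tailed
Student t-test (pooled variance by default, Welch behind a flag); three or
more with one-way ANOVA followed by Fisher's Least Significant Difference
-- unadjusted pairwise t-tests on the pooled within-group mean square.  A
two-class SNP passes when its t-test reaches the strict threshold (1e-3 by
default); a multi-class SNP passes when the omnibus ANOVA reaches 0.05 and
at least one LSD pairwise contrast reaches the strict threshold (the
threshold is applied to the pairwise group differences).  A transcript
qualifies when it carries at least one passing SNP located inside an open
reading frame.  The allele effect size is reported as
(mean_high - mean_low) / mean_low * 100%, with "higher group" decided per
SNP x trait at evaluation time.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import GenotypeTable

log = logging.getLogger(__name__)

__all__ = [
    "SnpAssociationResult",
    "two_group_t",
    "oneway_anova_lsd",
    "effect_percent",
    "snp_screen",
]


@dataclass
class SnpAssociationResult:
    snp_id: str
    transcript: str
    trait: str
    group_sizes: dict[int, int]          # dosage class -> n
    group_means: dict[int, float]
    test: str                            # "t_test" or "anova"
    p: float
    lsd_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    effect_percent: float | None = None
    in_orf: bool = False
    passes: bool = False


def two_group_t(values_a, values_b, variant: str = "pooled") -> tuple[float, float, float]:
    """Two-tailed two-sample t-test; returns (t, df, p).

    ``pooled`` is the classical equal-variance test (df = n_a + n_b - 2);
    ``welch`` uses the Welch--Satterthwaite df.  Zero pooled variance with
    equal means reports t = 0, p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return math.inf if a.mean() > b.mean() else -math.inf, float(a.size + b.size - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    if variant == "pooled":
        df = a.size + b.size - 2.0
    else:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def oneway_anova_lsd(groups) -> tuple[float, int, int, float, list[tuple[int, int, float]]]:
    """One-way ANOVA plus Fisher LSD pairwise comparisons.

    Returns (F, df_between, df_within, p, lsd) where ``lsd`` lists
    (i, j, p_ij) for every group pair, using unadjusted two-tailed t-tests
    on the pooled within-group mean square error.  With exactly two groups
    this degenerates to the pooled t-test (F = t^2).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    gs = [g[~np.isnan(g)] for g in gs]
    if len(gs) < 2:
        raise ValueError("need >= 2 groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("each group needs >= 2 observations")
    k = len(gs)
    ns = np.array([g.size for g in gs])
    means = np.array([g.mean() for g in gs])
    n_total = int(ns.sum())
    df1, df2 = k - 1, n_total - k
    grand = float(np.concatenate(gs).mean())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, df1, df2, 1.0, [(i, j, 1.0) for i, j in itertools.combinations(range(k), 2)]
        return math.inf, df1, df2, 0.0, [
            (i, j, 0.0 if means[i] != means[j] else 1.0)
            for i, j in itertools.combinations(range(k), 2)
        ]
    mse = ss_within / df2
    f_stat = (ss_between / df1) / mse
    p = float(stats.f.sf(f_stat, df1, df2))
    lsd = []
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt(mse * (1.0 / ns[i] + 1.0 / ns[j]))
        t = (means[i] - means[j]) / se
        lsd.append((i, j, float(2.0 * stats.t.sf(abs(t), df2))))
    return float(f_stat), df1, df2, p, lsd


def effect_percent(mean_high: float, mean_low: float) -> float:
    """Allele effect as a percentage of the lower group's mean content."""
    if mean_low <= 0:
        raise ValueError("effect_percent undefined for non-positive lower-group mean")
    return (mean_high - mean_low) / mean_low * 100.0


def _collapse_dosage(dosage: np.ndarray, mode: str | None) -> np.ndarray:
    if mode is None:
        return dosage
    if mode == "dominant":      # het grouped with alt-hom
        return np.where(dosage >= 1, 1.0, 0.0)
    if mode == "recessive":     # het grouped with ref-hom
        return np.where(dosage == 2, 1.0, 0.0)
    raise ValueError(f"unknown collapse mode {mode!r}")


def snp_screen(
    genotypes: GenotypeTable,
    traits: pd.DataFrame,
    alpha: float = 1e-3,
    min_group_size: int = 3,
    variant: str = "pooled",
    collapse: str | None = None,
    require_orf: bool = True,
) -> tuple[list[SnpAssociationResult], set[str]]:
    """Test every SNP x trait; return results and qualifying transcripts.

    Genotype classes smaller than ``min_group_size`` are dropped from that
    SNP's test; SNPs left with fewer than two classes are skipped as
    monomorphic (logged).  A transcript qualifies when any of its SNPs
    passes ``alpha`` (and lies in an ORF, unless ``require_orf`` is off).
    """
    shared = [s for s in genotypes.calls.columns if s in traits.index]
    if len(shared) < 2 * min_group_size:
        raise ValueError("too few shared samples for grouped tests")
    calls = genotypes.calls[shared]
    tr = traits.loc[shared]

    results: list[SnpAssociationResult] = []
    qualifying: set[str] = set()
    for snp_id, dosage_row in calls.iterrows():
        meta = genotypes.snps.loc[snp_id]
        dosage = _collapse_dosage(dosage_row.to_numpy(dtype=float), collapse)
        classes = {}
        for cls in np.unique(dosage[~np.isnan(dosage)]):
            members = np.where(dosage == cls)[0]
            if members.size >= min_group_size:
                classes[int(cls)] = members
        if len(classes) < 2:
            log.info("skipping monomorphic/underpowered SNP %s", snp_id)
            continue
        for trait in tr.columns:
            vals = tr[trait].to_numpy(dtype=float)
            groups = {c: vals[m][~np.isnan(vals[m])] for c, m in classes.items()}
            groups = {c: g for c, g in groups.items() if g.size >= min_group_size}
            if len(groups) < 2:
                continue
            keys = sorted(groups)
            means = {c: float(groups[c].mean()) for c in keys}
            lsd: list[tuple[int, int, float]] = []
            if len(keys) == 2:
                _, _, p = two_group_t(groups[keys[0]], groups[keys[1]], variant=variant)
                test = "t_test"
                passes = bool(p <= alpha)
            else:
                _, _, _, p, lsd_idx = oneway_anova_lsd([groups[c] for c in keys])
                lsd = [(keys[i], keys[j], pij) for i, j, pij in lsd_idx]
                test = "anova"
                # protected LSD: the omnibus must reach 0.05, then the strict
                # threshold applies to the pairwise group contrasts
                passes = bool(p <= 0.05 and min(pij for _, _, pij in lsd) <= alpha)
            hi, lo = max(means.values()), min(means.values())
            eff = effect_percent(hi, lo) if lo > 0 else None
            res = SnpAssociationResult(
                snp_id=str(snp_id),
                transcript=str(meta["transcript"]),
                trait=str(trait),
                group_sizes={c: int(groups[c].size) for c in keys},
                group_means=means,
                test=test,
                p=float(p),
                lsd_pairs=lsd,
                effect_percent=eff,
                in_orf=bool(meta["in_orf"]),
                passes=passes,
            )
            results.append(res)
            if passes and (res.in_orf or not require_orf):
                qualifying.add(res.transcript)
    return results, qualifying


def results_frame(results: list[SnpAssociationResult]) -> pd.DataFrame:
    """Flatten screen results into a tidy table."""
    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in results],
            "transcript": [r.transcript for r in results],
            "trait": [r.trait for r in results],
            "test": [r.test for r in results],
            "p": [r.p for r in results],
            "effect_percent": [r.effect_percent for r in results],
            "in_orf": [r.in_orf for r in results],
            "passes": [r.passes for r in results],
        }
    )
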