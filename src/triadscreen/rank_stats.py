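"""Spearman rank-correlation machinery and the expression--trait candidate screen.

The screen is the first step of the evidence pipeline: every family
transcript is correlated (Spearman, two-tailed) against every ginsenoside
trait, and a transcript becomes a candidate when its best p-value over the
traits reaches the lenient threshold (0.05 by default).  Transcripts are
additionally tiered into a highly-significant class (p <= 0.01) and a
significant-only class (0.01 < p <= 0.05), matching how association screens
in this field report their hit lists.

P-values come either from exact enumeration of rank permutations (feasible
for n <= 8 and used as the oracle throughout the test suite) or from the
classical t approximation t = rho * sqrt((n-2)/(1-rho^2)) with n-2 degrees
of freedom, which is what mainstream statistics packages print for larger n.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "ScreenResult",
    "spearman_rho",
    "spearman_p",
    "spearman_test",
    "correlation_screen",
    "tier_label",
]

_EXACT_MAX_N = 8


def tier_label(p: float, alpha1: float = 0.01, alpha2: float = 0.05) -> str:
    """Classify a two-tailed p-value into the screen's reporting tiers."""
    if p <= alpha1:
        return "highly_significant"
    if p <= alpha2:
        return "significant"
    return "ns"


@dataclass(frozen=True)
class CorrelationResult:
    transcript: str
    trait: str
    rho: float
    p_two_tailed: float
    n_pairs: int
    tier: str


@dataclass
class ScreenResult:
    """Output of :func:`correlation_screen`.

    ``results`` holds one row per transcript x trait pair; ``candidates`` is
    the ordered list of transcripts whose best p-value reaches ``alpha2``;
    ``transcript_tiers`` maps each transcript to the tier of its best pair.
    """

    results: pd.DataFrame
    candidates: list[str]
    transcript_tiers: dict[str, str]
    alpha1: float = 0.01
    alpha2: float = 0.05
    summary: dict[str, int] = field(default_factory=dict)


def _clean_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    NA values are removed pairwise.  Requires at least 3 complete pairs.
    A vector with zero rank variance (all tied) has no defined rank
    correlation; ``nan`` is returned for that degenerate case.
    """
    x, y = _clean_pairs(x, y)
    if x.size < 3:
        raise ValueError(f"need >= 3 complete pairs, got {x.size}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def _permutation_pool(ranks: np.ndarray) -> np.ndarray:
    """All distinct orderings of a rank vector, as a (k, n) float array."""
    perms = np.array(list(itertools.permutations(ranks)), dtype=float)
    return perms


def _exact_p(rho_obs: float, rank_x: np.ndarray, rank_y: np.ndarray) -> float:
    """Two-tailed exact p: share of the n! orderings of the y ranks whose
    correlation magnitude reaches ``|rho_obs|`` (ties kept as observed)."""
    perms = _permutation_pool(np.asarray(rank_y, dtype=float))
    xm = np.asarray(rank_x, dtype=float)
    xm = xm - xm.mean()
    xnorm = xm / math.sqrt(float(xm @ xm))
    pm = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((pm ** 2).sum(axis=1))
    rhos = (pm @ xnorm) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_p(
    rho: float,
    n: int,
    method: str = "auto",
    *,
    ranks: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Two-tailed p-value for an observed Spearman rho at sample size n.

    Parameters
    ----------
    method:
        ``"exact"`` enumerates all rank permutations (n <= 8 unless you are
        patient); ``"t_approx"`` uses the t statistic with n-2 df;
        ``"auto"`` picks exact for n <= 8 and the t approximation otherwise.
    ranks:
        Optional ``(rank_x, rank_y)`` pair giving the observed tie pattern
        for exact enumeration.  Without it, untied ranks ``1..n`` are
        assumed.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if math.isnan(rho):
        return float("nan")
    if method == "auto":
        method = "exact" if n <= _EXACT_MAX_N else "t_approx"
    if method == "exact":
        if ranks is None:
            rx = np.arange(1, n + 1, dtype=float)
            ry = rx
        else:
            rx, ry = (np.asarray(r, dtype=float) for r in ranks)
        return _exact_p(rho, rx, ry)
    if method != "t_approx":
        raise ValueError(f"unknown method {method!r}")
    if 1.0 - rho * rho < 1e-12:
        # |rho| = 1: t diverges; report the exact-enumeration limit.
        if n <= _EXACT_MAX_N:
            return spearman_p(rho, n, method="exact", ranks=ranks)
        return 2.0 / math.factorial(n)
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_test(x, y, method: str = "auto") -> tuple[float, float, int]:
    """Convenience wrapper: (rho, two-tailed p, n complete pairs)."""
    x, y = _clean_pairs(x, y)
    rho = spearman_rho(x, y)
    n = int(x.size)
    if math.isnan(rho):
        return rho, float("nan"), n
    ranks = (stats.rankdata(x), stats.rankdata(y))
    return rho, spearman_p(rho, n, method=method, ranks=ranks), n


def _rank_standardize(a: np.ndarray) -> np.ndarray:
    """Rank each row, then center and scale to unit norm (rows of a 2-D array)."""
    ranks = np.apply_along_axis(stats.rankdata, 1, a)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks ** 2).sum(axis=1))
    norms[norms == 0] = np.nan
    return ranks / norms[:, None]


def spearman_matrix(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All pairwise Spearman correlations between the rows of ``a``.

    Returns (rho, p) square matrices; p uses the t approximation.  Rows must
    be complete (no NA) -- the screen falls back to pairwise loops otherwise.
    """
    a = np.asarray(a, dtype=float)
    n = a.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples")
    z = _rank_standardize(a)
    rho = np.clip(z @ z.T, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1.0 - 1e-12] = 2.0 / math.factorial(n) if n <= 20 else 0.0
    np.fill_diagonal(p, 0.0)
    return rho, p


def correlation_screen(
    expr: pd.DataFrame,
    traits: pd.DataFrame,
    alpha1: float = 0.01,
    alpha2: float = 0.05,
    method: str = "auto",
    bh: bool = False,
) -> ScreenResult:
    """Correlate every transcript against every trait and select candidates.

    Parameters
    ----------
    expr:
        transcripts x samples abundance matrix.
    traits:
        samples x traits table (shared sample IDs; order-insensitive).
    bh:
        Apply Benjamini--Hochberg correction across all transcript x trait
        pairs before tiering.  Off by default: the screen is deliberately a
        per-test threshold rule.

    A transcript enters the candidate set if ANY trait gives p <= alpha2;
    its tier comes from its best (minimum) p.  ``summary`` records the tier
    partition: ``total == strict + lenient_only`` by construction.
    """
    shared = [s for s in expr.columns if s in traits.index]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared samples between expression and traits")
    e = expr[shared]
    t = traits.loc[shared]

    rows = []
    emat = e.to_numpy(dtype=float)
    tmat = t.to_numpy(dtype=float)
    complete = not (np.isnan(emat).any() or np.isnan(tmat).any())
    n = len(shared)
    if complete and (method == "t_approx" or (method == "auto" and n > _EXACT_MAX_N)):
        ez = _rank_standardize(emat)
        tz = _rank_standardize(tmat.T)
        rho = np.clip(ez @ tz.T, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
        pmat = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
        pmat[np.abs(rho) >= 1.0 - 1e-12] = 0.0
        for i, tr in enumerate(e.index):
            for j, trait in enumerate(t.columns):
                rows.append((tr, trait, float(rho[i, j]), float(pmat[i, j]), n))
    else:
        for tr in e.index:
            for trait in t.columns:
                r, p, m = spearman_test(e.loc[tr], t[trait], method=method)
                rows.append((tr, trait, r, p, m))

    df = pd.DataFrame(rows, columns=["transcript", "trait", "rho", "p", "n"])
    if bh:
        df["p"] = _benjamini_hochberg(df["p"].to_numpy())
    df["tier"] = [tier_label(p, alpha1, alpha2) for p in df["p"]]

    best = df.loc[df.groupby("transcript", sort=False)["p"].idxmin()]
    tiers = {r.transcript: tier_label(r.p, alpha1, alpha2) for r in best.itertuples()}
    candidates = [tr for tr in e.index if tiers[tr] != "ns"]
    strict = sum(1 for tr in candidates if tiers[tr] == "highly_significant")
    summary = {
        "total": len(candidates),
        "strict": strict,
        "lenient_only": len(candidates) - strict,
    }
    return ScreenResult(df, candidates, tiers, alpha1, alpha2, summary)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj
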