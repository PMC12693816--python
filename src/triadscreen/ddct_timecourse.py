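"""Relative quantification by 2^-ddCt and its trait-timecourse correlation.

dCt = Ct_target - Ct_reference per replicate; per condition the mean dCt is
taken first (the standard Livak presentation), ddCt = mean dCt of the
condition minus mean dCt of the calibrator, and fold change = 2^-ddCt.  The
calibrator's fold is exactly 1 by construction.  A per-replicate mode
(fold per replicate, then averaged, with SD) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rank_stats import spearman_test, tier_label

__all__ = ["FoldChangeTable", "fold_change_ddct", "timecourse_trait_correlation"]


@dataclass
class FoldChangeTable:
    table: pd.DataFrame       # condition x [mean_dct, ddct, fold, sd_fold]
    calibrator: str
    mode: str


def fold_change_ddct(
    ct: pd.DataFrame,
    calibrator: str,
    mode: str = "mean_dct",
) -> FoldChangeTable:
    """Fold change per condition from a Ct table.

    ``ct`` needs columns ``timepoint`` (condition label), ``target_ct`` and
    ``reference_ct``; ``calibrator`` names the baseline condition.
    ``mode="mean_dct"`` averages dCt within a condition before the ddCt
    step; ``mode="per_replicate"`` computes a fold per replicate and
    reports its mean and SD.
    """
    for col in ("timepoint", "target_ct", "reference_ct"):
        if col not in ct.columns:
            raise ValueError(f"Ct table missing column {col!r}")
    if ct["reference_ct"].isna().any():
        raise ValueError("missing reference Ct values")
    conditions = list(dict.fromkeys(ct["timepoint"]))
    if calibrator not in conditions:
        raise ValueError(f"calibrator {calibrator!r} not among conditions {conditions}")
    dct = ct["target_ct"].astype(float) - ct["reference_ct"].astype(float)
    mean_dct = dct.groupby(ct["timepoint"]).mean()
    cal = mean_dct[calibrator]
    rows = []
    for cond in conditions:
        ddct = mean_dct[cond] - cal
        if mode == "mean_dct":
            fold = 2.0 ** (-ddct)
            sd = float("nan")
        elif mode == "per_replicate":
            folds = 2.0 ** (-(dct[ct["timepoint"] == cond] - cal))
            fold = float(folds.mean())
            sd = float(folds.std(ddof=1)) if len(folds) > 1 else float("nan")
        else:
            raise ValueError(f"unknown mode {mode!r}")
        rows.append((cond, float(mean_dct[cond]), float(ddct), float(fold), sd))
    table = pd.DataFrame(
        rows, columns=["condition", "mean_dct", "ddct", "fold", "sd_fold"]
    ).set_index("condition")
    return FoldChangeTable(table, calibrator, mode)


def timecourse_trait_correlation(
    folds: FoldChangeTable,
    traits: pd.DataFrame,
    method: str = "auto",
) -> pd.DataFrame:
    """Spearman correlation of fold change against each trait's time course.

    Conditions are matched by label between the fold table and the trait
    table rows; needs at least 3 matched observations.  Returns one row per
    trait: (Ginsenoside, Correlation Coefficient, Sig. two-tailed, n, tier).
    """
    shared = [c for c in folds.table.index if c in traits.index]
    if len(shared) < 3:
        raise ValueError("fewer than 3 matched fold/content observations")
    f = folds.table.loc[shared, "fold"].to_numpy(dtype=float)
    rows = []
    for trait in traits.columns:
        y = traits.loc[shared, trait].to_numpy(dtype=float)
        rho, p, n = spearman_test(f, y, method=method)
        rows.append((trait, rho, p, n, tier_label(p)))
    return pd.DataFrame(
        rows, columns=["ginsenoside", "rho", "p_two_tailed", "n", "tier"]
    ).set_index("ginsenoside")
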