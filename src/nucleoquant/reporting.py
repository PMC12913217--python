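"""Cross-assay derived statistics: fold changes, refold capacity, group tests.

Conventions: fold changes are per-row values divided by the mean of the
control condition within the same assay; the luciferase refold capacity is
the Renilla activity after heat-shock recovery divided by the non-shocked
activity of the same genotype (so each genotype is normalized to itself);
two-sample comparisons default to a two-sided Mann–Whitney U test for
per-cell image metrics and Welch's t for per-sample assay values.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, ttest_ind
from statsmodels.stats.multitest import multipletests

from .errors import (DivisionByZero, MissingControl, NonPositiveControlMean,
                     TooFewValues)


def refold_capacity(activity_recovered: float,
                    activity_nonshocked: float) -> float:
    """Fraction of luciferase activity recovered after heat shock.

    ``activity_recovered / activity_nonshocked``; values above 1
    (over-recovery) are allowed with a warning.
    """
    if activity_nonshocked == 0:
        raise DivisionByZero("non-shocked activity is zero")
    if activity_nonshocked < 0 or activity_recovered < 0:
        raise ValueError("activities must be non-negative")
    ratio = activity_recovered / activity_nonshocked
    if ratio > 1:
        warnings.warn(f"refold capacity {ratio:.3g} exceeds 1 (over-recovery)",
                      stacklevel=2)
    return ratio


def fold_change_vs_control(table: pd.DataFrame, control: str,
                           value_col: str = "value",
                           condition_col: str = "condition",
                           assay_col: str | None = "assay") -> pd.DataFrame:
    """Divide every value by the mean of the control condition, per assay.

    Returns a copy of ``table`` with a ``fold_change`` column; control rows
    average to fold change 1 by construction. ``assay_col=None`` treats the
    whole table as one assay.
    """
    df = table.copy()
    if assay_col and assay_col not in df.columns:
        raise KeyError(f"column {assay_col!r} not in table")
    out = []
    grouped = df.groupby(assay_col, sort=False) if assay_col else [(None, df)]
    for _, g in grouped:
        ctrl = g.loc[g[condition_col] == control, value_col]
        if ctrl.empty:
            raise MissingControl(f"no rows with condition {control!r}")
        mean = float(ctrl.mean())
        if mean <= 0:
            raise NonPositiveControlMean(
                f"control mean {mean:.3g} must be positive")
        g = g.copy()
        g["fold_change"] = g[value_col] / mean
        out.append(g)
    return pd.concat(out).loc[df.index]


def group_test(values_a, values_b, kind: str = "rank") -> dict:
    """Two-sided two-sample test with per-group summaries.

    ``kind='rank'`` runs a Mann–Whitney U test (exact for small untied
    samples); ``kind='t'`` runs Welch's unequal-variance t-test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise TooFewValues("each group needs >= 2 values")
    if kind == "rank":
        res = mannwhitneyu(a, b, alternative="two-sided")
    elif kind == "t":
        res = ttest_ind(a, b, equal_var=False)
    else:
        raise ValueError("kind must be 'rank' or 't'")
    return {"p_value": float(res.pvalue), "statistic": float(res.statistic),
            "kind": kind, "n_a": len(a), "n_b": len(b),
            "mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "median_a": float(np.median(a)), "median_b": float(np.median(b))}


def adjust_fdr_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values for a batch of comparisons."""
    return multipletests(np.asarray(p_values, dtype=float),
                         method="fdr_bh")[1]
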