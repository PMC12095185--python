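"""Bench-validation statistics: 2^−ΔΔCt quantification and group tests.

Relative qPCR quantification normalizes the target gene's Ct to a reference
gene (ΔCt), then to a calibrator condition (ΔΔCt), and reports the fold
change 2^−ΔΔCt.  Group comparisons use the equal-variance pooled two-sample
t-test (replicate designs with n per group as small as 3), and pairwise
comparisons across several groups use Fisher's LSD-t: the one-way-ANOVA
pooled mean-square error as the common variance, uncorrected for
multiplicity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SD over n replicates for one experimental group."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summaries need n >= 2 replicates")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    pval: float


@dataclass(frozen=True)
class DdctResult:
    """Per-replicate ΔCt, ΔΔCt and fold changes 2^−ΔΔCt."""

    delta_ct: np.ndarray
    delta_delta_ct: np.ndarray
    fold_change: np.ndarray

    @property
    def mean_fold(self) -> float:
        return float(np.mean(self.fold_change))


def ddct(
    target_ct: Sequence[float],
    reference_ct: Sequence[float],
    calibrator_delta: float,
) -> DdctResult:
    """2^−ΔΔCt relative quantification against a reference gene.

    ``calibrator_delta`` is the calibrator condition's mean ΔCt; replicates
    of the calibrator itself therefore average to fold change 1.
    """
    target = np.asarray(target_ct, dtype=float)
    reference = np.asarray(reference_ct, dtype=float)
    if target.shape != reference.shape:
        raise ValueError("target and reference Ct replicates must be matched")
    delta = target - reference
    ddelta = delta - calibrator_delta
    return DdctResult(delta, ddelta, 2.0**-ddelta)


def summarize_replicates(table: pd.DataFrame) -> list[GroupSummary]:
    """Collapse a tidy replicate table (label/value columns) to summaries."""
    out = []
    for label, grp in table.groupby("label", sort=True):
        v = grp["value"].to_numpy(dtype=float)
        out.append(GroupSummary(str(label), float(v.mean()), float(v.std(ddof=1)), len(v)))
    return out


def pooled_t(g1: GroupSummary, g2: GroupSummary) -> TTestResult:
    """Equal-variance two-sample t-test from group summaries.

    sp² = ((n1−1)s1² + (n2−1)s2²)/(n1+n2−2);
    t = (m1−m2)/(sp·√(1/n1+1/n2)), two-sided p from t(n1+n2−2).
    """
    df = g1.n + g2.n - 2
    sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
    diff = g1.mean - g2.mean
    if sp2 == 0:
        if diff == 0:
            return TTestResult(0.0, df, 1.0)
        return TTestResult(float(np.sign(diff)) * np.inf, df, 0.0)
    t = diff / np.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
    pval = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(float(t), df, min(pval, 1.0))


def anova_mse(groups: Sequence[GroupSummary]) -> tuple[float, int]:
    """Pooled within-group mean square (the one-way ANOVA error term)."""
    ss = sum((g.n - 1) * g.sd**2 for g in groups)
    df = sum(g.n - 1 for g in groups)
    return ss / df, df


def lsd_t(
    groups: Sequence[GroupSummary], pair: tuple[str, str]
) -> TTestResult:
    """Fisher's LSD pairwise t using the pooled ANOVA error across all groups.

    No multiplicity correction — the least-significant-difference procedure.
    Reduces exactly to :func:`pooled_t` when only two groups are supplied.
    """
    if len(groups) < 2:
        raise ValueError("lsd_t needs at least two groups")
    lookup = {g.label: g for g in groups}
    try:
        gi, gj = lookup[pair[0]], lookup[pair[1]]
    except KeyError as exc:
        raise ValueError(f"unknown group label {exc.args[0]!r}") from exc
    mse, df = anova_mse(groups)
    diff = gi.mean - gj.mean
    if mse == 0:
        if diff == 0:
            return TTestResult(0.0, df, 1.0)
        return TTestResult(float(np.sign(diff)) * np.inf, df, 0.0)
    t = diff / np.sqrt(mse * (1.0 / gi.n + 1.0 / gj.n))
    pval = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(float(t), df, min(pval, 1.0))


def group_report(
    comparisons: Sequence[tuple[GroupSummary, GroupSummary]]
) -> pd.DataFrame:
    """Table-shaped report: one row per two-group comparison."""
    rows = []
    for g1, g2 in comparisons:
        res = pooled_t(g1, g2)
        rows.append(
            {
                "group1": g1.label,
                "group2": g2.label,
                "mean1": g1.mean,
                "sd1": g1.sd,
                "mean2": g2.mean,
                "sd2": g2.sd,
                "t": res.t,
                "df": res.df,
                "pval": res.pval,
            }
        )
    return pd.DataFrame(rows)
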