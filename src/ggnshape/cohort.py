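"""Group-level comparisons for a lesion cohort table.

The cohort is a DataFrame with one row per lesion: a binary pathology group
label plus the geometric descriptors (and optionally sex/age/lobe).
Categorical variables are compared with Pearson's chi-square (no continuity
correction); continuous descriptors with Welch's t-test by default or the
Mann-Whitney U test as the nonparametric alternative — both are always
reported so the analyst can choose per variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ChiSquareResult",
    "GroupComparison",
    "pearson_chi_square",
    "compare_groups",
]


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    pvalue: float
    expected: np.ndarray


@dataclass(frozen=True)
class GroupComparison:
    """Mean +/- SD per group plus parametric and nonparametric p-values."""

    feature: str
    groups: tuple[str, str]
    n: tuple[int, int]
    mean: tuple[float, float]
    sd: tuple[float, float]
    t_statistic: float
    p_welch: float
    u_statistic: float
    p_mannwhitney: float
    constant: bool = False

    @property
    def p(self) -> float:
        return self.p_welch

    def as_record(self) -> dict:
        g0, g1 = self.groups
        return {
            "feature": self.feature,
            f"mean_{g0}": self.mean[0],
            f"sd_{g0}": self.sd[0],
            f"mean_{g1}": self.mean[1],
            f"sd_{g1}": self.sd[1],
            "p_welch": self.p_welch,
            "p_mannwhitney": self.p_mannwhitney,
            "constant": self.constant,
        }


def pearson_chi_square(table) -> ChiSquareResult:
    """Pearson chi-square on an r x c contingency table.

    No Yates continuity correction; df = (r-1)(c-1); upper-tail p-value.
    Equals the textbook sum over cells of (observed - expected)^2 / expected.
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2:
        raise ValueError("contingency table must be 2D")
    if np.any(tab < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    res = stats.chi2_contingency(tab, correction=False)
    return ChiSquareResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        pvalue=float(res.pvalue),
        expected=res.expected_freq,
    )


def compare_groups(
    cohort: pd.DataFrame,
    feature: str,
    group_col: str = "group",
    groups: tuple[str, str] | None = None,
) -> GroupComparison:
    """Two-group comparison of one continuous descriptor.

    Reports mean +/- SD per group together with the Welch t-test and the
    Mann-Whitney U test (two-sided).  A feature constant across both groups
    yields NaN p-values with the ``constant`` flag set, rather than an error.
    """
    if groups is None:
        uniq = sorted(cohort[group_col].unique())
        if len(uniq) != 2:
            raise ValueError("group column must have exactly two levels")
        groups = (uniq[0], uniq[1])
    a = cohort.loc[cohort[group_col] == groups[0], feature].to_numpy(float)
    b = cohort.loc[cohort[group_col] == groups[1], feature].to_numpy(float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    constant = np.ptp(np.concatenate([a, b])) == 0.0
    if constant:
        t_stat = p_welch = np.nan
        u_stat, p_u = np.nan, np.nan
    else:
        t_res = stats.ttest_ind(a, b, equal_var=False)
        t_stat, p_welch = float(t_res.statistic), float(t_res.pvalue)
        u_res = stats.mannwhitneyu(a, b, alternative="two-sided")
        u_stat, p_u = float(u_res.statistic), float(u_res.pvalue)
    return GroupComparison(
        feature=feature,
        groups=groups,
        n=(len(a), len(b)),
        mean=(float(a.mean()), float(b.mean())),
        sd=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        t_statistic=t_stat,
        p_welch=p_welch,
        u_statistic=u_stat,
        p_mannwhitney=p_u,
        constant=bool(constant),
    )
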