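"""Group-comparison statistics: Mann-Whitney U with Bonferroni families and
Pearson chi-square homogeneity tests.

Ratio comparisons between groups are nonparametric (Mann-Whitney U, two
sided), with Bonferroni adjustment over a named comparison family; defect
frequencies between crosses are compared by chi-square. The family
membership is configuration, not hard-coded — callers assemble the list of
comparisons and pass it to :func:`bonferroni`.

Conventions (documented because they differ between implementations): the
reported U statistic is min(U_x, U_y); the exact two-sided p is the doubled
one-tail probability, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "mann_whitney", "bonferroni", "chi_square_homogeneity"]


@dataclass
class TestResult:
    __test__ = False  # keep pytest from collecting this as a test class

    name: str
    test: str
    statistic: float
    p_raw: float
    df: float | None = None
    group_sizes: tuple[int, ...] = ()
    family_size: int | None = None
    p_adjusted: float | None = None
    significant: bool | None = None
    note: str | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_raw <= 1.0 or np.isnan(self.p_raw)):
            raise ValueError(f"p_raw out of [0, 1]: {self.p_raw}")


def mann_whitney(x, y, mode: str = "auto", name: str = "") -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``mode``: "exact" enumerates the null distribution of U (no ties);
    "asymptotic" uses the tie-corrected normal approximation with continuity
    correction; "auto" picks exact when n*m <= 400 and there are no ties.
    The statistic is min(U_x, U_y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")

    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if mode == "auto":
        method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    elif mode in ("exact", "asymptotic"):
        method = mode
        if method == "exact" and has_ties:
            method = "asymptotic"  # scipy's exact distribution assumes no ties
    else:
        raise ValueError(f"unknown mode {mode!r}")

    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    u_x = float(res.statistic)
    u_min = min(u_x, x.size * y.size - u_x)
    return TestResult(
        name=name,
        test=f"mann-whitney-{method}",
        statistic=u_min,
        p_raw=float(min(res.pvalue, 1.0)),
        group_sizes=(x.size, y.size),
    )


def bonferroni(family: Sequence[TestResult], alpha: float = 0.05) -> list[TestResult]:
    """Bonferroni adjustment over one comparison family.

    m = family size; p_adjusted = min(1, m * p_raw); results are flagged
    significant at ``alpha`` on the adjusted p.
    """
    family = list(family)
    if not family:
        raise ValueError("empty test family")
    m = len(family)
    out = []
    for t in family:
        p_adj = min(1.0, m * t.p_raw)
        out.append(replace(t, family_size=m, p_adjusted=p_adj, significant=bool(p_adj < alpha)))
    return out


def chi_square_homogeneity(table, name: str = "") -> TestResult:
    """Pearson chi-square test of homogeneity on an r x c count table.

    Expected counts come from the margins; df = (r-1)(c-1). No Yates
    correction. Any expected cell below 1 sets a warning note on the result
    rather than failing.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) <= 0) or np.any(table.sum(axis=1) <= 0):
        raise ValueError("all row and column sums must be positive")

    stat, p, df, expected = sps.chi2_contingency(table, correction=False)
    note = None
    if np.any(expected < 1.0):
        note = "expected cell count < 1; chi-square approximation unreliable"
    return TestResult(
        name=name,
        test="chi-square-homogeneity",
        statistic=float(stat),
        p_raw=float(p),
        df=float(df),
        group_sizes=tuple(int(n) for n in table.sum(axis=1)),
        note=note,
    )
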