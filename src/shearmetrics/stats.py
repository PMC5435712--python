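"""Group comparisons and metric-vs-remodelling correlation.

Study tables hold one row per animal: group label (WKY-CON, SHR-CON,
WKY-NIF, SHR-NIF), regional haemodynamic summaries and remodelling
measurements.  Results are reported as mean ± sample SD per group; group
differences are tested by one-way ANOVA or Kruskal-Wallis with Bonferroni-
corrected pairwise comparisons; metric-remodelling association by Pearson
correlation with ordinary least-squares line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

VALID_GROUPS = ("WKY-CON", "SHR-CON", "WKY-NIF", "SHR-NIF")


def _groups(table: pd.DataFrame, variable: str):
    if variable not in table.columns:
        raise KeyError(f"variable {variable!r} not in table")
    if "group" not in table.columns:
        raise KeyError("table needs a 'group' column")
    return [(name, sub[variable].to_numpy(dtype=float))
            for name, sub in table.groupby("group", sort=False)]


def group_summary(table: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Per-group mean and sample SD (n-1 denominator) of a variable."""
    rows = []
    for name, vals in _groups(table, variable):
        if vals.size < 2:
            raise ValueError(
                f"group {name!r} has n={vals.size}; SD needs n >= 2")
        rows.append({"group": name, "n": vals.size,
                     "mean": float(np.mean(vals)),
                     "sd": float(np.std(vals, ddof=1))})
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    method: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, p_raw, p_adjusted
    correction: str = "bonferroni"


def compare_groups(table: pd.DataFrame, variable: str,
                   method: str = "anova") -> GroupComparison:
    """Omnibus multi-group test plus Bonferroni-corrected pairwise tests.

    ``anova`` uses one-way ANOVA with pairwise two-sided t tests;
    ``kruskal_wallis`` uses the Kruskal-Wallis H test with pairwise
    Mann-Whitney U tests. All tests two-sided.
    """
    groups = _groups(table, variable)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = [v for _, v in groups]
    if method == "anova":
        stat, p = sps.f_oneway(*samples)
        pair_test = lambda a, b: sps.ttest_ind(a, b).pvalue  # noqa: E731
    elif method == "kruskal_wallis":
        if all(np.ptp(v) == 0 for v in samples) and len(
                {v[0] for v in samples}) == 1:
            raise ValueError(
                "all observations identical; Kruskal-Wallis is degenerate")
        stat, p = sps.kruskal(*samples)
        pair_test = lambda a, b: sps.mannwhitneyu(  # noqa: E731
            a, b, alternative="two-sided").pvalue
    else:
        raise ValueError("method must be 'anova' or 'kruskal_wallis'")
    names = [n for n, _ in groups]
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            praw = float(pair_test(samples[i], samples[j]))
            rows.append({"group_a": names[i], "group_b": names[j],
                         "p_raw": praw,
                         "p_adjusted": min(1.0, praw * m)})
    return GroupComparison(method=method, statistic=float(stat),
                           p_value=float(p), pairwise=pd.DataFrame(rows))


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    slope: float
    intercept: float
    n: int


def correlate(table: pd.DataFrame, x: str, y: str) -> CorrelationResult:
    """Pearson correlation and least-squares line between two variables.

    The p-value comes from the t transform ``t = r sqrt((n-2)/(1-r^2))``
    with n-2 degrees of freedom (two-sided).
    """
    for col in (x, y):
        if col not in table.columns:
            raise KeyError(f"variable {col!r} not in table")
    xv = table[x].to_numpy(dtype=float)
    yv = table[y].to_numpy(dtype=float)
    ok = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[ok], yv[ok]
    n = xv.size
    if n < 3:
        raise ValueError("correlation needs at least 3 finite pairs")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("correlation undefined: zero variance")
    r, p = sps.pearsonr(xv, yv)
    lin = sps.linregress(xv, yv)
    return CorrelationResult(r=float(r), p_value=float(p),
                             slope=float(lin.slope),
                             intercept=float(lin.intercept), n=n)


def fisher_interval(rho: float, n: int, level: float = 0.95
                    ) -> tuple[float, float]:
    """Fisher-z sampling interval for the sample r around a population rho."""
    if n <= 3:
        raise ValueError("need n > 3")
    z = np.arctanh(rho)
    half = sps.norm.ppf(0.5 + level / 2.0) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def load_study_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if "group" not in table.columns:
        raise ValueError("study table must have a 'group' column")
    bad = set(table["group"]) - set(VALID_GROUPS)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    return table
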