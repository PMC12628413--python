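"""Descriptive statistics and the grouped-comparison routing logic.

The comparison of element means across site-functional groups follows a
normality -> variance-homogeneity -> test-choice route: Shapiro-Wilk per
group (reported, low-powered at n = 4), Levene's test across groups
(median-centered by default, i.e. Brown-Forsythe, matching the software
family the original analysis used; mean centering available), then
one-way ANOVA if variances are homogeneous (p > alpha) and Welch's
heteroscedasticity-robust ANOVA otherwise.

Also provides the Pearson correlation matrix with strength labels and
Bartlett's test of sphericity (the factor-extraction prerequisite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .data_io import ConcentrationTable


@dataclass(frozen=True)
class StatTestResult:
    test: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    alpha: float = 0.05
    routing_note: str = ""
    details: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    @property
    def p_display(self) -> str:
        return "< 0.0001" if self.p_value < 1e-4 else f"{self.p_value:.4f}"


def descriptives(table: ConcentrationTable) -> pd.DataFrame:
    """Per-element max, min, mean, median, SD (n-1) and CV%."""
    d = table.data
    out = pd.DataFrame({
        "Maximum": d.max(),
        "Minimum": d.min(),
        "Mean": d.mean(),
        "Median": d.median(),
        "Standard deviation": d.std(ddof=1),
    })
    out["Coefficient of variation"] = 100 * out["Standard deviation"] / out["Mean"]
    return out


def _group_arrays(table: ConcentrationTable, element: str) -> list[np.ndarray]:
    return [table.data.loc[table.groups == g, element].to_numpy()
            for g in table.group_codes]


def route_group_comparison(
    table: ConcentrationTable,
    element: str,
    alpha: float = 0.05,
    levene_center: str = "median",
) -> StatTestResult:
    """Levene-routed one-way vs Welch ANOVA for one element.

    Returns the routed test; Levene's and per-group Shapiro-Wilk results
    ride along in ``details``.
    """
    groups = _group_arrays(table, element)
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 samples each")

    shapiro = {}
    for code, arr in zip(table.group_codes, groups):
        W, p = stats.shapiro(arr)
        shapiro[code] = {"W": W, "p": p, "note": "low power at small n"}

    degenerate = any(np.ptp(arr) == 0 for arr in groups)
    if degenerate:
        lev_stat, lev_p = np.nan, np.nan
        homogeneous = False
        note = "a group has zero variance; Levene undefined, routing to Welch"
    else:
        lev_stat, lev_p = stats.levene(*groups, center=levene_center)
        homogeneous = lev_p > alpha
        routed = "one-way ANOVA" if homogeneous else "Welch's ANOVA"
        note = f"Levene p {'>' if homogeneous else '<='} {alpha}: {routed}"

    k = len(groups)
    n = sum(len(g) for g in groups)
    details = {
        "shapiro": shapiro,
        "levene": {"statistic": lev_stat, "p": lev_p, "center": levene_center},
    }
    if homogeneous:
        F, p = stats.f_oneway(*groups)
        return StatTestResult("one-way ANOVA", float(F), (k - 1, n - k), float(p),
                              alpha, note, details)
    frame = pd.DataFrame({"y": table.data[element], "g": table.groups})
    aov = pg.welch_anova(dv="y", between="g", data=frame)
    return StatTestResult(
        "Welch's ANOVA", float(aov["F"][0]),
        (float(aov["ddof1"][0]), round(float(aov["ddof2"][0]), 1)),
        float(aov["p_unc"][0]), alpha, note, details,
    )


def correlation_strength(r: float) -> str:
    a = abs(r)
    if a > 0.7:
        return "strong"
    if a >= 0.4:
        return "moderate"
    return "weak"


def pearson_matrix(table: ConcentrationTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Element x element Pearson r with strength labels.

    Constant columns yield undefined correlations, reported as NaN.
    """
    if table.n_samples < 3:
        raise ValueError("need >= 3 samples for a correlation matrix")
    r = table.data.corr(method="pearson")
    constant = table.data.std(ddof=1) == 0
    r.loc[constant, :] = np.nan
    r.loc[:, constant] = np.nan
    np.fill_diagonal(r.values, np.where(constant, np.nan, 1.0))
    labels = r.map(lambda v: "" if pd.isna(v) else correlation_strength(v))
    return r, labels


def bartlett_sphericity(
    table: ConcentrationTable | pd.DataFrame,
) -> StatTestResult:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2p + 5) / 6) * ln det(R), df = p (p - 1) / 2.
    """
    data = table.data if isinstance(table, ConcentrationTable) else table
    n, p = data.shape
    R = np.corrcoef(data.to_numpy(), rowvar=False)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix is singular; Bartlett test undefined")
    chi2 = -(n - 1 - (2 * p + 5) / 6) * logdet
    df = p * (p - 1) / 2
    pval = float(stats.chi2.sf(chi2, df))
    return StatTestResult("Bartlett's sphericity", float(chi2), (df,), pval)


def group_comparison_table(table: ConcentrationTable, **kwargs) -> pd.DataFrame:
    """Routing summary for every element (the study's Table-2 shape)."""
    rows = {}
    for el in table.data.columns:
        res = route_group_comparison(table, el, **kwargs)
        lev = res.details["levene"]
        rows[el] = {
            "levene_statistic": lev["statistic"],
            "levene_p": lev["p"],
            "test": res.test,
            "F": res.statistic,
            "p": res.p_value,
            "df1": res.df[0],
            "df2": res.df[1],
            "p_display": res.p_display,
        }
    return pd.DataFrame(rows).T
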