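"""Hakanson ecological risk factors and the summed risk index.

Each element's individual ecological risk factor weights its contamination
factor by a toxic-response factor Tr:  Er = Tr * CF.  The overall risk
index RI is the sum of Er over the elements with a defined Tr (here Pb,
Cu, Zn, Ni, Cr, Mn; Fe has no established factor and is skipped with a log
notice, never silently zeroed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .data_io import ConcentrationTable, ReferenceSet, DEFAULT_REFERENCE
from .pollution_indices import contamination_factor

log = logging.getLogger(__name__)


def classify_er(er: float) -> str:
    if er < 40:
        return "low risk"
    if er < 80:
        return "moderate risk"
    if er < 160:
        return "considerable risk"
    if er < 320:
        return "high risk"
    return "very high risk"


def classify_ri(ri: float) -> str:
    if ri < 150:
        return "low risk"
    if ri < 300:
        return "moderate risk"
    if ri < 600:
        return "considerable risk"
    return "very high risk"


def ecological_risk_factor(
    cfs: pd.DataFrame, ref: ReferenceSet = DEFAULT_REFERENCE
) -> pd.DataFrame:
    """Per-(sample, element) Er = Tr * CF over elements with a defined Tr."""
    skipped = [el for el in cfs.columns if el not in ref.toxic_response]
    if skipped:
        log.info("no toxic-response factor for %s; excluded from Er/RI", skipped)
    kept = [el for el in cfs.columns if el in ref.toxic_response]
    tr = pd.Series({el: ref.toxic_response[el] for el in kept})
    return cfs[kept] * tr


def risk_index(ers: pd.DataFrame | pd.Series) -> pd.Series | float:
    """RI = sum of Er over elements, per sample (or for one profile)."""
    if isinstance(ers, pd.Series):
        return float(ers.sum())
    return ers.sum(axis=1)


@dataclass(frozen=True)
class EcoRiskReport:
    er: pd.DataFrame            # per-(sample, element)
    ri: pd.Series               # per sample
    group_means: pd.DataFrame   # per-group mean Er and RI
    summary: pd.DataFrame       # mean/max/min/SD rows over all samples
    er_class: pd.DataFrame
    ri_class: pd.Series


def eco_risk_report(
    table: ConcentrationTable, ref: ReferenceSet = DEFAULT_REFERENCE
) -> EcoRiskReport:
    cf = contamination_factor(table, ref)
    er = ecological_risk_factor(cf, ref)
    ri = risk_index(er)
    both = er.assign(RI=ri)
    group_means = both.groupby(table.groups, sort=False).mean().loc[table.group_codes]
    summary = pd.DataFrame({
        "Maximum": both.max(),
        "Minimum": both.min(),
        "Mean": both.mean(),
        "Standard deviation": both.std(ddof=1),
    }).T
    return EcoRiskReport(
        er=er,
        ri=ri,
        group_means=group_means,
        summary=summary,
        er_class=er.map(classify_er),
        ri_class=ri.map(classify_ri),
    )
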