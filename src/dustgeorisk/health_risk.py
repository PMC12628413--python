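"""USEPA source-pathway-receptor human health risk model.

Average daily doses (ADD, mg/kg/day) for three exposure pathways:

* ingestion:   C * IR_ing * ED * EF / (BW * AT) * UCF
* inhalation:  C * IR_inh * ED * EF / (BW * AT * PEF)
* dermal:      C * SA * AF * DAF * ED * EF / (BW * AT) * UCF

where C is the dust concentration (mg/kg) and UCF = 1e-6 kg/mg converts it
to mg/mg (no UCF for inhalation, where PEF [m^3/kg] does the conversion).
Non-carcinogenic risk: HQ = ADD / RfD per pathway; HI = sum of the three
HQs, threshold 1.  Carcinogenic risk (Pb, Ni, Cr): CR = ADD * CSF per
pathway; TCR = sum, with bands at 1e-6 (insignificant below) and 1e-4
(unacceptable above).

The default receptor scenarios and toxicity values replicate the study
this package accompanies.  Two deliberate replication choices, each with
an orthodox alternative exposed as an option:

* carcinogenic doses use the same averaging time as the non-carcinogenic
  model (AT = ED * 365); ``lifetime_at=True`` switches to the USEPA
  lifetime convention AT = 70 * 365.
* the Cr inhalation slope factor defaults to the oral value 0.5; the
  conventional inhalation unit-risk-derived value (42) is selectable via
  ``ToxicityReference.orthodox_cr_inhalation()``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .data_io import ConcentrationTable

PATHWAYS = ("ingestion", "inhalation", "dermal")
NONCARC_ELEMENTS = ("Pb", "Cu", "Zn", "Ni", "Cr")
CARC_ELEMENTS = ("Pb", "Ni", "Cr")


class ConfigurationError(ValueError):
    """A required exposure or toxicity parameter is missing."""


@dataclass(frozen=True)
class ExposureScenario:
    """Receptor-specific exposure parameters.

    Units: IR_ing mg/day; IR_inh m^3/day; EF days/year; ED years; BW kg;
    AT days; SA cm^2; AF mg/(cm^2 day); DAF dimensionless; PEF m^3/kg;
    UCF kg/mg.
    """

    receptor: str
    IR_ing: float
    IR_inh: float
    EF: float
    ED: float
    BW: float
    AT: float
    SA: float
    AF: float
    DAF: float
    PEF: float = 1.36e9
    UCF: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("IR_ing", "IR_inh", "EF", "ED", "BW", "AT", "SA", "AF",
                     "DAF", "PEF", "UCF"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"scenario parameter {name} must be positive")

    def with_lifetime_at(self, lifetime_years: float = 70.0) -> "ExposureScenario":
        return replace(self, AT=lifetime_years * 365.0)


#: Child receptor (6-year exposure).  IR_inh = 7.63 m^3/day is the USEPA
#: child inhalation rate; it reproduces the study's printed child
#: inhalation doses exactly.
CHILD = ExposureScenario(
    receptor="child", IR_ing=200, IR_inh=7.63, EF=350, ED=6, BW=15,
    AT=6 * 365, SA=2800, AF=0.2, DAF=0.001,
)
ADULT = ExposureScenario(
    receptor="adult", IR_ing=100, IR_inh=20, EF=350, ED=24, BW=70,
    AT=24 * 365, SA=5700, AF=0.07, DAF=0.001,
)
DEFAULT_SCENARIOS = (CHILD, ADULT)


@dataclass(frozen=True)
class ToxicityReference:
    """Per-element, per-pathway reference doses and cancer slope factors.

    ``rfd[element][pathway]`` in mg/kg/day; ``csf[element][pathway]`` in
    (mg/kg/day)^-1.  Either may be absent: HQ is only computed where an
    RfD exists, CR only where a CSF exists.
    """

    rfd: Mapping[str, Mapping[str, float]]
    csf: Mapping[str, Mapping[str, float]]

    def orthodox_cr_inhalation(self) -> "ToxicityReference":
        csf = {el: dict(v) for el, v in self.csf.items()}
        csf.setdefault("Cr", {})["inhalation"] = 42.0
        return ToxicityReference(self.rfd, csf)


DEFAULT_TOXICITY = ToxicityReference(
    rfd={
        "Pb": {"ingestion": 3.5e-3, "inhalation": 3.52e-3, "dermal": 5.25e-4},
        "Cu": {"ingestion": 4.0e-2, "inhalation": 4.02e-2, "dermal": 1.2e-2},
        "Zn": {"ingestion": 3.0e-1, "inhalation": 3.0e-1, "dermal": 6.0e-2},
        "Ni": {"ingestion": 2.0e-2, "inhalation": 2.06e-2, "dermal": 5.4e-3},
        "Cr": {"ingestion": 3.0e-3, "inhalation": 2.86e-5, "dermal": 6.0e-5},
    },
    csf={
        "Pb": {p: 8.5e-3 for p in PATHWAYS},
        "Ni": {p: 8.4e-1 for p in PATHWAYS},
        "Cr": {p: 5.0e-1 for p in PATHWAYS},
    },
)


def average_daily_dose(
    conc: float, scenario: ExposureScenario, pathway: str
) -> float:
    """ADD (mg/kg/day) of one pathway for a concentration in mg/kg."""
    t = scenario.ED * scenario.EF / (scenario.BW * scenario.AT)
    if pathway == "ingestion":
        return conc * scenario.IR_ing * t * scenario.UCF
    if pathway == "inhalation":
        return conc * scenario.IR_inh * t / scenario.PEF
    if pathway == "dermal":
        return conc * scenario.SA * scenario.AF * scenario.DAF * t * scenario.UCF
    raise ConfigurationError(f"unknown pathway {pathway!r}")


def doses_frame(
    concentrations: Mapping[str, float] | pd.Series,
    scenario: ExposureScenario,
    elements: tuple[str, ...] = NONCARC_ELEMENTS,
) -> pd.DataFrame:
    """ADD per (element, pathway) for one receptor."""
    rows = {
        el: {p: average_daily_dose(float(concentrations[el]), scenario, p)
             for p in PATHWAYS}
        for el in elements
    }
    return pd.DataFrame(rows).T[list(PATHWAYS)]


def hazard_quotients(
    adds: pd.DataFrame, tox: ToxicityReference = DEFAULT_TOXICITY
) -> pd.DataFrame:
    """HQ per (element, pathway) and the summed hazard index HI.

    Pathways whose RfD is absent are reported as NaN (unavailable), never
    as zero; HI sums the available HQs.
    """
    hq = pd.DataFrame(np.nan, index=adds.index, columns=list(PATHWAYS))
    for el in adds.index:
        for p in PATHWAYS:
            rfd = tox.rfd.get(el, {}).get(p)
            if rfd is not None:
                hq.loc[el, p] = adds.loc[el, p] / rfd
    hq["HI"] = hq[list(PATHWAYS)].sum(axis=1)
    hq["exceeds_threshold"] = hq["HI"] > 1.0
    return hq


def classify_tcr(tcr: float) -> str:
    if tcr < 1e-6:
        return "insignificant"
    if tcr <= 1e-4:
        return "acceptable"
    return "unacceptable"


def carcinogenic_risks(
    adds: pd.DataFrame, tox: ToxicityReference = DEFAULT_TOXICITY
) -> pd.DataFrame:
    """CR per (element, pathway) and the total carcinogenic risk TCR."""
    elements = [el for el in adds.index if el in tox.csf]
    cr = pd.DataFrame(np.nan, index=pd.Index(elements, name=adds.index.name),
                      columns=list(PATHWAYS))
    for el in elements:
        for p in PATHWAYS:
            csf = tox.csf[el].get(p)
            if csf is not None:
                cr.loc[el, p] = adds.loc[el, p] * csf
    cr["TCR"] = cr[list(PATHWAYS)].sum(axis=1)
    cr["class"] = cr["TCR"].map(classify_tcr)
    return cr


@dataclass(frozen=True)
class RiskReport:
    adds: dict[str, pd.DataFrame]   # receptor -> ADD frame
    hq: dict[str, pd.DataFrame]     # receptor -> HQ/HI frame
    cr: dict[str, pd.DataFrame]     # receptor -> CR/TCR frame


def health_risk_report(
    table: ConcentrationTable | Mapping[str, float] | pd.Series,
    scenarios: tuple[ExposureScenario, ...] = DEFAULT_SCENARIOS,
    tox: ToxicityReference = DEFAULT_TOXICITY,
    lifetime_at: bool = False,
    lifetime_years: float = 70.0,
) -> RiskReport:
    """Full risk characterisation from all-sample mean concentrations.

    ``table`` may be a concentration table (its mean profile is used, the
    study's convention) or a ready element -> concentration mapping.
    """
    conc = table.mean_profile() if isinstance(table, ConcentrationTable) else table
    adds, hqs, crs = {}, {}, {}
    for sc in scenarios:
        a = doses_frame(conc, sc)
        adds[sc.receptor] = a
        hqs[sc.receptor] = hazard_quotients(a, tox)
        sc_cr = sc.with_lifetime_at(lifetime_years) if lifetime_at else sc
        a_cr = a if not lifetime_at else doses_frame(conc, sc_cr)
        crs[sc.receptor] = carcinogenic_risks(
            a_cr.loc[[el for el in a_cr.index if el in tox.csf]], tox
        )
    return RiskReport(adds=adds, hq=hqs, cr=crs)
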