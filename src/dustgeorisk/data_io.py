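"""Core data model and I/O for element concentration tables.

The pipeline's universal input is a samples x elements matrix of total
concentrations (mg/kg) with a categorical site-functional group label per
sample.  The packaged study dataset holds 24 mineral-dust samples from an
iron mine, in six functional groups of four: surface drilling (A1),
crushing/grinding (A2), transport and unloading (A3), machinery-cabin
interiors (B1), truck exterior surfaces (B2) and interior pathways (C).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Canonical element order used by every report in the package.
ELEMENTS: tuple[str, ...] = ("Pb", "Cu", "Zn", "Ni", "Cr", "Mn", "Fe")

#: Group codes of the packaged dataset (arbitrary labels are accepted for
#: user data; >= 2 groups with >= 2 samples each are required by the
#: statistics module).
FIXTURE_GROUPS: tuple[str, ...] = ("A1", "A2", "A3", "B1", "B2", "C")

WIDE_COLUMNS = ("sample_id", "group") + ELEMENTS
LONG_COLUMNS = ("sample_id", "group", "element", "concentration_mg_kg")


class SchemaError(ValueError):
    """A required column or field is missing from an input file."""


class ValidationError(ValueError):
    """An input value violates the data model (negative, non-numeric...)."""


@dataclass(frozen=True)
class ConcentrationTable:
    """Validated samples x elements concentration matrix (mg/kg).

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with exactly the columns
        :data:`ELEMENTS`, in canonical order, all values finite and >= 0.
    groups:
        Series of group labels aligned with ``data.index``.
    """

    data: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        df = self.data
        if list(df.columns) != list(ELEMENTS):
            missing = set(ELEMENTS) - set(df.columns)
            if missing:
                raise SchemaError(f"missing element column(s): {sorted(missing)}")
            object.__setattr__(self, "data", df.loc[:, list(ELEMENTS)])
            df = self.data
        if not df.index.equals(self.groups.index):
            raise ValidationError("group labels are not aligned with sample ids")
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = df.stack()[~np.isfinite(df.stack())]
            row, col = bad.index[0]
            raise ValidationError(f"non-finite concentration at row {row!r}, column {col!r}")
        if (values < 0).any():
            bad = df.stack()[df.stack() < 0]
            row, col = bad.index[0]
            raise ValidationError(f"negative concentration at row {row!r}, column {col!r}")

    # ------------------------------------------------------------------
    @property
    def samples(self) -> pd.Index:
        return self.data.index

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def group_codes(self) -> list[str]:
        """Group labels in order of first appearance."""
        return list(dict.fromkeys(self.groups))

    def group_means(self) -> pd.DataFrame:
        """Per-group arithmetic mean concentration profile."""
        gm = self.data.groupby(self.groups, sort=False).mean()
        return gm.loc[self.group_codes]

    def mean_profile(self) -> pd.Series:
        """All-sample arithmetic mean concentration per element."""
        return self.data.mean()

    def subset(self, samples: Iterable[str]) -> "ConcentrationTable":
        idx = list(samples)
        return ConcentrationTable(self.data.loc[idx], self.groups.loc[idx])

    # ------------------------------------------------------------------
    def to_wide_frame(self) -> pd.DataFrame:
        out = self.data.copy()
        out.insert(0, "group", self.groups)
        out.insert(0, "sample_id", self.data.index)
        return out.reset_index(drop=True)

    def to_long_frame(self) -> pd.DataFrame:
        long = (
            self.to_wide_frame()
            .melt(id_vars=["sample_id", "group"], var_name="element",
                  value_name="concentration_mg_kg")
        )
        return long

    def write(self, path: str | Path, layout: str = "wide") -> None:
        frame = self.to_wide_frame() if layout == "wide" else self.to_long_frame()
        frame.to_csv(path, index=False)


def _validate_numeric(frame: pd.DataFrame, columns: Iterable[str]) -> None:
    for col in columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad):
            row = frame.loc[bad[0], "sample_id"] if "sample_id" in frame else bad[0]
            raise ValidationError(f"non-numeric value in column {col!r} at row {row!r}")
        frame[col] = coerced


def load_concentration_table(path: str | Path, layout: str = "wide") -> ConcentrationTable:
    """Read a concentration table from CSV.

    ``layout='wide'`` expects columns ``sample_id, group, Pb, ..., Fe``;
    ``layout='long'`` expects ``sample_id, group, element,
    concentration_mg_kg``.  Element names are normalised to canonical
    symbols (case-insensitive).  Units are taken to be mg/kg.
    """
    frame = pd.read_csv(path)
    if layout == "long":
        missing = set(LONG_COLUMNS) - set(frame.columns)
        if missing:
            raise SchemaError(f"missing column(s) in long layout: {sorted(missing)}")
        canon = {e.lower(): e for e in ELEMENTS}
        frame["element"] = [
            canon.get(str(e).strip().lower(), str(e).strip()) for e in frame["element"]
        ]
        unknown = set(frame["element"]) - set(ELEMENTS)
        if unknown:
            raise SchemaError(f"unknown element(s): {sorted(unknown)}")
        _validate_numeric(frame, ["concentration_mg_kg"])
        wide = frame.pivot_table(
            index=["sample_id", "group"], columns="element",
            values="concentration_mg_kg", sort=False,
        ).reset_index()
        wide.columns.name = None
    elif layout == "wide":
        canon = {c.lower(): c for c in WIDE_COLUMNS}
        frame = frame.rename(columns={c: canon.get(str(c).strip().lower(), c)
                                      for c in frame.columns})
        missing = set(WIDE_COLUMNS) - set(frame.columns)
        if missing:
            raise SchemaError(f"missing column(s) in wide layout: {sorted(missing)}")
        _validate_numeric(frame, list(ELEMENTS))
        wide = frame
    else:
        raise ValueError(f"unknown layout {layout!r}")

    if wide[list(ELEMENTS)].isna().any().any():
        bad = wide[list(ELEMENTS)].isna().stack()
        (row, col) = bad[bad].index[0]
        raise ValidationError(
            f"missing concentration for sample {wide.loc[row, 'sample_id']!r}, element {col!r}"
        )
    data = wide.set_index("sample_id")[list(ELEMENTS)].astype(float)
    groups = wide.set_index("sample_id")["group"].astype(str)
    return ConcentrationTable(data, groups)


# ----------------------------------------------------------------------
# Geochemical reference sets
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceSet:
    """Per-element geochemical background plus Hakanson toxic-response factors.

    ``background`` holds the baseline concentration B_n (mg/kg) used by the
    contamination indices; ``toxic_response`` the dimensionless weights used
    by the ecological risk factor (absent for elements without an
    established factor, e.g. Fe).
    """

    name: str
    background: Mapping[str, float]
    toxic_response: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.background.values()):
            raise ValidationError(f"background values must be positive in {self.name!r}")


#: Hakanson toxic-response factors for the studied elements; Mn = 1 is
#: implied by the study's per-sample risk table (Er(Mn) == CF(Mn)); Fe has
#: no established factor and is excluded from ecological risk.
TOXIC_RESPONSE: dict[str, float] = {"Pb": 5, "Cu": 5, "Ni": 5, "Cr": 2, "Zn": 1, "Mn": 1}

AVERAGE_SHALE = ReferenceSet(
    "turekian_wedepohl_shale",
    {"Pb": 20, "Cu": 45, "Zn": 95, "Ni": 68, "Cr": 90, "Mn": 850, "Fe": 47_200},
    TOXIC_RESPONSE,
)
UPPER_CONTINENTAL_CRUST = ReferenceSet(
    "wedepohl_upper_crust",
    {"Pb": 17, "Cu": 14.3, "Zn": 52, "Ni": 18.6, "Cr": 35, "Mn": 527, "Fe": 30_890},
    TOXIC_RESPONSE,
)
CRUSTAL_ABUNDANCE = ReferenceSet(
    "yaroshevsky_crust",
    {"Pb": 16, "Cu": 47, "Zn": 83, "Ni": 58, "Cr": 83, "Mn": 1000, "Fe": 46_500},
    TOXIC_RESPONSE,
)

DEFAULT_REFERENCE = AVERAGE_SHALE


def builtin_reference_sets() -> list[ReferenceSet]:
    """The three packaged background sets; average shale is the default."""
    return [AVERAGE_SHALE, UPPER_CONTINENTAL_CRUST, CRUSTAL_ABUNDANCE]


def get_reference_set(name: str) -> ReferenceSet:
    for ref in builtin_reference_sets():
        if ref.name == name:
            return ref
    names = [r.name for r in builtin_reference_sets()]
    raise KeyError(f"unknown reference set {name!r}; available: {names}")


def fixture_table() -> ConcentrationTable:
    """The packaged 24-sample study dataset (six groups of four)."""
    with resources.as_file(
        resources.files("dustgeorisk").joinpath("data/elgedida_dust.csv")
    ) as path:
        return load_concentration_table(path, layout="wide")
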