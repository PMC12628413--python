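"""Synthetic concentration tables with grouped structure.

Generates strictly positive samples x elements matrices whose per-group
location/scale match a specification, by default parameterised from the
packaged dataset's group means and within-group standard deviations.
Concentrations are drawn lognormally (they are positive and right-skewed;
the packaged data's Cu column has a CV of ~143%), with moment matching so
the requested arithmetic mean and SD are recovered; optional inter-element
correlation is applied to the underlying Gaussian (a Gaussian copula in
log space), which preserves positivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ELEMENTS, ConcentrationTable, fixture_table


class ParameterError(ValueError):
    """A synthetic-data parameter is infeasible (e.g. non-PSD correlation)."""


@dataclass
class SyntheticSpec:
    """Specification of a grouped synthetic concentration table.

    ``element_params[(group, element)]`` holds ``(location, scale)`` as the
    arithmetic mean and SD of the target distribution in mg/kg.
    ``distribution`` is ``"lognormal"`` (default) or ``"truncnorm"``
    (normal truncated at zero).  ``correlation``, if given, is an
    n_elements x n_elements matrix applied within every group.
    """

    groups: list[tuple[str, int]]
    element_params: dict[tuple[str, str], tuple[float, float]]
    distribution: str = "lognormal"
    correlation: np.ndarray | None = None
    seed: int = 0
    elements: tuple[str, ...] = ELEMENTS

    def __post_init__(self) -> None:
        for (g, el), (loc, scale) in self.element_params.items():
            if scale < 0:
                raise ParameterError(f"negative scale for ({g}, {el})")
            if loc <= 0:
                raise ParameterError(f"non-positive location for ({g}, {el})")
        if self.correlation is not None:
            C = np.asarray(self.correlation, float)
            p = len(self.elements)
            if C.shape != (p, p) or not np.allclose(C, C.T):
                raise ParameterError("correlation matrix must be symmetric p x p")
            if not np.allclose(np.diag(C), 1.0):
                raise ParameterError("correlation matrix must have unit diagonal")
            if np.linalg.eigvalsh(C).min() < -1e-10:
                raise ParameterError("correlation matrix is not positive semi-definite")
            self.correlation = C


def default_spec_from_fixture(seed: int = 0) -> SyntheticSpec:
    """Spec matching the packaged dataset: six groups of four, per-group
    element means and within-group sample SDs (n-1 denominator)."""
    table = fixture_table()
    means = table.data.groupby(table.groups, sort=False).mean()
    sds = table.data.groupby(table.groups, sort=False).std(ddof=1)
    params = {
        (g, el): (float(means.loc[g, el]), float(sds.loc[g, el]))
        for g in means.index
        for el in ELEMENTS
    }
    groups = [(g, int((table.groups == g).sum())) for g in table.group_codes]
    return SyntheticSpec(groups=groups, element_params=params, seed=seed)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of ln X for arithmetic mean/SD of X."""
    if sd == 0:
        return np.log(mean), 0.0
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2, np.sqrt(sigma2)


def generate(spec: SyntheticSpec, seed: int | None = None) -> ConcentrationTable:
    """Draw a reproducible concentration table from ``spec``.

    A single integer seed (``spec.seed`` unless overridden) governs all
    draws.  Sample ids are ``S1..Sn`` in group order.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    elements = list(spec.elements)
    p = len(elements)
    if spec.correlation is not None:
        # eigendecomposition handles the PSD-but-singular case Cholesky cannot
        w, V = np.linalg.eigh(spec.correlation)
        L = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    else:
        L = np.eye(p)

    rows, labels, ids = [], [], []
    counter = 1
    for group, n in spec.groups:
        Z = rng.standard_normal((n, p)) @ L.T
        block = np.empty((n, p))
        for j, el in enumerate(elements):
            loc, scale = spec.element_params[(group, el)]
            if spec.distribution == "lognormal":
                mu, sigma = _lognormal_params(loc, scale)
                block[:, j] = np.exp(mu + sigma * Z[:, j])
            elif spec.distribution == "truncnorm":
                x = loc + scale * Z[:, j]
                # re-draw (marginally) until positive; keeps it simple and exact
                bad = x <= 0
                while bad.any():
                    x[bad] = loc + scale * rng.standard_normal(bad.sum())
                    bad = x <= 0
                block[:, j] = x
            else:
                raise ParameterError(f"unknown distribution {spec.distribution!r}")
        rows.append(block)
        labels.extend([group] * n)
        ids.extend(f"S{counter + i}" for i in range(n))
        counter += n

    data = pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="sample_id"),
                        columns=elements)
    groups = pd.Series(labels, index=data.index, name="group")
    return ConcentrationTable(data, groups)
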