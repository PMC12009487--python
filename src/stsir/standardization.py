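"""Indirect standardization: expected counts and crude SIRs.

Expected counts allocate the pooled case total to regions in proportion to
population: within a stratum s (a single year, or the whole panel),
``E_i = n_i * (sum Y / sum n)``.  The crude standardized incidence ratio is
``SIR_ij = Y_ij / E_ij``; values above 1 mean more cases than the region's
population share would predict.

No age or sex adjustment is performed: the standardization is purely
population-proportional, which is a documented limitation for registries
whose regions differ in age structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import CountPanel

logger = logging.getLogger(__name__)

__all__ = ["ExpectedMatrix", "SIRMatrix", "expected_counts", "crude_sir", "sir_table"]

VALID_STRATIFICATIONS = ("per_year", "overall")


@dataclass(frozen=True)
class ExpectedMatrix:
    """Indirectly standardized expected counts E_ij.

    In ``per_year`` mode the expecteds are calibrated within every year
    (sum_i E_ij = sum_i Y_ij exactly); in ``overall`` mode only the grand
    totals match.
    """

    expected: np.ndarray
    stratification: str

    def __post_init__(self):
        if self.stratification not in VALID_STRATIFICATIONS:
            raise ValueError(f"unknown stratification {self.stratification!r}")
        object.__setattr__(self, "expected", np.asarray(self.expected, dtype=float))


@dataclass(frozen=True)
class SIRMatrix:
    """Crude SIRs Y_ij / E_ij; cells with E=0 and Y>0 are NaN (undefined)."""

    sir: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "sir", np.asarray(self.sir, dtype=float))


def expected_counts(panel: CountPanel, stratification: str = "per_year") -> ExpectedMatrix:
    """Compute indirectly standardized expected counts.

    per_year: ``E_ij = n_ij * (sum_i Y_ij / sum_i n_ij)`` within each year j.
    overall:  ``E_ij = n_ij * (sum_ij Y_ij / sum_ij n_ij)``.

    A stratum whose case total is zero yields E = 0 there, with a warning.
    """
    if stratification not in VALID_STRATIFICATIONS:
        raise ValueError(f"unknown stratification {stratification!r}")
    Y = panel.observed.astype(float)
    n = panel.population
    if stratification == "per_year":
        year_cases = Y.sum(axis=0)
        year_pop = n.sum(axis=0)
        if np.any(year_cases == 0):
            zero_years = [panel.years[j] for j in np.nonzero(year_cases == 0)[0]]
            logger.warning("zero case total in year(s) %s: E set to 0 there", zero_years)
        rate = np.divide(year_cases, year_pop)
        E = n * rate[None, :]
    else:
        total = Y.sum()
        if total == 0:
            logger.warning("zero case total overall: E is identically 0")
        E = n * (total / n.sum())
    return ExpectedMatrix(E, stratification)


def crude_sir(panel: CountPanel, expected: ExpectedMatrix) -> SIRMatrix:
    """Elementwise crude SIR = Y / E.

    Cells with E=0 and Y>0 are undefined and returned as NaN (never inf);
    cells with E=0 and Y=0 are returned as NaN as well.
    """
    Y = panel.observed.astype(float)
    E = expected.expected
    if Y.shape != E.shape:
        raise ValueError(f"shape mismatch: observed {Y.shape} vs expected {E.shape}")
    with np.errstate(divide="ignore", invalid="ignore"):
        sir = np.where(E > 0, Y / np.where(E > 0, E, 1.0), np.nan)
    if np.any((E == 0) & (Y > 0)):
        logger.warning("SIR undefined (E=0 with Y>0) in %d cells", int(((E == 0) & (Y > 0)).sum()))
    return SIRMatrix(sir)


def sir_table(panel: CountPanel, expected: ExpectedMatrix, sir: SIRMatrix) -> pd.DataFrame:
    """Long-format report table: region, year, observed, expected, sir.

    SIRs are kept at full precision internally; round only for presentation.
    """
    rows = []
    for i, r in enumerate(panel.region_ids):
        for j, y in enumerate(panel.years):
            rows.append(
                (r, y, int(panel.observed[i, j]), expected.expected[i, j], sir.sir[i, j])
            )
    return pd.DataFrame(rows, columns=["region", "year", "observed", "expected", "sir"])
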