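"""Correlation ledger linking microscopic properties to sorption free energy.

Each property column (H-bond counts, contact integrals, energy components,
surface fractions, ...) is regressed against the sorption free-energy
response; Pearson r, the OLS line, and the best-fitting slope-1 offset are
reported.  The slope-1 offset is what remains meaningful when the response is
only known up to an additive constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, UndefinedStatisticError

__all__ = [
    "pearson",
    "linear_fit",
    "unit_slope_fit",
    "strength_class",
    "CorrelationReport",
    "correlation_table",
]

#: |r| thresholds for the reported strength classes (reporting only).
STRONG_R = 0.7
MODERATE_R = 0.4


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-d series of equal length")
    if x.size < 3:
        raise InvalidInputError("need at least 3 paired values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidInputError("series must be finite")
    return x, y


def pearson(x, y) -> float:
    """Product-moment correlation coefficient."""
    x, y = _paired(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant series")
    return float(stats.pearsonr(x, y).statistic)


def linear_fit(x, y) -> tuple[float, float]:
    """Ordinary least-squares line: (slope, intercept)."""
    x, y = _paired(x, y)
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("regression undefined for constant x")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


def unit_slope_fit(x, y) -> float:
    """Least-squares intercept at fixed slope 1: offset = mean(y − x)."""
    x, y = _paired(x, y)
    return float(np.mean(y - x))


def strength_class(r: float) -> str:
    a = abs(r)
    if a >= STRONG_R:
        return "strong"
    if a >= MODERATE_R:
        return "moderate"
    return "weak"


@dataclass
class CorrelationReport:
    """Per-property correlation/regression ledger against the response."""

    response: str
    table: pd.DataFrame  # index: property; columns: r, slope, intercept, offset, strength

    def strong(self) -> pd.DataFrame:
        return self.table[self.table["strength"] == "strong"]


def correlation_table(
    pt: pd.DataFrame, response: str = "dG_sorb"
) -> CorrelationReport:
    """Correlate every property column of a compound table with the response.

    Constant property columns are flagged (strength ``undefined``, r NaN)
    rather than fatal; the response itself must be complete and non-constant.
    """
    if response not in pt.columns:
        raise InvalidInputError(f"response column {response!r} missing")
    y = pt[response].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise InvalidInputError("response column has missing values")
    if len(pt) < 3:
        raise InvalidInputError("need at least 3 compounds")
    rows = {}
    for col in pt.columns:
        if col == response or not pd.api.types.is_numeric_dtype(pt[col]):
            continue
        x = pt[col].to_numpy(dtype=float)
        try:
            r = pearson(x, y)
            slope, intercept = linear_fit(x, y)
            rows[col] = dict(
                r=r, slope=slope, intercept=intercept,
                offset=unit_slope_fit(x, y), strength=strength_class(r),
            )
        except UndefinedStatisticError:
            rows[col] = dict(
                r=np.nan, slope=np.nan, intercept=np.nan,
                offset=unit_slope_fit(x, y), strength="undefined",
            )
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "property"
    return CorrelationReport(response=response, table=table)
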