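"""Descriptive statistics and Pearson correlation screening for exposure data.

Correlations between element concentrations across stations are a standard
first look at whether metals share a source: a significant positive r is
read as a common origin, near-zero or negative r as distinct sources.
Significance uses the exact t transform r*sqrt(n-2)/sqrt(1-r^2) with n-2
degrees of freedom, two-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import DataError, ExposureTable

__all__ = ["ElementSummary", "CorrelationMatrix", "element_summary", "pearson_matrix"]


@dataclass(frozen=True)
class ElementSummary:
    """Per-element mean, sample SD, and empirical median over stations.

    ``table`` has one row per element with columns ``mean``, ``sd``,
    ``median``, ``n``; units are those of the source exposure table.  With a
    single station the SD is undefined and reported as NaN with
    ``sd_defined`` False.
    """

    table: pd.DataFrame
    unit: str
    sd_defined: bool

    def median(self, element: str) -> float:
        return float(self.table.loc[element, "median"])

    def mean(self, element: str) -> float:
        return float(self.table.loc[element, "mean"])


@dataclass(frozen=True)
class CorrelationMatrix:
    """Element-by-element Pearson r with two-tailed p-values and flags.

    ``significant`` is True exactly where p < alpha.  ``r`` is symmetric
    with a unit diagonal; values are unrounded (round only for display).
    """

    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    n: int
    alpha: float = 0.05

    def rounded(self, ndigits: int = 2) -> pd.DataFrame:
        return self.r.round(ndigits)


def element_summary(table: ExposureTable) -> ElementSummary:
    """Arithmetic mean, sample SD (n-1), and median per element.

    The median of an even-length column is the mean of the two central order
    statistics.
    """
    n = len(table.stations)
    rows = {}
    for el in table.elements:
        x = table.column(el)
        xs = np.sort(x)
        if n % 2:
            med = xs[n // 2]
        else:
            med = 0.5 * (xs[n // 2 - 1] + xs[n // 2])
        rows[el] = {
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)) if n > 1 else float("nan"),
            "median": float(med),
            "n": n,
        }
    return ElementSummary(
        table=pd.DataFrame.from_dict(rows, orient="index"),
        unit=table.unit,
        sd_defined=n > 1,
    )


def pearson_matrix(table: ExposureTable, alpha: float = 0.05) -> CorrelationMatrix:
    """Product-moment correlations between element columns over stations.

    Requires >= 3 stations and no constant column.  p-values come from the
    exact two-tailed t test with n-2 degrees of freedom.
    """
    n = len(table.stations)
    if n < 3:
        raise DataError(f"need >= 3 stations for correlations, got {n}")
    for el in table.elements:
        if np.ptp(table.column(el)) == 0:
            raise DataError(f"element {el!r} is constant across stations")
    elements = table.elements
    k = len(elements)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            rij, pij = stats.pearsonr(table.column(elements[i]), table.column(elements[j]))
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    r_df = pd.DataFrame(r, index=elements, columns=elements)
    p_df = pd.DataFrame(p, index=elements, columns=elements)
    sig = (p_df < alpha) & ~np.eye(k, dtype=bool)
    return CorrelationMatrix(r=r_df, p=p_df, significant=sig, n=n, alpha=alpha)
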