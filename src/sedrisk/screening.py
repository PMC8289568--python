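"""Tier-1 screening of sediment concentrations against guideline triggers.

The first tier of a tiered risk assessment simply compares measured
concentrations with low/high sediment-quality trigger values: any station
above a low trigger flags the element for the detailed probabilistic tiers.
A distributional guard supplements the raw counts — an element whose fitted
99th percentile sits below its low trigger is "not of concern" even before
looking at species sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .data import ExposureTable, GuidelineSet
from .distributions import FittedDistribution

__all__ = [
    "ElementScreen",
    "ScreeningResult",
    "screen",
    "exceedance_probability",
    "percentile_guard",
]


@dataclass(frozen=True)
class ElementScreen:
    element: str
    n_stations: int
    low_trigger: float | None
    high_trigger: float | None
    exceed_low: tuple = ()      # sorted station ids above the low trigger
    exceed_high: tuple = ()
    screened: bool = True       # False when no guideline exists for the element

    @property
    def n_exceed_low(self) -> int:
        return len(self.exceed_low)

    @property
    def n_exceed_high(self) -> int:
        return len(self.exceed_high)

    @property
    def flagged(self) -> bool:
        return self.n_exceed_low > 0


@dataclass(frozen=True)
class ScreeningResult:
    """Per-element tier-1 outcome; iterate or index by element symbol."""

    by_element: dict[str, ElementScreen]
    unit: str

    def __getitem__(self, element: str) -> ElementScreen:
        return self.by_element[element]

    def flagged_elements(self) -> list[str]:
        return [e for e, s in self.by_element.items() if s.screened and s.flagged]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for el, s in self.by_element.items():
            rows.append(
                {
                    "element": el,
                    "screened": s.screened,
                    "low_trigger": s.low_trigger,
                    "high_trigger": s.high_trigger,
                    "n_exceed_low": s.n_exceed_low,
                    "n_exceed_high": s.n_exceed_high,
                    "stations_exceed_low": ";".join(map(str, s.exceed_low)),
                    "flagged": s.flagged,
                }
            )
        return pd.DataFrame(rows).set_index("element")


def screen(table: ExposureTable, guidelines: GuidelineSet) -> ScreeningResult:
    """Count stations strictly above each trigger, per element.

    Exceedance is strict (value > trigger): a concentration exactly equal to
    a guideline does not alarm.  Guidelines are converted to the exposure
    table's unit before comparison.  Elements absent from the guideline set
    are marked unscreened rather than erroring.
    """
    gl = guidelines.to_unit(table.unit)
    out: dict[str, ElementScreen] = {}
    for el in table.elements:
        n = len(table.stations)
        if el not in gl.elements:
            out[el] = ElementScreen(el, n, None, None, screened=False)
            continue
        low, high = gl.low(el), gl.high(el)
        col = table.mean[el]
        ex_low = tuple(sorted(col.index[col > low], key=_station_key))
        ex_high = tuple(sorted(col.index[col > high], key=_station_key))
        out[el] = ElementScreen(el, n, low, high, ex_low, ex_high)
    return ScreeningResult(by_element=out, unit=table.unit)


def _station_key(s):
    try:
        return (0, int(s))
    except (TypeError, ValueError):
        return (1, str(s))


def exceedance_probability(fit: FittedDistribution, threshold: float) -> float:
    """P(X > threshold) under the fitted distribution, 1 - F(threshold)."""
    if not (threshold > 0):
        raise ValueError("threshold must be > 0")
    return float(fit.sf(threshold))


def percentile_guard(
    fit: FittedDistribution, q: float, trigger: float
) -> tuple[bool, float]:
    """Does the fitted q-quantile sit below the trigger?

    Returns ``(passes, percentile_value)``; ``passes`` is True when the
    fitted quantile is strictly below the trigger, the "not of concern"
    verdict of the distributional tier-1 guard (q = 0.99 by convention).
    """
    if not (0 < q < 1):
        raise ValueError("q must lie strictly inside (0, 1)")
    value = float(fit.quantile(q))
    return value < trigger, value
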