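"""Exposure x effects convolution and remediation targets.

The detailed tier of the assessment overlays the exposure distribution
(PDD, fitted to measured concentrations) on the species sensitivity
distribution (SSD, fitted to toxicity endpoints).  The expected fraction of
species affected is the convolution

    E[F_SSD(X)],  X ~ PDD,

i.e. the average, over the exposure distribution, of the fraction of
species whose endpoint lies below the ambient concentration.  When the two
distributions coincide this is exactly 1/2.

Remediation asks the inverse question: by what factor s must all
concentrations shrink (a log-location shift that preserves the fitted
shape) so that the convolved percentage of species affected drops to an
acceptable level n at confidence p?  The required reduction is 100(1-s)%
and the median target concentration is s times the current median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .data import ToxicityDataset
from .distributions import (
    DegenerateDataError,
    Family,
    FitError,
    FittedDistribution,
    _fit_family,
    fit_pdd,
)
from .hazard import DEFAULT_FAMILY, fit_ssd

__all__ = [
    "RiskResult",
    "RemediationResult",
    "fraction_affected",
    "species_affected",
    "required_reduction_to_target",
    "required_reduction_for_risk",
]

#: Fixed Gauss–Legendre rule used for bootstrap-replicate convolutions,
#: where bootstrap noise dwarfs quadrature error; the primary estimate
#: always goes through adaptive quadrature at 1e-6.
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(256)
_GL_P = 0.5 * (_GL_NODES + 1.0)          # map [-1,1] -> (0,1)
_GL_W = 0.5 * _GL_WEIGHTS

#: Smallest remediation scale factor attempted before declaring the
#: criterion unattainable.
_S_MIN = 1e-12


@dataclass(frozen=True)
class RiskResult:
    """Percentage of species affected by the current exposure."""

    element: str
    percent_affected: float          # reported at the stated confidence
    point_percent: float             # MLE convolution, no bootstrap
    confidence_percent: float
    method: str                      # "quadrature" | "quadrature+bootstrap"
    n_boot: int
    n_failed: int
    seed: int | None

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_affected <= 100.0):
            raise ValueError("percent_affected must lie in [0, 100]")


@dataclass(frozen=True)
class RemediationResult:
    """Required reduction of the exposure median to meet a protection level."""

    element: str
    protection_n_percent: float      # max tolerated % species affected
    confidence_percent: float
    required_reduction_percent: float
    median_target: float             # canonical units
    current_median: float
    percent_affected: float          # at current exposure, same confidence
    mode: str                        # "risk" | "target"
    unit: str
    n_boot: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.required_reduction_percent < 100.0 + 1e-9):
            raise ValueError("reduction must lie in [0, 100)")

    @property
    def nil(self) -> bool:
        return self.required_reduction_percent == 0.0


def fraction_affected(pdd: FittedDistribution, ssd: FittedDistribution) -> float:
    """E[F_SSD(X)] for X ~ PDD, by adaptive quadrature (abs tol 1e-6).

    Integrates in probability space, F_SSD(Q_PDD(p)) over p in (0,1), which
    is bounded and smooth and equivalent to quadrature over
    log-concentration via the change of variables p = F_PDD(x).
    """
    if pdd.unit != ssd.unit:
        raise ValueError(f"unit mismatch: PDD in {pdd.unit!r}, SSD in {ssd.unit!r}")
    val, _ = integrate.quad(
        lambda p: ssd.cdf(pdd.quantile(p)), 0.0, 1.0, epsabs=1e-6, limit=200
    )
    return float(min(max(val, 0.0), 1.0))


def _fraction_affected_gl(q_pdd: np.ndarray, ssd: FittedDistribution) -> float:
    """Fixed-rule convolution given precomputed PDD quantiles at the GL nodes."""
    return float(np.dot(_GL_W, ssd.cdf(q_pdd)))


def _fit_pair(
    exposure: np.ndarray,
    tox: ToxicityDataset,
    pdd_family: str,
    ssd_family: Family,
    x0_pdd=None,
    x0_ssd=None,
) -> tuple[FittedDistribution, FittedDistribution]:
    if pdd_family == "auto":
        pdd = fit_pdd(exposure, unit=tox.unit)
        pdd_fit = getattr(pdd, pdd.selected)
    else:
        pdd_fit = _fit_family(pdd_family, exposure, tox.unit, "pdd", x0=x0_pdd)
    ssd_fit = _fit_family(ssd_family, tox.concentrations, tox.unit, "ssd", x0=x0_ssd)
    return pdd_fit, ssd_fit


def _bootstrap_pairs(
    exposure: np.ndarray,
    tox: ToxicityDataset,
    parent_pdd: FittedDistribution,
    parent_ssd: FittedDistribution,
    n_boot: int,
    seed: int | None,
) -> tuple[list[tuple[FittedDistribution, FittedDistribution]], int]:
    """Paired bootstrap: resample stations and species, refit both sides."""
    from .data import ToxicityDataset as TD

    rng = np.random.default_rng(seed)
    pairs = []
    failed = 0
    x = np.asarray(exposure, dtype=float)
    t = tox.concentrations
    for _ in range(n_boot):
        xb = x[rng.integers(0, x.size, x.size)]
        tb = t[rng.integers(0, t.size, t.size)]
        try:
            pdd_b = _fit_family(
                parent_pdd.family, xb, parent_pdd.unit, "pdd",
                x0=parent_pdd.params if parent_pdd.family == "burr3" else None,
            )
            ssd_b = _fit_family(
                parent_ssd.family, tb, parent_ssd.unit, "ssd",
                x0=parent_ssd.params if parent_ssd.family == "burr3" else None,
            )
        except (DegenerateDataError, FitError, ValueError):
            failed += 1
            continue
        pairs.append((pdd_b, ssd_b))
    if failed > 0.2 * n_boot:
        raise FitError(
            f"{failed}/{n_boot} paired bootstrap refits failed; "
            "data too unstable for confidence-adjusted risk"
        )
    return pairs, failed


def species_affected(
    exposure,
    tox: ToxicityDataset,
    confidence_percent: float = 50,
    n_boot: int = 500,
    seed: int | None = None,
    pdd_family: str = "auto",
    ssd_family: Family = DEFAULT_FAMILY,
) -> RiskResult:
    """Percentage of species affected by the current exposure.

    At confidence 50 the MLE convolution is reported directly.  Above 50,
    the reported value is the ``confidence_percent``-th percentile of
    paired-bootstrap replicate convolutions (resample stations and species
    independently, refit both distributions, convolve) — an upper,
    protective reading of the estimation uncertainty.
    """
    if not (50 <= confidence_percent <= 99.9):
        raise ValueError("confidence_percent must lie in [50, 99.9]")
    x = np.asarray(exposure, dtype=float)
    parent_pdd, parent_ssd = _fit_pair(x, tox, pdd_family, ssd_family)
    point = 100.0 * fraction_affected(parent_pdd, parent_ssd)
    if confidence_percent == 50:
        return RiskResult(tox.element, point, point, 50.0, "quadrature", 0, 0, seed)
    pairs, failed = _bootstrap_pairs(x, tox, parent_pdd, parent_ssd, n_boot, seed)
    reps = [100.0 * _fraction_affected_gl(p.quantile(_GL_P), s) for p, s in pairs]
    value = float(np.percentile(reps, confidence_percent))
    return RiskResult(
        tox.element, value, point, confidence_percent,
        "quadrature+bootstrap", n_boot, failed, seed,
    )


def required_reduction_to_target(current_median: float, target: float) -> float:
    """Percent reduction of the median needed to reach a target concentration.

    ``100 * max(0, 1 - target/current_median)``; both arguments must be
    positive and in the same units.  Zero (the target already met) renders
    as "NIL" in reports.
    """
    if not (current_median > 0 and target > 0):
        raise ValueError("current_median and target must be > 0")
    return 100.0 * max(0.0, 1.0 - target / current_median)


def required_reduction_for_risk(
    exposure,
    tox: ToxicityDataset,
    max_affected_percent: float,
    confidence_percent: float = 95,
    n_boot: int = 500,
    seed: int | None = None,
    pdd_family: str = "auto",
    ssd_family: Family = DEFAULT_FAMILY,
    s_tol: float = 1e-4,
) -> RemediationResult:
    """Scale the exposure down until the convolved risk meets the criterion.

    Finds the largest multiplicative scale s in (0, 1] such that the
    percentage of species affected by the scaled exposure, at the stated
    confidence, does not exceed ``max_affected_percent``; bisection to
    ``s_tol`` on s, returning the compliant endpoint so the criterion is
    satisfied at the reported scale.  Already-compliant exposures return
    reduction 0 with the current median as target.
    """
    if not (0 < max_affected_percent < 100):
        raise ValueError("max_affected_percent must lie strictly inside (0, 100)")
    x = np.asarray(exposure, dtype=float)
    parent_pdd, parent_ssd = _fit_pair(x, tox, pdd_family, ssd_family)
    current_median = float(np.median(x))

    if confidence_percent == 50:
        pairs, failed, nb = [], 0, 0
    else:
        pairs, failed = _bootstrap_pairs(x, tox, parent_pdd, parent_ssd, n_boot, seed)
        nb = n_boot
    # PDD quantiles at the quadrature nodes scale linearly with s, so they
    # are precomputed once per replicate and the bisection only re-evaluates
    # the SSD side.
    q_parent = np.asarray(parent_pdd.quantile(_GL_P), dtype=float)
    q_reps = [np.asarray(p.quantile(_GL_P), dtype=float) for p, _ in pairs]

    def risk_at(s: float) -> float:
        if confidence_percent == 50:
            return 100.0 * fraction_affected(parent_pdd.scaled(s), parent_ssd)
        reps = [
            100.0 * _fraction_affected_gl(s * q, ssd_b)
            for q, (_, ssd_b) in zip(q_reps, pairs)
        ]
        return float(np.percentile(reps, confidence_percent))

    current_risk = risk_at(1.0)

    def result(s: float) -> RemediationResult:
        reduction = 100.0 * (1.0 - s)
        return RemediationResult(
            element=tox.element,
            protection_n_percent=max_affected_percent,
            confidence_percent=confidence_percent,
            required_reduction_percent=reduction,
            median_target=s * current_median,
            current_median=current_median,
            percent_affected=current_risk,
            mode="risk",
            unit=tox.unit,
            n_boot=nb,
            seed=seed,
        )

    if current_risk <= max_affected_percent:
        return result(1.0)

    lo = 0.5
    while risk_at(lo) > max_affected_percent:
        lo *= 0.5
        if lo < _S_MIN:
            raise FitError(
                f"criterion {max_affected_percent}% unattainable even at "
                f"scale {_S_MIN}; SSD lower tail too heavy"
            )
    hi = min(2.0 * lo, 1.0)  # risk_at(hi) > criterion, risk_at(lo) <= criterion
    while hi - lo > s_tol:
        mid = 0.5 * (lo + hi)
        if risk_at(mid) <= max_affected_percent:
            lo = mid
        else:
            hi = mid
    return result(lo)
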