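"""Log-normal and Burr Type III distributions, MLE fitting, and KS diagnostics.

These two families are the workhorses of probabilistic sediment risk
assessment.  The same machinery serves both sides of the analysis:

* fitted to measured concentrations it is the exposure distribution
  (probability density distribution, PDD);
* fitted to per-species toxicity endpoints it is the species sensitivity
  distribution (SSD), whose lower quantiles are hazardous concentrations.

The Burr Type III CDF is ``F(x) = (1 + (b/x)^c)^(-k)`` on x > 0 with scale
``b`` and shapes ``c, k`` (all strictly positive); at ``k = 1`` it reduces
to the log-logistic.  Its extra shape parameter lets it track the heavy
lower tails that matter for SSD work better than the log-normal, at the
price of a likelihood surface that is nearly flat along ridges in (c, k) —
hence the multi-start optimiser below.

Goodness of fit uses the Kolmogorov–Smirnov statistic with a parametric
bootstrap p-value: because the parameters are estimated from the same
sample, the classical KS table would be anti-conservative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, NamedTuple

import numpy as np
from scipy import optimize, stats

from .units import CANONICAL_UNIT

__all__ = [
    "LogNormalParams",
    "BurrIIIParams",
    "FittedDistribution",
    "PDDFit",
    "DegenerateDataError",
    "FitError",
    "lognormal_mle",
    "burr3_mle",
    "burr3_cdf",
    "burr3_quantile",
    "burr3_logpdf",
    "ks_statistic",
    "ks_test",
    "fit_pdd",
]

Family = Literal["lognormal", "burr3"]


class DegenerateDataError(ValueError):
    """All samples identical (or otherwise unfittable) — no spread to model."""


class FitError(RuntimeError):
    """Optimiser failed to converge; ``best`` carries the best parameters found."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class LogNormalParams:
    """log-concentration location ``mu`` and scale ``sigma`` (natural log)."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    @property
    def median(self) -> float:
        return math.exp(self.mu)


@dataclass(frozen=True)
class BurrIIIParams:
    """Burr III scale ``b`` (concentration units) and shapes ``c``, ``k``."""

    b: float
    c: float
    k: float

    def __post_init__(self) -> None:
        for name in ("b", "c", "k"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def median(self) -> float:
        return burr3_quantile(self, 0.5)


# ---------------------------------------------------------------------------
# Burr III closed forms, computed in log space for extreme arguments
# ---------------------------------------------------------------------------

def _check_positive_x(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentrations must be strictly positive")
    return x


def burr3_cdf(params: BurrIIIParams, x):
    """``(1 + (b/x)^c)^(-k)``, stable for x far into either tail."""
    x = _check_positive_x(x)
    t = params.c * (math.log(params.b) - np.log(x))
    out = np.exp(-params.k * np.logaddexp(0.0, t))
    return out if out.ndim else float(out)


def burr3_quantile(params: BurrIIIParams, p):
    """Exact inverse of :func:`burr3_cdf`: ``b / (p^(-1/k) - 1)^(1/c)``."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probability must lie strictly inside (0, 1)")
    # log-space throughout: t = -log(p)/k, log(p^(-1/k) - 1) = t + log1p(-e^-t)
    # (log(expm1(t)) for small t), so extreme shape parameters cannot overflow
    t = -np.log(p) / params.k
    log_em1 = np.where(t > 0.693, t + np.log1p(-np.exp(-np.minimum(t, 745.0))),
                       np.log(np.expm1(np.minimum(t, 0.694))))
    out = np.exp(math.log(params.b) - log_em1 / params.c)
    # deep-tail results can still underflow float range; keep them positive
    out = np.maximum(out, np.finfo(float).tiny)
    return out if out.ndim else float(out)


def burr3_logpdf(params: BurrIIIParams, x):
    x = _check_positive_x(x)
    t = params.c * (math.log(params.b) - np.log(x))
    out = (
        math.log(params.k)
        + math.log(params.c)
        + t
        - np.log(x)
        - (params.k + 1.0) * np.logaddexp(0.0, t)
    )
    return out if out.ndim else float(out)


def _lognormal_logpdf(params: LogNormalParams, x):
    x = _check_positive_x(x)
    return stats.norm.logpdf(np.log(x), params.mu, params.sigma) - np.log(x)


# ---------------------------------------------------------------------------
# Fitted-distribution container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FittedDistribution:
    """A fitted log-normal or Burr III with its fit diagnostics.

    Depending on what was fitted this object is the exposure distribution
    (``kind='pdd'``) or the species sensitivity distribution
    (``kind='ssd'``).  ``ks_p`` is None until :func:`ks_test` fills it in.
    """

    family: Family
    params: LogNormalParams | BurrIIIParams
    n: int
    loglik: float
    ks_d: float | None = None
    ks_p: float | None = None
    converged: bool = True
    unit: str = CANONICAL_UNIT
    kind: str = "pdd"

    def cdf(self, x):
        if self.family == "lognormal":
            x = _check_positive_x(x)
            out = stats.norm.cdf(np.log(x), self.params.mu, self.params.sigma)
            return out if np.ndim(out) else float(out)
        return burr3_cdf(self.params, x)

    def sf(self, x):
        """Exceedance probability 1 - F(x)."""
        if self.family == "lognormal":
            x = _check_positive_x(x)
            out = stats.norm.sf(np.log(x), self.params.mu, self.params.sigma)
            return out if np.ndim(out) else float(out)
        t = self.params.c * (math.log(self.params.b) - np.log(_check_positive_x(x)))
        out = -np.expm1(-self.params.k * np.logaddexp(0.0, t))
        return out if np.ndim(out) else float(out)

    def quantile(self, p):
        if self.family == "lognormal":
            p = np.asarray(p, dtype=float)
            if np.any((p <= 0) | (p >= 1)):
                raise ValueError("probability must lie strictly inside (0, 1)")
            out = np.exp(stats.norm.ppf(p, self.params.mu, self.params.sigma))
            return out if out.ndim else float(out)
        return burr3_quantile(self.params, p)

    def logpdf(self, x):
        if self.family == "lognormal":
            return _lognormal_logpdf(self.params, x)
        return burr3_logpdf(self.params, x)

    def pdf(self, x):
        return np.exp(self.logpdf(x))

    @property
    def median(self) -> float:
        return self.params.median

    def scaled(self, s: float) -> "FittedDistribution":
        """The distribution of ``s * X`` — a log-location shift.

        Used by remediation: reducing every concentration by the same factor
        moves the exposure distribution without changing its shape.
        """
        if not (s > 0):
            raise ValueError("scale factor must be > 0")
        if self.family == "lognormal":
            p = LogNormalParams(self.params.mu + math.log(s), self.params.sigma)
        else:
            p = BurrIIIParams(self.params.b * s, self.params.c, self.params.k)
        return replace(self, params=p, loglik=float("nan"), ks_d=None, ks_p=None)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.quantile(rng.uniform(size=n))


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _check_samples(samples, min_n: int) -> np.ndarray:
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} samples, got {x.size}")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("all samples must be finite and strictly positive")
    if np.ptp(x) == 0:
        raise DegenerateDataError("all samples are identical; nothing to fit")
    return x


def lognormal_mle(samples, unit: str = CANONICAL_UNIT, kind: str = "pdd") -> FittedDistribution:
    """Closed-form log-normal MLE: mu = mean(log x), sigma = MLE SD (divisor n)."""
    x = _check_samples(samples, 3)
    logs = np.log(x)
    mu = float(np.mean(logs))
    sigma = float(np.std(logs))  # ddof=0: the MLE
    params = LogNormalParams(mu, sigma)
    ll = float(np.sum(_lognormal_logpdf(params, x)))
    return FittedDistribution("lognormal", params, x.size, ll, unit=unit, kind=kind)


def _burr3_negloglik(theta: np.ndarray, logx: np.ndarray) -> float:
    # theta = (log b, log c, log k) on data pre-scaled to geometric mean 1
    logb, logc, logk = theta
    c, k = math.exp(logc), math.exp(logk)
    t = c * (logb - logx)
    ll = logk + logc + t - logx - (k + 1.0) * np.logaddexp(0.0, t)
    return -float(np.sum(ll))

_LOG_BOUND = math.log(1e3)
_BOUNDS = [(-_LOG_BOUND, _LOG_BOUND)] * 3


def burr3_mle(
    samples,
    unit: str = CANONICAL_UNIT,
    kind: str = "pdd",
    x0: BurrIIIParams | None = None,
    multistart: bool = True,
) -> FittedDistribution:
    """Burr III MLE with log-parameter optimisation and multi-start.

    Data are rescaled to geometric mean 1 so the scale parameter sits near
    1 regardless of units.  Initialisation comes from a log-logistic fit
    (the k = 1 sub-family, which has a well-behaved likelihood), expanded
    into a 3x3 grid of (c, k) scalings {1/2, 1, 2} because the full
    likelihood is ridge-shaped in (c, k).  The achieved log-likelihood is
    never below the log-logistic initialiser's.

    ``x0`` (with ``multistart=False``) gives the single-start fast path used
    for bootstrap refits, seeded at the parent fit's parameters.
    """
    x = _check_samples(samples, 4)
    g = float(np.exp(np.mean(np.log(x))))  # geometric mean
    logx = np.log(x / g)

    starts: list[np.ndarray] = []
    if x0 is not None:
        starts.append(np.log([x0.b / g, x0.c, x0.k]))
    if x0 is None or multistart:
        c0, _, b0 = stats.fisk.fit(x / g, floc=0)
        c0 = min(max(c0, 1e-2), 1e2)
        b0 = min(max(b0, 1e-2), 1e2)
        base = np.log([b0, c0, 1.0])
        if multistart:
            for fc in (0.5, 1.0, 2.0):
                for fk in (0.5, 1.0, 2.0):
                    starts.append(base + np.log([1.0, fc, fk]))
        else:
            starts.append(base)

    best = None
    for s in starts:
        res = optimize.minimize(
            _burr3_negloglik, s, args=(logx,), method="L-BFGS-B", bounds=_BOUNDS
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    # never end below the log-logistic initialiser
    init_nll = min(_burr3_negloglik(s, logx) for s in starts)
    converged = bool(best.success) and best.fun <= init_nll + 1e-6
    logb, logc, logk = best.x
    params = BurrIIIParams(math.exp(logb) * g, math.exp(logc), math.exp(logk))
    ll = float(np.sum(burr3_logpdf(params, x)))
    fit = FittedDistribution("burr3", params, x.size, ll, converged=converged,
                             unit=unit, kind=kind)
    if not converged:
        raise FitError("Burr III fit did not converge from any start", best=fit)
    return fit


def _fit_family(family: Family, x, unit: str, kind: str,
                x0=None) -> FittedDistribution:
    if family == "lognormal":
        return lognormal_mle(x, unit=unit, kind=kind)
    if family == "burr3":
        if x0 is not None:
            return burr3_mle(x, unit=unit, kind=kind, x0=x0, multistart=False)
        return burr3_mle(x, unit=unit, kind=kind)
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# Kolmogorov–Smirnov goodness of fit
# ---------------------------------------------------------------------------

def ks_statistic(fit: FittedDistribution, samples) -> float:
    """sup-distance between the empirical and fitted CDFs.

    Evaluates both one-sided gaps at every order statistic: with sorted
    samples x_(1..n), D = max_i max(i/n - F(x_i), F(x_i) - (i-1)/n).
    Ties are allowed.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    f = np.atleast_1d(fit.cdf(x))
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - f)
    d_minus = np.max(f - (i - 1) / n)
    return float(max(d_plus, d_minus, 0.0))


def ks_test(
    fit: FittedDistribution,
    samples,
    n_boot: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """KS statistic and parametric-bootstrap p-value.

    Each bootstrap replicate draws n points from the fitted distribution,
    refits the same family (single-start, seeded at the parent parameters
    for Burr III), and recomputes D; p is the fraction of replicate D values
    at or above the observed one, with the usual +1 correction.  This
    accounts for the parameters having been estimated from the sample —
    the classical KS table would reject far too rarely in that setting.
    """
    if n_boot < 99:
        raise ValueError("n_boot must be >= 99 for usable p resolution")
    x = np.asarray(samples, dtype=float)
    d_obs = ks_statistic(fit, x)
    rng = np.random.default_rng(seed)
    n = x.size
    exceed = 0
    for _ in range(n_boot):
        xb = fit.sample(n, rng)
        try:
            refit = _fit_family(fit.family, xb, fit.unit, fit.kind,
                                x0=fit.params if fit.family == "burr3" else None)
        except (DegenerateDataError, FitError, ValueError):
            # a failed synthetic refit counts as extreme (conservative)
            exceed += 1
            continue
        if ks_statistic(refit, xb) >= d_obs:
            exceed += 1
    p = (1 + exceed) / (n_boot + 1)
    return d_obs, float(p)


# ---------------------------------------------------------------------------
# Dual-family exposure fit
# ---------------------------------------------------------------------------

class PDDFit(NamedTuple):
    lognormal: FittedDistribution
    burr3: FittedDistribution
    selected: Family


def fit_pdd(
    samples,
    unit: str = CANONICAL_UNIT,
    kind: str = "pdd",
    n_boot: int = 0,
    seed: int | None = None,
) -> PDDFit:
    """Fit both families to one sample and select by smaller KS D.

    Both fits are always returned (risk reports show the two curves side by
    side); ties in D select the log-normal.  ``n_boot > 0`` additionally
    attaches parametric-bootstrap p-values to both fits.
    """
    ln = lognormal_mle(samples, unit=unit, kind=kind)
    b3 = burr3_mle(samples, unit=unit, kind=kind)
    d_ln = ks_statistic(ln, samples)
    d_b3 = ks_statistic(b3, samples)
    p_ln = p_b3 = None
    if n_boot:
        _, p_ln = ks_test(ln, samples, n_boot=n_boot, seed=seed)
        _, p_b3 = ks_test(b3, samples, n_boot=n_boot,
                          seed=None if seed is None else seed + 1)
    ln = replace(ln, ks_d=d_ln, ks_p=p_ln)
    b3 = replace(b3, ks_d=d_b3, ks_p=p_b3)
    selected: Family = "lognormal" if d_ln <= d_b3 else "burr3"
    return PDDFit(lognormal=ln, burr3=b3, selected=selected)
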