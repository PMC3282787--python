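"""Discrete power-law fitting for degree distributions.

The model is P(X = x) = x^(-alpha) / zeta(alpha, xmin) for integers
x >= xmin, with the Hurwitz zeta as normaliser.  Fitting follows the
standard tail-estimation recipe: for every candidate xmin among the observed
values, alpha is the discrete maximum-likelihood estimate and the candidate
minimising the Kolmogorov-Smirnov distance between the empirical and model
tail CDFs is chosen.  Goodness of fit is a semiparametric bootstrap: each
synthetic sample draws from the fitted tail model with probability ntail/n
and uniformly from the observed sub-xmin values otherwise, is refitted, and
the p-value is the fraction of synthetic KS distances at least as large as
the observed one.  p < 0.1 rejects the power law; p >= 0.1 means the power
law is a plausible fit (which does not exclude a better-fitting alternative).

Degrees are integers, so the discrete formulation is the default; a
continuous-approximation alpha is available for cross-checking against
continuous fitters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import zeta as hzeta

from .errors import DegenerateSampleError, IrefkitError, PowerLawFitError

ALPHA_BOUNDS = (1.01, 25.0)
REJECTION_LEVEL = 0.1


@dataclass(frozen=True)
class PowerLawFit:
    """Result of a discrete power-law fit (plus optional bootstrap assessment)."""

    alpha: float
    xmin: int
    ntail: int
    ks_D: float
    p_value: float | None = None
    n_bootstrap: int = 0
    seed: int | None = None

    @property
    def verdict(self) -> str | None:
        """"plausible" (p >= 0.1), "rejected" (p < 0.1) or None before bootstrap."""
        if self.p_value is None:
            return None
        return "rejected" if self.p_value < REJECTION_LEVEL else "plausible"


def _validate_values(values) -> np.ndarray:
    x = np.asarray(values)
    if x.size == 0:
        raise IrefkitError("empty sample")
    if not np.issubdtype(x.dtype, np.integer):
        xi = x.astype(np.int64)
        if not np.all(xi == x):
            raise IrefkitError("degree values must be positive integers")
        x = xi
    if np.any(x < 1):
        raise IrefkitError("degree values must be positive integers")
    return np.sort(x.astype(np.int64))


def _golden_max(f, lo: float, hi: float, tol: float = 1e-5) -> float:
    """Golden-section maximiser of a unimodal f on [lo, hi]; deterministic."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def _mle_alpha(tail_log_sum: float, ntail: int, xmin: int) -> float:
    def loglik(alpha: float) -> float:
        return -ntail * np.log(hzeta(alpha, xmin)) - alpha * tail_log_sum
    return _golden_max(loglik, *ALPHA_BOUNDS)


def _ks_distance(alpha: float, xmin: int, tail: np.ndarray) -> float:
    """Max |empirical - model| tail CDF over the observed tail values."""
    upts, counts = np.unique(tail, return_counts=True)
    ecdf = np.cumsum(counts) / tail.size
    z = hzeta(alpha, xmin)
    mcdf = 1.0 - hzeta(alpha, upts + 1) / z
    return float(np.max(np.abs(ecdf - mcdf)))


def fit_discrete_powerlaw(values, min_tail: int = 10) -> PowerLawFit:
    """Fit alpha and xmin to an integer sample by KS-minimisation over xmin.

    Candidates are the distinct observed values whose tail holds at least
    ``min_tail`` points and at least two distinct values; ties in KS distance
    go to the smaller xmin (larger tail).  Raises
    :class:`DegenerateSampleError` when the sample has a single distinct
    value and :class:`PowerLawFitError` when no candidate is admissible.
    """
    x = _validate_values(values)
    uniq = np.unique(x)
    if uniq.size < 2:
        raise DegenerateSampleError("sample has no variation; cannot fit a tail")
    # suffix sums of log(x) over the sorted sample, for O(1) tail log-sums
    logs = np.log(x.astype(float))
    suffix = np.concatenate([np.cumsum(logs[::-1])[::-1], [0.0]])
    best: PowerLawFit | None = None
    for j, xmin in enumerate(uniq[:-1]):  # last unique value leaves a 1-point tail
        start = np.searchsorted(x, xmin, side="left")
        ntail = x.size - start
        if ntail < min_tail or uniq.size - j < 2:
            continue
        alpha = _mle_alpha(suffix[start], ntail, int(xmin))
        D = _ks_distance(alpha, int(xmin), x[start:])
        if best is None or D < best.ks_D:
            best = PowerLawFit(alpha=float(alpha), xmin=int(xmin),
                               ntail=int(ntail), ks_D=D)
    if best is None:
        raise PowerLawFitError(
            f"no xmin candidate with a tail of at least {min_tail} points")
    return best


def continuous_alpha(values, xmin: int) -> float:
    """Continuous-approximation MLE alpha = 1 + n / sum(ln(x/(xmin-1/2))).

    Offered for cross-checking against continuous power-law fitters; the
    discrete fit is authoritative for integer degrees.
    """
    x = _validate_values(values)
    tail = x[x >= xmin].astype(float)
    if tail.size == 0:
        raise IrefkitError("empty tail")
    return float(1.0 + tail.size / np.sum(np.log(tail / (xmin - 0.5))))


def sample_discrete_powerlaw(alpha: float, xmin: int, n: int,
                             seed=None, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw n i.i.d. values from the discrete power law (inverse-CDF, exact)."""
    if alpha <= 1.0:
        raise IrefkitError("alpha must exceed 1 for a normalisable tail")
    if xmin < 1 or n < 1:
        raise IrefkitError("xmin and n must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    u = rng.random(n)
    z = hzeta(alpha, xmin)
    # CDF table leaving ~1/(10n) overflow mass, ccdf(x) ~ (x/xmin)^(1-alpha);
    # the rare draw beyond it falls back to exact integer bisection
    hi = int(np.ceil(xmin * (10.0 * n) ** (1.0 / (alpha - 1.0))))
    hi = min(max(hi, xmin + 1), xmin + 2_000_000)
    xs = np.arange(xmin, hi + 1, dtype=np.int64)
    cdf = 1.0 - hzeta(alpha, xs + 1) / z
    idx = np.searchsorted(cdf, u, side="left")
    out = xmin + idx
    overflow = idx >= xs.size
    for k in np.nonzero(overflow)[0]:  # beyond the table: integer bisection
        lo_b, hi_b = int(xs[-1]), int(xs[-1]) * 2
        while 1.0 - hzeta(alpha, hi_b + 1) / z < u[k]:
            lo_b, hi_b = hi_b, hi_b * 2
        while lo_b < hi_b:
            mid = (lo_b + hi_b) // 2
            if 1.0 - hzeta(alpha, mid + 1) / z >= u[k]:
                hi_b = mid
            else:
                lo_b = mid + 1
        out[k] = lo_b
    return out.astype(np.int64)


def bootstrap_pvalue(values, fit: PowerLawFit, B: int = 1000, seed: int = 0,
                     min_tail: int = 10) -> float:
    """Semiparametric bootstrap goodness-of-fit p-value for a fitted power law."""
    if B < 1:
        raise IrefkitError("B must be at least 1")
    x = _validate_values(values)
    n = x.size
    body = x[x < fit.xmin]
    p_tail = fit.ntail / n
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(B):
        from_tail = rng.random(n) < p_tail
        k = int(from_tail.sum())
        parts = []
        if k:
            parts.append(sample_discrete_powerlaw(fit.alpha, fit.xmin, k, rng=rng))
        if n - k:
            parts.append(rng.choice(body, size=n - k, replace=True))
        synth = np.concatenate(parts)
        try:
            refit = fit_discrete_powerlaw(synth, min_tail=min_tail)
        except (DegenerateSampleError, PowerLawFitError):
            continue  # a synthetic sample too degenerate to fit cannot exceed D
        if refit.ks_D >= fit.ks_D:
            exceed += 1
    return exceed / B


def assess_powerlaw(values, B: int = 1000, seed: int = 0,
                    min_tail: int = 10) -> PowerLawFit:
    """Fit, bootstrap and return a complete :class:`PowerLawFit` with verdict."""
    fit = fit_discrete_powerlaw(values, min_tail=min_tail)
    p = bootstrap_pvalue(values, fit, B=B, seed=seed, min_tail=min_tail)
    return replace(fit, p_value=p, n_bootstrap=B, seed=seed)


def cumulative_degree_distribution(values) -> list[tuple[int, float]]:
    """(k, fraction of values >= k) for each distinct k, non-increasing in k."""
    x = _validate_values(values)
    uniq, counts = np.unique(x, return_counts=True)
    ge = np.cumsum(counts[::-1])[::-1] / x.size
    return [(int(k), float(f)) for k, f in zip(uniq, ge)]


__all__ = [
    "PowerLawFit", "ALPHA_BOUNDS", "REJECTION_LEVEL",
    "fit_discrete_powerlaw", "continuous_alpha", "sample_discrete_powerlaw",
    "bootstrap_pvalue", "assess_powerlaw", "cumulative_degree_distribution",
]
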