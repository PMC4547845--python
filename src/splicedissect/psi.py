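"""Bayesian two-isoform PSI estimation and Bayes-factor divergence testing.

PSI ("percent spliced in") is the fraction of a gene's transcripts that
include the alternative segment of a splicing event.  Reads informative for
an event support either the inclusion or the exclusion isoform; with
per-event informativeness constants ``c_inc``/``c_exc`` (effective numbers
of distinguishing read positions per isoform) the probability that an
informative read supports inclusion is

    q(psi) = psi * c_inc / (psi * c_inc + (1 - psi) * c_exc)

Under a Uniform(0, 1) prior on PSI and a Binomial(n, q(psi)) likelihood the
posterior is Beta(n_inc + 1, n_exc + 1) whenever ``c_inc == c_exc``;
otherwise it is evaluated on a fixed grid.  The Bayes factor for a splicing
difference between two count records compares the marginal likelihood under
two independent PSI values against a single shared PSI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate, stats
from scipy.special import betaln, xlogy

__all__ = [
    "PsiEstimate",
    "inclusion_probability",
    "psi_posterior",
    "log_bayes_factor",
    "bayes_factor",
    "log_marginal_quadrature",
    "log_bayes_factor_quadrature",
    "delta_psi",
    "fisher_divergence_test",
    "isoform_ratio_psi",
]

#: number of grid points used for the quadrature fallback
GRID_POINTS = 2001


@lru_cache(maxsize=8)
def _leggauss_cached(n_points: int):
    return np.polynomial.legendre.leggauss(n_points)


@dataclass(frozen=True)
class PsiEstimate:
    """Posterior summary of PSI for one (or one pooled) count record."""

    psi_mean: float
    psi_variance: float
    ci_low: float
    ci_high: float
    n_total: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.psi_mean <= self.ci_high <= 1.0):
            raise ValueError(
                f"inconsistent PSI estimate: mean={self.psi_mean}, "
                f"ci=[{self.ci_low}, {self.ci_high}]"
            )


def inclusion_probability(psi, c_inc: float = 1.0, c_exc: float = 1.0):
    """Informativeness-corrected probability that a read supports inclusion.

    With equal constants this is the identity; psi = 0 and psi = 1 map to
    0 and 1 regardless of the constants.
    """
    psi = np.asarray(psi, dtype=float)
    if np.any(psi < 0) or np.any(psi > 1):
        raise ValueError("psi must lie in [0, 1]")
    if c_inc <= 0 or c_exc <= 0:
        raise ValueError("informativeness constants must be positive")
    num = psi * c_inc
    den = num + (1.0 - psi) * c_exc
    with np.errstate(invalid="ignore"):
        q = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return q if q.ndim else float(q)


def psi_posterior(
    n_inclusion: int,
    n_exclusion: int,
    c_inc: float = 1.0,
    c_exc: float = 1.0,
    n_points: int = GRID_POINTS,
) -> PsiEstimate:
    """Posterior mean, variance and equal-tailed 95% credible interval of PSI.

    Closed-form Beta(n_inc + 1, n_exc + 1) when the informativeness
    constants are equal; fixed-grid quadrature otherwise.  A (0, 0) record
    returns the Uniform(0, 1) prior.
    """
    if n_inclusion < 0 or n_exclusion < 0:
        raise ValueError("read counts must be non-negative")
    n = int(n_inclusion) + int(n_exclusion)
    if c_inc == c_exc:
        a, b = n_inclusion + 1.0, n_exclusion + 1.0
        mean = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1.0))
        lo, hi = stats.beta.ppf([0.025, 0.975], a, b)
        return PsiEstimate(float(mean), float(var), float(lo), float(hi), n)

    grid = np.linspace(0.0, 1.0, n_points)
    q = inclusion_probability(grid, c_inc, c_exc)
    log_like = xlogy(n_inclusion, q) + xlogy(n_exclusion, 1.0 - q)
    w = np.exp(log_like - log_like.max())
    norm = integrate.simpson(w, x=grid)
    dens = w / norm
    mean = integrate.simpson(dens * grid, x=grid)
    var = integrate.simpson(dens * (grid - mean) ** 2, x=grid)
    cdf = integrate.cumulative_trapezoid(dens, grid, initial=0.0)
    cdf /= cdf[-1]
    lo, hi = np.interp([0.025, 0.975], cdf, grid)
    mean = min(max(float(mean), float(lo)), float(hi))
    return PsiEstimate(mean, float(var), float(lo), float(hi), n)


def log_bayes_factor(
    n_inc1, n_exc1, n_inc2, n_exc2, c_inc: float = 1.0, c_exc: float = 1.0
):
    """Natural-log Bayes factor for "two PSI values" vs "one shared PSI".

    Vectorised closed form for equal informativeness constants:

        BF = B(a1, b1) * B(a2, b2) / B(a1 + a2 - 1, b1 + b2 - 1)

    with a = n_inc + 1, b = n_exc + 1, computed via log Beta functions.
    """
    if c_inc != c_exc:
        return log_bayes_factor_quadrature(
            n_inc1, n_exc1, n_inc2, n_exc2, c_inc, c_exc
        )
    a1 = np.asarray(n_inc1, dtype=float) + 1.0
    b1 = np.asarray(n_exc1, dtype=float) + 1.0
    a2 = np.asarray(n_inc2, dtype=float) + 1.0
    b2 = np.asarray(n_exc2, dtype=float) + 1.0
    out = betaln(a1, b1) + betaln(a2, b2) - betaln(a1 + a2 - 1.0, b1 + b2 - 1.0)
    return out if np.ndim(out) else float(out)


def bayes_factor(n_inc1, n_exc1, n_inc2, n_exc2, c_inc=1.0, c_exc=1.0):
    """Bayes factor on the natural scale; see :func:`log_bayes_factor`."""
    return np.exp(log_bayes_factor(n_inc1, n_exc1, n_inc2, n_exc2, c_inc, c_exc))


def log_marginal_quadrature(
    n_inclusion: int,
    n_exclusion: int,
    c_inc: float = 1.0,
    c_exc: float = 1.0,
    n_points: int = 501,
) -> float:
    """log integral_0^1 q(psi)^n_inc (1-q(psi))^n_exc dpsi, Gauss-Legendre.

    For equal informativeness constants the integrand is a polynomial of
    degree n_inc + n_exc, so the rule is exact whenever
    2 * n_points - 1 >= n_inc + n_exc; the default covers totals up to
    1,000 reads exactly.
    """
    nodes, weights = _leggauss_cached(n_points)
    grid = 0.5 * (nodes + 1.0)  # map [-1, 1] -> [0, 1]
    q = inclusion_probability(grid, c_inc, c_exc)
    log_f = xlogy(n_inclusion, q) + xlogy(n_exclusion, 1.0 - q)
    m = log_f.max()
    return float(m + np.log(0.5 * np.sum(weights * np.exp(log_f - m))))


def log_bayes_factor_quadrature(
    n_inc1, n_exc1, n_inc2, n_exc2, c_inc=1.0, c_exc=1.0, n_points=501
) -> float:
    """Numeric-integration Bayes factor; reference path for the closed form."""
    m1 = log_marginal_quadrature(n_inc1, n_exc1, c_inc, c_exc, n_points)
    m2 = log_marginal_quadrature(n_inc2, n_exc2, c_inc, c_exc, n_points)
    ms = log_marginal_quadrature(
        n_inc1 + n_inc2, n_exc1 + n_exc2, c_inc, c_exc, n_points
    )
    return m1 + m2 - ms


def delta_psi(estimate_1, estimate_2) -> float:
    """Signed PSI difference, first argument minus second.

    Convention throughout the package: the first argument is the C57BL/6J
    strain or allele, so a positive value means higher inclusion in B.
    """
    m1 = estimate_1.psi_mean if isinstance(estimate_1, PsiEstimate) else estimate_1
    m2 = estimate_2.psi_mean if isinstance(estimate_2, PsiEstimate) else estimate_2
    return float(m1) - float(m2)


def fisher_divergence_test(
    n_inc1: int, n_exc1: int, n_inc2: int, n_exc2: int
) -> float:
    """Two-sided Fisher exact p-value on the 2x2 inclusion/exclusion table.

    Uses the standard convention of summing the probabilities of all tables
    with fixed margins that are no more probable than the observed one.
    A degenerate (all-zero margin) table returns p = 1 with a warning.
    """
    table = np.array([[n_inc1, n_exc1], [n_inc2, n_exc2]])
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        warnings.warn("degenerate 2x2 table (zero margin); p = 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def isoform_ratio_psi(n_long: int, n_short: int) -> float:
    """Plain isoform-ratio PSI: long / (long + short) supporting reads.

    This is the estimator used for validation-style count vectors (e.g.
    full-length cDNA reads assigned to isoforms), without any prior.
    """
    if n_long < 0 or n_short < 0:
        raise ValueError("counts must be non-negative")
    total = n_long + n_short
    if total == 0:
        raise ValueError("isoform_ratio_psi requires at least one read")
    return n_long / total
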