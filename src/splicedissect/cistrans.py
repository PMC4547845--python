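"""Cis/trans dissection of splicing divergence.

In an F1 hybrid both parental alleles share one trans-regulatory
environment, so an allelic PSI difference can only be of cis origin.
Trans effects are detected by comparing the parental PSI ratio with the
allelic PSI ratio (Altman–Bland interaction test on the log scale):

    z = (log R_parental - log R_allelic) / sqrt(SE_p^2 + SE_a^2)

where R = PSI_B / PSI_S from counts pooled over replicates, and the SEs
come from the Beta posterior variances via the delta method.  P-values are
converted to q-values with Storey's procedure, and each parental-divergent
event is classified as cis_only, trans_only, cis_and_trans or unexplained
by combining the allelic divergence call with the trans-test significance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

__all__ = [
    "ratio_and_se",
    "ratio_and_se_from_moments",
    "trans_z_test",
    "storey_qvalues",
    "classify",
    "CATEGORIES",
]

CATEGORIES = (
    "cis_only", "trans_only", "cis_and_trans", "unexplained", "conserved",
    "filtered",
)


def ratio_and_se(n_inc1, n_exc1, n_inc2, n_exc2):
    """Log PSI ratio and its delta-method standard error from pooled counts.

    PSI means and variances are those of the Beta(n_inc+1, n_exc+1)
    posterior; sides are assumed independent:

        log R = log psi_1 - log psi_2
        SE^2  = var_1 / psi_1^2 + var_2 / psi_2^2

    Vectorised over events.  Raises if a side has zero total reads (such
    events must be removed by the coverage filter first).
    """
    i1 = np.asarray(n_inc1, dtype=float)
    e1 = np.asarray(n_exc1, dtype=float)
    i2 = np.asarray(n_inc2, dtype=float)
    e2 = np.asarray(n_exc2, dtype=float)
    if np.any(i1 + e1 == 0) or np.any(i2 + e2 == 0):
        raise ValueError("zero total reads on one side; apply coverage filter")
    a1, b1 = i1 + 1.0, e1 + 1.0
    a2, b2 = i2 + 1.0, e2 + 1.0
    m1 = a1 / (a1 + b1)
    v1 = a1 * b1 / ((a1 + b1) ** 2 * (a1 + b1 + 1.0))
    m2 = a2 / (a2 + b2)
    v2 = a2 * b2 / ((a2 + b2) ** 2 * (a2 + b2 + 1.0))
    log_ratio = np.log(m1) - np.log(m2)
    se = np.sqrt(v1 / m1**2 + v2 / m2**2)
    if np.ndim(n_inc1) == 0 and not isinstance(n_inc1, np.ndarray):
        return float(log_ratio), float(se)
    return log_ratio, se


def ratio_and_se_from_moments(psi1, var1, psi2, var2):
    """Delta-method log ratio and SE from PSI means and variances directly."""
    if psi1 <= 0 or psi2 <= 0:
        raise ValueError("PSI means must be strictly positive on the log scale")
    log_ratio = float(np.log(psi1) - np.log(psi2))
    se = float(np.sqrt(var1 / psi1**2 + var2 / psi2**2))
    return log_ratio, se


def trans_z_test(log_ratio_parental, se_parental, log_ratio_allelic, se_allelic):
    """Interaction z-test between parental and allelic log PSI ratios.

    Returns (z, two-sided p) from the standard normal; vectorised.
    """
    lrp = np.asarray(log_ratio_parental, dtype=float)
    lra = np.asarray(log_ratio_allelic, dtype=float)
    sep = np.asarray(se_parental, dtype=float)
    sea = np.asarray(se_allelic, dtype=float)
    if np.any(sep <= 0) or np.any(sea <= 0):
        raise ValueError("standard errors must be positive")
    z = (lrp - lra) / np.sqrt(sep**2 + sea**2)
    p = 2.0 * stats.norm.sf(np.abs(z))
    if np.ndim(log_ratio_parental) == 0 and not isinstance(
        log_ratio_parental, np.ndarray
    ):
        return float(z), float(p)
    return z, p


def storey_qvalues(p_values) -> np.ndarray:
    """Storey q-values with smoother-based pi0 estimation.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on the grid
    lambda = 0.05, 0.10, ..., 0.95 is smoothed with a cubic spline and
    evaluated at the largest lambda (capped at 1).  For fewer than 100
    tests the estimate falls back to pi0 at lambda = 0.5.  q-values are the
    step-up minima of pi0 * m * p / rank, clipped to [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    lam = np.arange(0.05, 0.951, 0.05)
    pi0_lam = np.array([(p > la).sum() / (m * (1.0 - la)) for la in lam])
    if m < 100:
        pi0 = pi0_lam[np.argmin(np.abs(lam - 0.5))]
    else:
        spline = UnivariateSpline(lam, pi0_lam, k=3)
        pi0 = float(spline(lam[-1]))
    pi0 = min(max(pi0, 0.0), 1.0)
    if pi0 == 0.0:
        pi0 = 1.0 / m  # degenerate: all p tiny; keep q-values finite
    order = np.argsort(p)
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def classify(
    parental_calls: pd.DataFrame,
    allelic_calls: pd.DataFrame,
    trans_results: pd.DataFrame,
    trans_fdr_cutoff: float,
) -> pd.DataFrame:
    """Combine divergence calls and trans tests into cis/trans categories.

    All three frames are indexed by event_id and must cover the same
    retained event set.  Categories:

    - cis_only:      parental & allelic divergent, trans not significant
    - trans_only:    parental divergent, not allelic, trans significant
    - cis_and_trans: parental & allelic divergent, trans significant
    - unexplained:   parental divergent, not allelic, trans not significant
    - conserved:     not parental divergent (but retained)
    """
    idx = parental_calls.index
    for name, other in (("allelic", allelic_calls), ("trans", trans_results)):
        missing = idx.symmetric_difference(other.index)
        if len(missing):
            raise ValueError(
                f"event set mismatch with {name} input: {sorted(missing)[:5]}..."
                if len(missing) > 5 else
                f"event set mismatch with {name} input: {sorted(missing)}"
            )
    parental = parental_calls["divergent"].reindex(idx).to_numpy(bool)
    allelic = allelic_calls["divergent"].reindex(idx).to_numpy(bool)
    trans = (trans_results["q_value"].reindex(idx) <= trans_fdr_cutoff).to_numpy(bool)
    category = np.full(len(idx), "conserved", dtype=object)
    category[parental & allelic & ~trans] = "cis_only"
    category[parental & allelic & trans] = "cis_and_trans"
    category[parental & ~allelic & trans] = "trans_only"
    category[parental & ~allelic & ~trans] = "unexplained"
    out = pd.DataFrame(
        {
            "parental_divergent": parental,
            "allelic_divergent": allelic,
            "trans_significant": trans,
            "category": category,
        },
        index=idx,
    )
    out.attrs["trans_fdr_cutoff"] = trans_fdr_cutoff
    return out
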