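"""Mock-hybrid consistency filtering of allelic PSI quantification.

Allelic quantification in an F1 hybrid uses only reads assignable to one
allele.  Events with few distinguishing variants lose coverage, and events
where assignability correlates with isoform lose accuracy.  Both failure
modes are detected with a *mock* F1 hybrid — an equal mixture of the two
parental read sets processed exactly like a real hybrid: the parental PSI
of a well-behaved event must be recovered from its mock allelic counts.

Two screens are applied per allele:

1. coverage: events with < 20 assignable reads in any mock replicate are
   dropped as underpowered;
2. consistency: the parental-vs-mock ΔPSI is standardised by a
   coverage-dependent local standard deviation (learned from a pure
   downsampling comparison, where only sampling noise acts), giving a
   Z-value and a normal two-sided p; Benjamini–Hochberg at FDR 0.05 across
   all (event, allele) pairs flags assignment-biased events.

The local SD is the sample SD of downsampling deltas inside a centered
window holding 1% of the coverage-sorted events (minimum 20), smoothed
against coverage rank with a local-quadratic loess and floored at 1e-4.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .divergence import counts_to_arrays

__all__ = [
    "mock_coverage_filter",
    "loess_smooth",
    "local_sd",
    "mock_z_filter",
    "run_mock_filter",
]

SIGMA_FLOOR = 1e-4


def mock_coverage_filter(
    mock_counts: pd.DataFrame, threshold: int = 20,
    sample: str = "mock", alleles=("B", "S"),
) -> set[str]:
    """Event ids with < threshold allelic reads in any mock record."""
    drop: set[str] = set()
    for allele in alleles:
        ids, inc, exc = counts_to_arrays(mock_counts, sample, allele)
        low = ((inc + exc) < threshold).any(axis=1)
        drop.update(ids[low])
    return drop


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
    eval_points: int = 200,
) -> np.ndarray:
    """Loess (locally weighted polynomial regression) with tricube weights.

    Fits at ``eval_points`` positions spread over the data and linearly
    interpolates back to ``x``; this is the standard speed-up and is
    accurate for the smooth, dense curves it is used on here.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < degree + 2:
        return np.full_like(x, y.mean())
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    k = max(int(np.ceil(span * n)), degree + 2)
    xe = np.unique(np.quantile(xs, np.linspace(0, 1, min(eval_points, n))))
    fitted = np.empty(xe.size)
    for i, x0 in enumerate(xe):
        lo = np.searchsorted(xs, x0)
        a = max(0, min(lo - k // 2, n - k))
        b = a + k
        xw, yw = xs[a:b], ys[a:b]
        h = np.max(np.abs(xw - x0))
        if h == 0:
            fitted[i] = yw.mean()
            continue
        w = (1.0 - np.minimum(np.abs(xw - x0) / h, 1.0) ** 3) ** 3
        coef = np.polyfit(xw - x0, yw, deg=degree, w=np.sqrt(np.maximum(w, 1e-12)))
        fitted[i] = coef[-1]
    return np.interp(x, xe, fitted)


def local_sd(
    deltas: np.ndarray,
    coverage: np.ndarray,
    window_fraction: float = 0.01,
    min_window: int = 20,
    span: float = 0.75,
) -> np.ndarray:
    """Coverage-dependent local SD of sampling-noise deltas.

    Events are sorted by coverage; each event's raw sigma is the sample SD
    of the deltas in a centered window of ceil(window_fraction * N) events
    (at least ``min_window``, truncated at the ends); the raw curve is then
    loess-smoothed against coverage rank and floored at 1e-4.  Returned in
    the original event order.
    """
    deltas = np.asarray(deltas, dtype=float)
    coverage = np.asarray(coverage, dtype=float)
    n = deltas.size
    if n < 2:
        raise ValueError("local_sd requires at least two events")
    w = max(int(np.ceil(window_fraction * n)), min_window)
    if n < w:
        warnings.warn(
            f"only {n} events (< window {w}); using a single global SD",
            stacklevel=2,
        )
        return np.full(n, max(float(deltas.std(ddof=1)), SIGMA_FLOOR))
    order = np.argsort(coverage, kind="stable")
    d = deltas[order]
    # rolling window SD with edge truncation via cumulative sums
    half = w // 2
    starts = np.clip(np.arange(n) - half, 0, n - w)
    c1 = np.concatenate([[0.0], np.cumsum(d)])
    c2 = np.concatenate([[0.0], np.cumsum(d * d)])
    s1 = c1[starts + w] - c1[starts]
    s2 = c2[starts + w] - c2[starts]
    var = (s2 - s1 * s1 / w) / (w - 1)
    raw = np.sqrt(np.maximum(var, 0.0))
    smooth = loess_smooth(np.arange(n, dtype=float), raw, span=span)
    sigma = np.maximum(smooth, SIGMA_FLOOR)
    out = np.empty(n)
    out[order] = sigma
    return out


def mock_z_filter(
    event_ids: np.ndarray,
    alleles: np.ndarray,
    psi_parental: np.ndarray,
    psi_mock: np.ndarray,
    coverage: np.ndarray,
    sigma_local: np.ndarray,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Z-test of parental-vs-mock PSI deltas with BH adjustment.

    One row per (event, allele).  verdict is 'drop_inconsistent' where the
    BH-adjusted two-sided normal p falls below ``fdr``, else 'keep'.
    """
    delta = np.asarray(psi_parental, dtype=float) - np.asarray(psi_mock, dtype=float)
    sigma = np.asarray(sigma_local, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma_local must be positive (floored upstream)")
    z = delta / sigma
    p = 2.0 * stats.norm.sf(np.abs(z))
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    p_adj = np.maximum(p_adj, p)
    verdict = np.where(p_adj < fdr, "drop_inconsistent", "keep")
    return pd.DataFrame(
        {
            "event_id": event_ids,
            "allele": alleles,
            "psi_parental": psi_parental,
            "psi_mock": psi_mock,
            "delta": delta,
            "coverage": coverage,
            "sigma_local": sigma,
            "z_value": z,
            "p_value": p,
            "p_adjusted": p_adj,
            "verdict": verdict,
        }
    )


def _pooled_psi(counts, sample, allele):
    ids, inc, exc = counts_to_arrays(counts, sample, allele)
    pinc, pexc = inc.sum(axis=1), exc.sum(axis=1)
    psi = (pinc + 1.0) / (pinc + pexc + 2.0)
    return pd.DataFrame(
        {"psi": psi, "coverage": pinc + pexc},
        index=pd.Index(ids, name="event_id"),
    )


def run_mock_filter(
    parental_counts: pd.DataFrame,
    mock_counts: pd.DataFrame,
    downsampled_counts: pd.DataFrame,
    coverage_threshold: int = 20,
    fdr: float = 0.05,
    window_fraction: float = 0.01,
    span: float = 0.75,
    parent_samples: dict[str, str] | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Full mock-hybrid filter; returns (kept event ids, per-record report).

    ``parental_counts`` holds samples 'parent_B'/'parent_S' (allele
    'pooled'); ``mock_counts`` holds sample 'mock' with alleles 'B'/'S';
    ``downsampled_counts`` holds sample 'downsampled' with alleles 'B'/'S'
    (parental reads subsampled to mock allelic coverage).  PSI values are
    posterior means of counts pooled across replicates.  Real-hybrid data
    play no role here.
    """
    parent_samples = parent_samples or {"B": "parent_B", "S": "parent_S"}
    low_cov = mock_coverage_filter(mock_counts, coverage_threshold)

    frames = []
    for allele, parent in parent_samples.items():
        par = _pooled_psi(parental_counts, parent, None)
        mock = _pooled_psi(mock_counts, "mock", allele)
        down = _pooled_psi(downsampled_counts, "downsampled", allele)
        common = par.index.intersection(mock.index).intersection(down.index)
        common = common[~common.isin(low_cov)]
        if len(common) == 0:
            continue
        par, mock, down = par.loc[common], mock.loc[common], down.loc[common]
        # sampling-noise deltas from the pure downsampling comparison
        train_delta = (par["psi"] - down["psi"]).to_numpy()
        train_cov = down["coverage"].to_numpy(float)
        sigma_train = local_sd(
            train_delta, train_cov,
            window_fraction=window_fraction, span=span,
        )
        # map sigma onto mock events by coverage
        order = np.argsort(train_cov, kind="stable")
        sigma_mock = np.interp(
            mock["coverage"].to_numpy(float),
            train_cov[order], sigma_train[order],
        )
        sigma_mock = np.maximum(sigma_mock, SIGMA_FLOOR)
        frames.append(
            dict(
                event_ids=common.to_numpy(),
                alleles=np.full(len(common), allele),
                psi_parental=par["psi"].to_numpy(),
                psi_mock=mock["psi"].to_numpy(),
                coverage=mock["coverage"].to_numpy(float),
                sigma_local=sigma_mock,
            )
        )
    if not frames:
        raise ValueError("no events survive the mock coverage filter")
    stacked = {
        k: np.concatenate([f[k] for f in frames]) for k in frames[0]
    }
    report = mock_z_filter(fdr=fdr, **stacked)

    inconsistent = set(
        report.loc[report["verdict"] == "drop_inconsistent", "event_id"]
    )
    all_ids = set(parental_counts["event_id"].unique())
    kept = (all_ids - low_cov) - inconsistent
    lc = pd.DataFrame(
        {
            "event_id": sorted(low_cov),
            "allele": "both",
            "verdict": "drop_low_coverage",
        }
    )
    report = pd.concat([report, lc], ignore_index=True)
    return kept, report
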