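"""Divergence calling between two samples and permutation-based FDR.

A splicing event is called divergent between two samples (parental strains,
or the two alleles of an F1 hybrid) when the Bayes factor exceeds ``bf_min``
in *every* replicate pair and the absolute value of the replicate-averaged
signed ΔPSI exceeds ``delta_min`` (defaults 5 and 0.1).  Replicates are
paired by index.

The false-discovery rate of that joint threshold is estimated by
bootstrapped label permutation: events are resampled with replacement, the
sample labels of replicates 2..k are swapped between the two samples to
form a null comparison, and the number of null events passing the threshold
is divided by the number of real events passing it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .psi import log_bayes_factor

__all__ = [
    "counts_to_arrays",
    "coverage_filter",
    "call_divergent",
    "divergence_table",
    "permutation_fdr",
    "select_controls",
]

DEFAULT_FDR_GRID = np.round(np.arange(0.01, 0.201, 0.01), 2)


def counts_to_arrays(
    counts: pd.DataFrame, sample: str, allele: str | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pivot a long count table into (event_ids, inc[N, k], exc[N, k]).

    ``counts`` has columns event_id, sample, replicate, allele,
    n_inclusion, n_exclusion.  Missing (event, replicate) cells become 0.
    """
    sub = counts[counts["sample"] == sample]
    if allele is not None:
        sub = sub[sub["allele"] == allele]
    if sub.empty:
        raise ValueError(f"no count records for sample={sample!r}, allele={allele!r}")
    inc = sub.pivot_table(
        index="event_id", columns="replicate", values="n_inclusion",
        aggfunc="sum", fill_value=0,
    ).sort_index()
    exc = sub.pivot_table(
        index="event_id", columns="replicate", values="n_exclusion",
        aggfunc="sum", fill_value=0,
    ).sort_index()
    return inc.index.to_numpy(), inc.to_numpy(float), exc.to_numpy(float)


def _align(ids1, inc1, exc1, ids2, inc2, exc2):
    common = np.intersect1d(ids1, ids2)
    i1 = pd.Index(ids1).get_indexer(common)
    i2 = pd.Index(ids2).get_indexer(common)
    return common, inc1[i1], exc1[i1], inc2[i2], exc2[i2]


def coverage_filter(totals: np.ndarray, threshold: int = 20) -> np.ndarray:
    """Boolean mask of events with >= threshold reads in every replicate.

    ``totals`` is (N, k) spliced-in + spliced-out reads; columns may also
    stack several samples' replicates.
    """
    totals = np.atleast_2d(np.asarray(totals))
    return (totals >= threshold).all(axis=1)


def call_divergent(
    bf_values,
    delta_values,
    bf_min: float = 5.0,
    delta_min: float = 0.1,
    delta_agg: str = "signed-mean",
):
    """Joint Bayes-factor / ΔPSI divergence flag.

    Divergent iff BF > bf_min in all replicates (strict) and the aggregated
    |ΔPSI| > delta_min (strict).  ``delta_agg`` chooses between
    'signed-mean' (|mean of signed ΔPSI|, default: sign-inconsistent
    replicates cancel) and 'abs-mean' (mean of |ΔPSI|).
    """
    bf = np.atleast_2d(np.asarray(bf_values, dtype=float))
    dl = np.atleast_2d(np.asarray(delta_values, dtype=float))
    if bf.shape != dl.shape:
        raise ValueError("bf_values and delta_values must have equal shape")
    if bf.shape[1] < 2:
        raise ValueError("at least two replicates required")
    if delta_agg == "signed-mean":
        agg = np.abs(dl.mean(axis=1))
    elif delta_agg == "abs-mean":
        agg = np.abs(dl).mean(axis=1)
    else:
        raise ValueError(f"unknown delta_agg {delta_agg!r}")
    flag = (bf > bf_min).all(axis=1) & (agg > delta_min)
    if np.ndim(bf_values) == 1 or (
        hasattr(bf_values, "ndim") and bf_values.ndim == 1
    ):
        return bool(flag[0])
    return flag


def _replicate_stats(inc1, exc1, inc2, exc2, c_inc=1.0, c_exc=1.0):
    """Per-replicate posterior-mean ΔPSI and log BF arrays, shape (N, k)."""
    psi1 = (inc1 + 1.0) / (inc1 + exc1 + 2.0)
    psi2 = (inc2 + 1.0) / (inc2 + exc2 + 2.0)
    delta = psi1 - psi2
    logbf = log_bayes_factor(inc1, exc1, inc2, exc2, c_inc, c_exc)
    return delta, logbf


def divergence_table(
    counts: pd.DataFrame,
    sample1: str,
    sample2: str,
    allele1: str | None = None,
    allele2: str | None = None,
    bf_min: float = 5.0,
    delta_min: float = 0.1,
    coverage_min: int = 20,
    delta_agg: str = "signed-mean",
    comparison: str = "parental",
) -> pd.DataFrame:
    """Per-event divergence calls between two samples.

    Events are first coverage-filtered (>= coverage_min reads in every
    replicate of both samples), then flagged by :func:`call_divergent`.
    Replicates are paired by index.  Returns a frame indexed by event_id
    with per-replicate log BF / ΔPSI columns, mean_delta and ``divergent``.
    """
    ids1, inc1, exc1 = counts_to_arrays(counts, sample1, allele1)
    ids2, inc2, exc2 = counts_to_arrays(counts, sample2, allele2)
    ids, inc1, exc1, inc2, exc2 = _align(ids1, inc1, exc1, ids2, inc2, exc2)
    if inc1.shape[1] != inc2.shape[1]:
        raise ValueError("replicate structure mismatch between samples")
    covered = coverage_filter(
        np.hstack([inc1 + exc1, inc2 + exc2]), coverage_min
    )
    ids = ids[covered]
    inc1, exc1 = inc1[covered], exc1[covered]
    inc2, exc2 = inc2[covered], exc2[covered]
    delta, logbf = _replicate_stats(inc1, exc1, inc2, exc2)
    k = delta.shape[1]
    if delta_agg == "signed-mean":
        mean_delta = delta.mean(axis=1)
        agg = np.abs(mean_delta)
    else:
        mean_delta = delta.mean(axis=1)
        agg = np.abs(delta).mean(axis=1)
    divergent = (logbf > np.log(bf_min)).all(axis=1) & (agg > delta_min)
    data = {"comparison": comparison}
    for j in range(k):
        data[f"log_bf_{j + 1}"] = logbf[:, j]
        data[f"delta_psi_{j + 1}"] = delta[:, j]
    data["mean_delta"] = mean_delta
    data["divergent"] = divergent
    out = pd.DataFrame(data, index=pd.Index(ids, name="event_id"))
    out.attrs["bf_min"] = bf_min
    out.attrs["delta_min"] = delta_min
    out.attrs["n_replicates"] = k
    return out


def permutation_fdr(
    counts: pd.DataFrame,
    sample1: str,
    sample2: str,
    allele1: str | None = None,
    allele2: str | None = None,
    bf_min: float = 5.0,
    cutoffs=DEFAULT_FDR_GRID,
    n_permutations: int = 100,
    coverage_min: int = 20,
    delta_agg: str = "signed-mean",
    seed: int | None = None,
) -> pd.DataFrame:
    """Bootstrapped label-permutation FDR per |ΔPSI| cutoff.

    For each cutoff x: real positives are events with BF > bf_min in all
    replicates and aggregated |ΔPSI| > x.  Each of ``n_permutations``
    pseudo-datasets bootstraps events with replacement and swaps the sample
    labels of replicates 2..k; events passing the threshold there are false
    positives.  FDR(x) = mean over permutations of FP_i / N_real, with the
    2.5/97.5 percentile band.  Cutoffs with N_real = 0 report NaN.
    """
    rng = np.random.default_rng(seed)
    ids1, inc1, exc1 = counts_to_arrays(counts, sample1, allele1)
    ids2, inc2, exc2 = counts_to_arrays(counts, sample2, allele2)
    ids, inc1, exc1, inc2, exc2 = _align(ids1, inc1, exc1, ids2, inc2, exc2)
    covered = coverage_filter(np.hstack([inc1 + exc1, inc2 + exc2]), coverage_min)
    inc1, exc1 = inc1[covered], exc1[covered]
    inc2, exc2 = inc2[covered], exc2[covered]
    n_events, k = inc1.shape
    if k < 2:
        raise ValueError("permutation FDR requires >= 2 replicates per sample")

    delta, logbf = _replicate_stats(inc1, exc1, inc2, exc2)
    bf_pass = (logbf > np.log(bf_min)).all(axis=1)
    if delta_agg == "signed-mean":
        real_agg = np.abs(delta.mean(axis=1))
    else:
        real_agg = np.abs(delta).mean(axis=1)

    # null comparison: replicate 1 keeps its labels, replicates >= 2 swap
    ninc1 = np.concatenate([inc1[:, :1], inc2[:, 1:]], axis=1)
    nexc1 = np.concatenate([exc1[:, :1], exc2[:, 1:]], axis=1)
    ninc2 = np.concatenate([inc2[:, :1], inc1[:, 1:]], axis=1)
    nexc2 = np.concatenate([exc2[:, :1], exc1[:, 1:]], axis=1)
    ndelta, nlogbf = _replicate_stats(ninc1, nexc1, ninc2, nexc2)
    null_bf_pass = (nlogbf > np.log(bf_min)).all(axis=1)
    if delta_agg == "signed-mean":
        null_agg = np.abs(ndelta.mean(axis=1))
    else:
        null_agg = np.abs(ndelta).mean(axis=1)

    boot = rng.integers(0, n_events, size=(n_permutations, n_events))
    rows = []
    for x in np.asarray(cutoffs, dtype=float):
        n_real = int((bf_pass & (real_agg > x)).sum())
        null_pass = null_bf_pass & (null_agg > x)
        fp = null_pass[boot].sum(axis=1)
        fp_stats = (
            float(fp.mean()),
            float(np.percentile(fp, 2.5)), float(np.percentile(fp, 97.5)),
        )
        if n_real == 0:
            rows.append((x, np.nan, np.nan, np.nan, np.nan, 0, *fp_stats))
            continue
        ratio = fp / n_real
        rows.append((
            x, float(ratio.mean()), float(ratio.std(ddof=1)),
            float(np.percentile(ratio, 2.5)), float(np.percentile(ratio, 97.5)),
            n_real, *fp_stats,
        ))
    out = pd.DataFrame(
        rows,
        columns=["cutoff", "fdr_mean", "fdr_sd", "fdr_lo", "fdr_hi", "n_real",
                 "fp_mean", "fp_lo", "fp_hi"],
    )
    out.attrs["n_events"] = n_events
    return out


def select_controls(
    counts: pd.DataFrame,
    sample1: str,
    sample2: str,
    allele1: str | None = None,
    allele2: str | None = None,
    bf_max: float = 1.0,
    psi_low: float = 0.05,
    psi_high: float = 0.95,
    delta_max: float = 0.05,
    coverage_min: int = 20,
) -> np.ndarray:
    """Events with no evidence of splicing divergence (control set).

    Requires, after the coverage filter: BF < bf_max in every replicate,
    psi_low < PSI < psi_high in every replicate of both samples (posterior
    means), and |mean ΔPSI| < delta_max.  All inequalities strict.
    """
    ids1, inc1, exc1 = counts_to_arrays(counts, sample1, allele1)
    ids2, inc2, exc2 = counts_to_arrays(counts, sample2, allele2)
    ids, inc1, exc1, inc2, exc2 = _align(ids1, inc1, exc1, ids2, inc2, exc2)
    covered = coverage_filter(np.hstack([inc1 + exc1, inc2 + exc2]), coverage_min)
    ids = ids[covered]
    inc1, exc1 = inc1[covered], exc1[covered]
    inc2, exc2 = inc2[covered], exc2[covered]
    delta, logbf = _replicate_stats(inc1, exc1, inc2, exc2)
    psi1 = (inc1 + 1.0) / (inc1 + exc1 + 2.0)
    psi2 = (inc2 + 1.0) / (inc2 + exc2 + 2.0)
    ok = (
        (logbf < np.log(bf_max)).all(axis=1)
        & (psi1 > psi_low).all(axis=1) & (psi1 < psi_high).all(axis=1)
        & (psi2 > psi_low).all(axis=1) & (psi2 < psi_high).all(axis=1)
        & (np.abs(delta.mean(axis=1)) < delta_max)
    )
    return ids[ok]
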