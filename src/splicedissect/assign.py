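"""Allele assignment of hybrid reads by edit distance.

Each hybrid read is compared against the local haplotype sequences of the
two parental genomes; it is assigned to the allele with the strictly
smaller Levenshtein (indel-aware) edit distance and discarded as
unassigned on a tie.  Distances are computed with edlib in infix mode, so
a read that is an exact substring of its own haplotype has distance 0
regardless of the surrounding slop.  'N' bases match nothing, including
other 'N's.

This module also builds the two bias-control datasets used by the
mock-hybrid filter: the mock F1 (an equal mixture of the parental read
sets, or at count level the parental counts thinned by per-event
assignability) and the downsampled-parental dataset (parental counts
hypergeometrically subsampled to mock allelic coverage, isolating pure
sampling noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

__all__ = [
    "AssignedRead",
    "levenshtein",
    "infix_distance",
    "assign_read",
    "assign_reads",
    "build_mock_f1_counts",
    "build_mock_f1_reads",
    "downsample_parental",
]

VALID_BASES = set("ACGTN")


def _sanitize(seq: str, sentinel: str) -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"invalid bases in sequence: {sorted(bad)}")
    # distinct sentinels per side make N match nothing, even another N
    return seq.replace("N", sentinel)


def levenshtein(a: str, b: str) -> int:
    """Global Levenshtein distance (substitutions, insertions, deletions)."""
    return edlib.align(_sanitize(a, "X"), _sanitize(b, "Z"), mode="NW")[
        "editDistance"
    ]


def infix_distance(read: str, locus: str) -> int:
    """Best edit distance of ``read`` against any substring of ``locus``."""
    return edlib.align(_sanitize(read, "X"), _sanitize(locus, "Z"), mode="HW")[
        "editDistance"
    ]


@dataclass(frozen=True)
class AssignedRead:
    read_id: str
    allele: str  # 'B', 'S' or 'unassigned'
    edit_distance_B: int
    edit_distance_S: int


def assign_read(
    read: str, locus_B: str, locus_S: str, read_id: str = ""
) -> AssignedRead:
    """Assign one read to the haplotype with strictly smaller edit distance.

    Ties (reads overlapping no distinguishing variant) are unassigned and
    are discarded from allele-specific quantification downstream.
    """
    if not read:
        raise ValueError("empty read")
    d_b = infix_distance(read, locus_B)
    d_s = infix_distance(read, locus_S)
    if d_b < d_s:
        allele = "B"
    elif d_s < d_b:
        allele = "S"
    else:
        allele = "unassigned"
    return AssignedRead(read_id, allele, d_b, d_s)


def assign_reads(
    reads: pd.DataFrame,
    haplotype_B: dict[str, str],
    haplotype_S: dict[str, str],
    slop: int = 20,
) -> pd.DataFrame:
    """Assign a table of reads using origin-interval locus retrieval.

    ``reads`` needs columns read_id, sequence, chromosome, start_B, end_B,
    start_S, end_S (genomic origin interval on each haplotype; for reads of
    unknown origin the full chromosome may be used).  The locus is the
    origin interval widened by ``slop`` nt on both sides.
    """
    rows = []
    for r in reads.itertuples(index=False):
        seq_b = haplotype_B[r.chromosome]
        seq_s = haplotype_S[r.chromosome]
        locus_b = seq_b[max(0, int(r.start_B) - slop): int(r.end_B) + slop]
        locus_s = seq_s[max(0, int(r.start_S) - slop): int(r.end_S) + slop]
        a = assign_read(r.sequence, locus_b, locus_s, read_id=r.read_id)
        rows.append((a.read_id, a.edit_distance_B, a.edit_distance_S, a.allele))
    return pd.DataFrame(rows, columns=["read_id", "dist_B", "dist_S", "allele"])


def build_mock_f1_counts(
    parental_counts: pd.DataFrame,
    assignability,
    seed: int | None = None,
    parent_samples: dict[str, str] | None = None,
    sample_name: str = "mock",
) -> pd.DataFrame:
    """Count-level mock F1: equal parental amounts, thinned by assignability.

    Per event and replicate, both parents are first hypergeometrically
    downsampled to the smaller total (mixing equal amounts), then each
    parent's (inclusion, exclusion) counts are binomially thinned by the
    per-event assignability — the probability that a hybrid read can be
    assigned to an allele.  ``assignability`` is a scalar or a mapping
    event_id -> probability.
    """
    rng = np.random.default_rng(seed)
    parent_samples = parent_samples or {"B": "parent_B", "S": "parent_S"}
    piv = {}
    for allele, sample in parent_samples.items():
        sub = parental_counts[parental_counts["sample"] == sample]
        piv[allele] = sub.set_index(["event_id", "replicate"])[
            ["n_inclusion", "n_exclusion"]
        ].sort_index()
    idx = piv["B"].index.intersection(piv["S"].index)
    if len(idx) != len(piv["B"]) or len(idx) != len(piv["S"]):
        raise ValueError("replicate structure mismatch between parents")
    out = []
    for allele in ("B", "S"):
        tab = piv[allele].loc[idx]
        inc = tab["n_inclusion"].to_numpy(np.int64)
        exc = tab["n_exclusion"].to_numpy(np.int64)
        tot = inc + exc
        other = piv["S" if allele == "B" else "B"].loc[idx]
        target = np.minimum(tot, (other["n_inclusion"] + other["n_exclusion"]).to_numpy(np.int64))
        inc_ds = _hypergeom_downsample(rng, inc, exc, target)
        exc_ds = target - inc_ds
        if np.isscalar(assignability):
            p = np.full(len(idx), float(assignability))
        else:
            p = np.array([assignability[e] for e, _ in idx])
        inc_m = rng.binomial(inc_ds, p)
        exc_m = rng.binomial(exc_ds, p)
        df = pd.DataFrame(
            {
                "event_id": [e for e, _ in idx],
                "sample": sample_name,
                "replicate": [r for _, r in idx],
                "allele": allele,
                "n_inclusion": inc_m,
                "n_exclusion": exc_m,
            }
        )
        out.append(df)
    return pd.concat(out, ignore_index=True)


def build_mock_f1_reads(
    reads_B: pd.DataFrame, reads_S: pd.DataFrame, seed: int | None = None
) -> pd.DataFrame:
    """Read-level mock F1: draw equal numbers of reads from each parent."""
    rng = np.random.default_rng(seed)
    n = min(len(reads_B), len(reads_S))
    take_b = reads_B.iloc[rng.choice(len(reads_B), size=n, replace=False)]
    take_s = reads_S.iloc[rng.choice(len(reads_S), size=n, replace=False)]
    return pd.concat([take_b, take_s], ignore_index=True)


def _hypergeom_downsample(rng, inc, exc, target):
    inc = np.asarray(inc, np.int64)
    exc = np.asarray(exc, np.int64)
    target = np.asarray(target, np.int64)
    tot = inc + exc
    if np.any(target > tot):
        bad = np.flatnonzero(target > tot)
        raise ValueError(f"downsampling target exceeds coverage at rows {bad[:5]}")
    out = np.zeros_like(inc)
    nz = target > 0
    # hypergeometric requires ngood + nbad >= 1
    out[nz] = rng.hypergeometric(inc[nz], exc[nz], target[nz])
    return out


def downsample_parental(
    parental_counts: pd.DataFrame,
    mock_counts: pd.DataFrame,
    seed: int | None = None,
    parent_samples: dict[str, str] | None = None,
    sample_name: str = "downsampled",
) -> pd.DataFrame:
    """Subsample parental counts to mock allelic coverage, without replacement.

    For each (event, replicate, allele) the parental (inclusion, exclusion)
    pair is reduced by hypergeometric sampling to the total observed for
    that allele in the mock hybrid.  A mock total exceeding the parental
    total raises an error naming the event; a target of 0 yields a (0, 0)
    record, which the coverage filter later removes.
    """
    rng = np.random.default_rng(seed)
    parent_samples = parent_samples or {"B": "parent_B", "S": "parent_S"}
    out = []
    for allele, sample in parent_samples.items():
        par = parental_counts[parental_counts["sample"] == sample].set_index(
            ["event_id", "replicate"]
        ).sort_index()
        mock = mock_counts[
            (mock_counts["sample"].isin(mock_counts["sample"].unique()))
            & (mock_counts["allele"] == allele)
        ].set_index(["event_id", "replicate"]).sort_index()
        idx = par.index.intersection(mock.index)
        par, mock = par.loc[idx], mock.loc[idx]
        inc = par["n_inclusion"].to_numpy(np.int64)
        exc = par["n_exclusion"].to_numpy(np.int64)
        target = (mock["n_inclusion"] + mock["n_exclusion"]).to_numpy(np.int64)
        over = target > inc + exc
        if np.any(over):
            ev = [e for (e, _), o in zip(idx, over) if o]
            raise ValueError(
                f"mock coverage exceeds parental coverage for events {ev[:5]}"
            )
        inc_ds = _hypergeom_downsample(rng, inc, exc, target)
        out.append(
            pd.DataFrame(
                {
                    "event_id": [e for e, _ in idx],
                    "sample": sample_name,
                    "replicate": [r for _, r in idx],
                    "allele": allele,
                    "n_inclusion": inc_ds,
                    "n_exclusion": target - inc_ds,
                }
            )
        )
    return pd.concat(out, ignore_index=True)
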