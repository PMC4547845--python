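"""Genomic feature annotation and enrichment statistics for splicing events.

Covers the sequence-level follow-up questions of a cis/trans dissection:
are the flanking regions of cis-divergent events enriched for haplotype
variants, do those events carry variants at their exact splice sites, and
how strongly do such variants change splice-site strength under a position
weight matrix (PWM) model?  Also provides the coding/frame classification
used for the event-effect enrichment table, with the Fisher and
Mann–Whitney comparison tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .events import EventModel, Interval, merge_intervals, total_length
from .psi import fisher_divergence_test

__all__ = [
    "FlankingRegions",
    "flanking_regions",
    "variant_density",
    "splice_site_windows",
    "splice_site_variant_overlap",
    "classify_event_effect",
    "compare_groups",
    "enrichment_table_test",
    "score_splice_site",
    "DONOR_PWM",
    "ACCEPTOR_PWM",
]

DONOR_WINDOW = (-3, 6)    # exon-relative: 3 exonic, 6 intronic positions
ACCEPTOR_WINDOW = (-20, 3)  # 20 intronic, 3 exonic positions


@dataclass(frozen=True)
class FlankingRegions:
    """Union of alternative region(s) plus their 100 nt flanks."""

    event_id: str
    intervals: tuple[Interval, ...]

    @property
    def total_length(self) -> int:
        return total_length(list(self.intervals))


def flanking_regions(event: EventModel, flank: int = 100) -> FlankingRegions:
    """The alternative region(s) of an event with ``flank`` nt on each side.

    SE: alternative exon + 100 nt of each flanking intron; RI: retained
    intron + 100 nt of each flanking exon; A3SS/A5SS: alternative exon
    region + 100 nt exon/intron flanks; MXE: both alternative exons, each
    with 100 nt intron flanks.  Clipped at position 0.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    regs = [
        (max(0, s - flank), e + flank) for s, e in event.alt_regions
    ]
    if not regs:
        raise ValueError(f"{event.event_id}: no alternative region")
    return FlankingRegions(event.event_id, tuple(merge_intervals(regs)))


def variant_density(regions: FlankingRegions, variants: pd.DataFrame) -> float:
    """Variants per nt inside the region union (indels anchor-counted).

    ``variants`` needs columns chromosome?/position; only positions are
    used (pre-filter by chromosome when tables span several).
    """
    length = regions.total_length
    if length == 0:
        raise ValueError("zero-length region set")
    pos = variants["position"].to_numpy()
    n = sum(((pos >= s) & (pos < e)).sum() for s, e in regions.intervals)
    return float(n) / length


def splice_site_windows(
    event: EventModel,
    donor_window: tuple[int, int] = DONOR_WINDOW,
    acceptor_window: tuple[int, int] = ACCEPTOR_WINDOW,
) -> list[Interval]:
    """Genomic windows around the event's alternative splice sites.

    Windows are given exon-relative (negative = exonic side) and oriented
    by strand: a plus-strand donor at boundary b spans [b-3, b+6).
    """
    out = []
    for boundary, kind in event.splice_sites():
        exon_side, intron_side = (
            (-donor_window[0], donor_window[1]) if kind == "donor"
            else (acceptor_window[1], -acceptor_window[0])
        )
        intron_right = (kind == "donor") == (event.strand == "+")
        if intron_right:
            out.append((boundary - exon_side, boundary + intron_side))
        else:
            out.append((boundary - intron_side, boundary + exon_side))
    return [(max(0, s), e) for s, e in out]


def splice_site_variant_overlap(
    event: EventModel,
    variants: pd.DataFrame,
    donor_window: tuple[int, int] = DONOR_WINDOW,
    acceptor_window: tuple[int, int] = ACCEPTOR_WINDOW,
) -> bool:
    """True iff any variant lies in a donor/acceptor window of the event."""
    if len(variants) == 0:
        return False
    sub = variants
    if "chromosome" in variants.columns:
        sub = variants[variants["chromosome"] == event.chromosome]
    pos = sub["position"].to_numpy()
    return any(
        ((pos >= s) & (pos < e)).any()
        for s, e in splice_site_windows(event, donor_window, acceptor_window)
    )


def classify_event_effect(
    event: EventModel, cds_intervals: tuple[Interval, ...] | None = None
) -> tuple[str, str]:
    """(region class, frame class) of an event.

    Coding iff the alternative region overlaps annotated CDS.  For coding
    events, frame-neutral iff the isoform length difference (for MXE the
    difference of the two alternative exon lengths) is divisible by 3.
    Missing annotation yields 'non-coding' with a warning.
    """
    if cds_intervals is None:
        cds_intervals = event.cds
        if not cds_intervals:
            warnings.warn(
                f"{event.event_id}: no CDS annotation; treated as non-coding",
                stacklevel=2,
            )
    overlaps = any(
        s < ce and cs < e
        for s, e in event.alt_regions
        for cs, ce in (cds_intervals or ())
    )
    if not overlaps:
        return "non-coding", "not-applicable"
    frame = "frame-neutral" if event.length_difference % 3 == 0 else "frame-shifting"
    return "coding", frame


def compare_groups(values_a, values_b) -> float:
    """Two-sided Mann–Whitney U p-value between two value groups.

    Exact null distribution when the smaller group has <= 8 values and no
    ties are present; normal approximation with tie correction otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


def enrichment_table_test(
    k1: int, n1: int, k2: int, n2: int
) -> tuple[float, float, float]:
    """Percentages (one decimal) and two-sided Fisher p for a 2x2 table.

    Compares k1-of-n1 against k2-of-n2 divergent events (e.g. the
    non-coding vs coding, or frame-neutral vs frame-shifting rows of an
    event-effect table).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("k must satisfy 0 <= k <= n")
    p = fisher_divergence_test(k1, n1 - k1, k2, n2 - k2)
    return round(100.0 * k1 / n1, 1), round(100.0 * k2 / n2, 1), p


# ---------------------------------------------------------------------------
# splice-site strength scoring

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _consensus_pwm(consensus: str, strong: float = 0.97,
                   invariant: set[int] = frozenset()) -> np.ndarray:
    """PWM concentrated on a consensus string (rows ACGT, columns positions)."""
    w = len(consensus)
    pwm = np.full((4, w), (1.0 - strong) / 3.0)
    for j, base in enumerate(consensus):
        pwm[_BASE_INDEX[base], j] = strong
    # non-invariant positions are softer
    for j in range(w):
        if j not in invariant:
            pwm[:, j] = 0.6 * pwm[:, j] + 0.4 * 0.25
    pwm /= pwm.sum(axis=0, keepdims=True)
    return pwm


#: 9-column donor matrix over the [-3, +6) window (consensus CAG|GTAAGT)
DONOR_PWM = _consensus_pwm("CAGGTAAGT", invariant={3, 4})
#: 23-column acceptor matrix over the [-20, +3) window (polypyrimidine + AG|G)
ACCEPTOR_PWM = _consensus_pwm("TTTTTTTTTTTTTTTTTCAGG", invariant={18, 19})


def score_splice_site(
    sequence: str,
    weight_matrix: np.ndarray,
    background: float = 0.25,
    pseudo: float = 1e-4,
) -> float:
    """PWM log-odds score (bits) of a splice-site window.

    Sum over positions of log2((f + pseudo) / background) where f is the
    matrix frequency of the observed base.  A uniform matrix scores ~0 for
    every sequence; 'N' positions are skipped with a warning.
    """
    seq = sequence.upper()
    if len(seq) != weight_matrix.shape[1]:
        raise ValueError(
            f"window length {len(seq)} != matrix width {weight_matrix.shape[1]}"
        )
    if not np.allclose(weight_matrix.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("matrix columns must sum to 1")
    score = 0.0
    for j, base in enumerate(seq):
        if base == "N":
            warnings.warn(f"N at position {j}; skipped", stacklevel=2)
            continue
        f = weight_matrix[_BASE_INDEX[base], j]
        score += np.log2((f + pseudo) / background)
    return float(score)
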