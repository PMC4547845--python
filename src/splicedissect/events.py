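"""Alternative-splicing event models.

Five event types are supported: skipped exon (SE), retained intron (RI),
mutually exclusive exons (MXE), alternative 5' splice site (A5SS) and
alternative 3' splice site (A3SS).  An event is described by the ordered
exonic segments of its inclusion and exclusion isoforms.  All coordinates
are 0-based half-open internally; GFF3 output converts to 1-based closed.

The *alternative region(s)* of an event — the genomic interval(s) present
in one isoform but not the other — drive downstream annotation: flanking
regions, splice-site windows and reading-frame classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AS_TYPES = ("SE", "RI", "MXE", "A3SS", "A5SS")

Interval = tuple[int, int]


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Union of half-open intervals as a sorted, non-overlapping list."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def symmetric_difference(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Genomic symmetric difference of two interval sets."""
    bounds = sorted({x for iv in a + b for x in iv})
    out: list[Interval] = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        mid = (s + e) // 2
        in_a = any(lo <= mid < hi for lo, hi in a)
        in_b = any(lo <= mid < hi for lo, hi in b)
        if in_a != in_b:
            if out and out[-1][1] == s:
                out[-1] = (out[-1][0], e)
            else:
                out.append((s, e))
    return out


def total_length(intervals: list[Interval]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


@dataclass
class EventModel:
    """One alternative-splicing event.

    ``inclusion_segments`` / ``exclusion_segments`` are the ordered exonic
    segments of the two isoforms (for RI the retained intron is part of the
    single inclusion "exon").  ``c_inclusion`` / ``c_exclusion`` are the
    positive informativeness constants: effective numbers of read positions
    distinguishing each isoform (both 1 means no correction).
    """

    event_id: str
    as_type: str
    chromosome: str
    strand: str
    inclusion_segments: tuple[Interval, ...]
    exclusion_segments: tuple[Interval, ...]
    c_inclusion: float = 1.0
    c_exclusion: float = 1.0
    region_class: str = "coding"  # {coding, non-coding}
    frame_class: str = "not-applicable"
    cds: tuple[Interval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.as_type not in AS_TYPES:
            raise ValueError(f"unknown AS type {self.as_type!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.c_inclusion <= 0 or self.c_exclusion <= 0:
            raise ValueError("informativeness constants must be positive")
        for segs in (self.inclusion_segments, self.exclusion_segments):
            merged = merge_intervals(list(segs))
            if total_length(list(segs)) != sum(e - s for s, e in merged):
                raise ValueError(f"{self.event_id}: overlapping segments")

    # ------------------------------------------------------------------
    @property
    def alt_regions(self) -> list[Interval]:
        """Interval(s) present in exactly one isoform."""
        return symmetric_difference(
            list(self.inclusion_segments), list(self.exclusion_segments)
        )

    @property
    def span(self) -> Interval:
        segs = list(self.inclusion_segments) + list(self.exclusion_segments)
        return (min(s for s, _ in segs), max(e for _, e in segs))

    @property
    def length_difference(self) -> int:
        """Absolute nt difference between inclusion and exclusion isoforms."""
        inc = total_length(list(self.inclusion_segments))
        exc = total_length(list(self.exclusion_segments))
        return abs(inc - exc)

    def splice_sites(self) -> list[tuple[int, str]]:
        """Alternative-junction splice sites as (boundary, kind) pairs.

        Boundaries are genomic coordinates at which an exon/intron junction
        of the alternative region lies; kinds are 'donor'/'acceptor' in the
        biological sense (strand-aware).
        """
        plus_kinds = {
            "SE": ("acceptor", "donor"),
            "RI": ("donor", "acceptor"),
            "MXE": ("acceptor", "donor"),
            "A3SS": ("acceptor", "acceptor"),
            "A5SS": ("donor", "donor"),
        }[self.as_type]
        sites: list[tuple[int, str]] = []
        for s, e in self.alt_regions:
            if self.strand == "-":
                # transcription runs right-to-left: boundary roles swap
                sites.append((s, plus_kinds[1]))
                sites.append((e, plus_kinds[0]))
            else:
                sites.append((s, plus_kinds[0]))
                sites.append((e, plus_kinds[1]))
        return sites


class EventCatalog:
    """Ordered collection of events with id-based lookup."""

    def __init__(self, events: list[EventModel]):
        self.events = list(events)
        self._by_id = {ev.event_id: ev for ev in self.events}
        if len(self._by_id) != len(self.events):
            raise ValueError("duplicate event ids in catalog")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, event_id: str) -> EventModel:
        return self._by_id[event_id]

    def __contains__(self, event_id: str) -> bool:
        return event_id in self._by_id

    def chromosome_extents(self) -> dict[str, int]:
        """Rightmost coordinate used on each chromosome."""
        out: dict[str, int] = {}
        for ev in self.events:
            out[ev.chromosome] = max(out.get(ev.chromosome, 0), ev.span[1])
        return out
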