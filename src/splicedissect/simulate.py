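"""Synthetic data with known cis/trans splicing architectures.

The generator produces everything the analysis consumes — an event catalog
over toy chromosomes, a ground-truth PSI architecture per event, haplotype
variant tables, allele-specific count tables and (optionally) haplotype
sequences with reads — with the statistical structure the method assumes:

* cis effects shift PSI between the two alleles *and* between the parents;
  trans effects shift PSI between the parents only, because both alleles of
  an F1 hybrid share one trans environment;
* effects are additive on the PSI scale and split symmetrically around the
  event's base PSI (±δ/2), clipped to [0.01, 0.99];
* per-event read depth is negative-binomially overdispersed, the hybrid is
  sequenced deeper than the parents (default ×388.0/169.4, mirroring the
  study design this emulates), and only a fraction of hybrid reads
  (default 0.6; 'cast' preset 0.3) can be assigned to an allele;
* sequence variants are denser in the flanking regions of cis-divergent
  events, and a configurable fraction of cis events carries a variant
  inside a splice-site window.

Every output is deterministic given the config seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .events import AS_TYPES, EventCatalog, EventModel, merge_intervals
from .features import classify_event_effect, flanking_regions, splice_site_windows
from .psi import inclusion_probability

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "simulate_dataset", "generate_catalog", "generate_truth",
           "sample_counts", "generate_variants", "emit_reads"]

# per-type proportions of the 11,818-event reference mix
# (SE 5,615; RI 1,768; MXE 696; A3SS 2,236; A5SS 1,503)
DEFAULT_TYPE_MIX = (
    5615 / 11818, 1768 / 11818, 696 / 11818, 2236 / 11818, 1503 / 11818,
)

ARCHITECTURES = ("conserved", "cis", "trans", "cis+trans")

# stage offsets mixed with the config seed so stages are independent streams
_STAGE = {"catalog": 1, "truth": 2, "counts": 3, "variants": 4, "reads": 5}


@dataclass
class SimConfig:
    """Parameters of the synthetic study; defaults are the study conditions."""

    n_events: int = 1000
    type_mix: tuple[float, ...] = DEFAULT_TYPE_MIX
    depth_mean: float = 200.0
    depth_dispersion: float = 10.0
    hybrid_depth_factor: float = 388.0 / 169.4
    n_replicates: int = 3
    frac_cis: float = 0.30
    frac_trans: float = 0.10
    frac_both: float = 0.0
    effect_size_dist: tuple = ("fixed", 0.3)
    psi_base_range: tuple[float, float] = (0.05, 0.95)
    variant_rate_background: float = 0.015
    variant_rate_cis_flank: float = 0.030
    splice_site_variant_frac: float = 0.35
    indel_frac: float = 0.10
    max_indel: int = 9
    assignability: float = 0.6
    read_length: int = 90
    sequencing_error: float = 0.0
    exon_length_range: tuple[int, int] = (100, 300)
    intron_length_range: tuple[int, int] = (200, 1500)
    alt_shift_range: tuple[int, int] = (30, 150)
    coding_fraction: float = 8418 / 11818
    events_per_chromosome: int = 200
    reads_per_event: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be non-negative")
        if len(self.type_mix) != len(AS_TYPES):
            raise ValueError("type_mix needs one proportion per AS type")
        if abs(sum(self.type_mix) - 1.0) > 1e-9 or min(self.type_mix) < 0:
            raise ValueError("type_mix proportions must be >= 0 and sum to 1")
        fracs = (self.frac_cis, self.frac_trans, self.frac_both)
        if min(fracs) < 0 or sum(fracs) > 1.0 + 1e-9:
            raise ValueError("architecture fractions must be >= 0 and sum <= 1")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")
        for rate in (self.variant_rate_background, self.variant_rate_cis_flank):
            if rate < 0:
                raise ValueError("variant rates must be non-negative")
            if rate > 1:
                raise ValueError("variant rates above 1 per nt are impossible")
        if not (0.0 < self.assignability <= 1.0):
            raise ValueError("assignability must lie in (0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (0.0 <= self.sequencing_error < 1.0):
            raise ValueError("sequencing_error must lie in [0, 1)")

    def with_cast_preset(self) -> "SimConfig":
        """Lower-divergence strain pair: ~30% of hybrid reads assignable."""
        return replace(self, assignability=0.3)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("type_mix", "effect_size_dist", "psi_base_range",
                    "exon_length_range", "intron_length_range",
                    "alt_shift_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _rng(config: SimConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STAGE[stage]])


# ---------------------------------------------------------------------------
# catalog


def _build_event(as_type, event_id, chrom, strand, cursor, rng, config):
    ex = lambda: int(rng.integers(*config.exon_length_range))
    iv = lambda: int(rng.integers(*config.intron_length_range))
    s = cursor
    if as_type == "SE":
        e1, i1, a, i2, e2 = ex(), iv(), ex(), iv(), ex()
        up = (s, s + e1)
        alt = (up[1] + i1, up[1] + i1 + a)
        down = (alt[1] + i2, alt[1] + i2 + e2)
        inc, exc = (up, alt, down), (up, down)
    elif as_type == "RI":
        e1, i1, e2 = ex(), iv(), ex()
        up = (s, s + e1)
        down = (up[1] + i1, up[1] + i1 + e2)
        inc, exc = ((s, down[1]),), (up, down)
    elif as_type == "MXE":
        e1, i1, a, i2, b, i3, e2 = ex(), iv(), ex(), iv(), ex(), iv(), ex()
        up = (s, s + e1)
        ex_a = (up[1] + i1, up[1] + i1 + a)
        ex_b = (ex_a[1] + i2, ex_a[1] + i2 + b)
        down = (ex_b[1] + i3, ex_b[1] + i3 + e2)
        inc, exc = (up, ex_a, down), (up, ex_b, down)
    elif as_type == "A3SS":
        e1, i1, e2 = ex(), iv(), ex()
        shift = int(rng.integers(*config.alt_shift_range))
        up = (s, s + e1)
        p = up[1] + i1
        inc = (up, (p, p + shift + e2))
        exc = (up, (p + shift, p + shift + e2))
    elif as_type == "A5SS":
        e1, i1, e2 = ex(), iv(), ex()
        shift = int(rng.integers(*config.alt_shift_range))
        up = (s, s + e1)
        down = (up[1] + shift + i1, up[1] + shift + i1 + e2)
        inc = ((s, s + e1 + shift), down)
        exc = (up, down)
    else:  # pragma: no cover
        raise ValueError(as_type)
    coding = bool(rng.random() < config.coding_fraction)
    span_end = max(e for _, e in inc + exc)
    event = EventModel(
        event_id=event_id,
        as_type=as_type,
        chromosome=chrom,
        strand="+" if rng.random() < 0.5 else "-",
        inclusion_segments=inc,
        exclusion_segments=exc,
        cds=((s, span_end),) if coding else tuple(),
    )
    event.region_class, event.frame_class = classify_event_effect(event, event.cds)
    return event, span_end


def generate_catalog(config: SimConfig) -> EventCatalog:
    """Non-overlapping events of all five types on toy chromosomes."""
    rng = _rng(config, "catalog")
    if config.n_events == 0:
        warnings.warn("zero events requested; returning an empty catalog",
                      stacklevel=2)
        return EventCatalog([])
    types = rng.choice(len(AS_TYPES), size=config.n_events, p=config.type_mix)
    events: list[EventModel] = []
    cursor, chrom_i = 300, 1
    for i, ti in enumerate(types):
        if i and i % config.events_per_chromosome == 0:
            chrom_i += 1
            cursor = 300
        event, span_end = _build_event(
            AS_TYPES[ti], f"ev{i + 1:06d}", f"chr{chrom_i}",
            "+", cursor, rng, config,
        )
        events.append(event)
        # gap keeps events (and their 100 nt flanks) disjoint
        cursor = span_end + int(rng.integers(500, 1000))
    logger.info("generated catalog: %d events on %d chromosomes",
                len(events), chrom_i)
    return EventCatalog(events)


# ---------------------------------------------------------------------------
# truth


def _effect_sizes(rng, dist, size):
    kind = dist[0]
    if kind == "fixed":
        mag = np.full(size, float(dist[1]))
    elif kind == "uniform":
        mag = rng.uniform(float(dist[1]), float(dist[2]), size=size)
    elif kind == "beta":
        mag = rng.beta(float(dist[1]), float(dist[2]), size=size)
    else:
        raise ValueError(f"unknown effect size distribution {kind!r}")
    sign = rng.choice([-1.0, 1.0], size=size)
    return mag * sign


def generate_truth(catalog: EventCatalog, config: SimConfig) -> pd.DataFrame:
    """Ground-truth PSI architecture for every catalog event.

    Allelic ΔPSI equals δ_cis and parental ΔPSI equals δ_cis + δ_trans
    (both before clipping to [0.01, 0.99]); conserved events have identical
    PSI in all four contexts.
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    rng = _rng(config, "truth")
    n = len(catalog)
    p_cons = 1.0 - config.frac_cis - config.frac_trans - config.frac_both
    arch = rng.choice(
        ARCHITECTURES, size=n,
        p=[p_cons, config.frac_cis, config.frac_trans, config.frac_both],
    )
    base = rng.uniform(*config.psi_base_range, size=n)
    d_cis = np.where(
        np.isin(arch, ["cis", "cis+trans"]),
        _effect_sizes(rng, config.effect_size_dist, n), 0.0,
    )
    d_trans = np.where(
        np.isin(arch, ["trans", "cis+trans"]),
        _effect_sizes(rng, config.effect_size_dist, n), 0.0,
    )
    clip = lambda v: np.clip(v, 0.01, 0.99)
    truth = pd.DataFrame(
        {
            "event_id": [ev.event_id for ev in catalog],
            "architecture": arch,
            "psi_base": base,
            "delta_cis": d_cis,
            "delta_trans": d_trans,
            "psi_parent_B": clip(base + (d_cis + d_trans) / 2.0),
            "psi_parent_S": clip(base - (d_cis + d_trans) / 2.0),
            "psi_allele_B": clip(base + d_cis / 2.0),
            "psi_allele_S": clip(base - d_cis / 2.0),
        }
    )
    return truth


# ---------------------------------------------------------------------------
# counts


def _nb_totals(rng, mean, dispersion, size):
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def sample_counts(
    truth: pd.DataFrame, config: SimConfig, catalog: EventCatalog | None = None
) -> pd.DataFrame:
    """Per-replicate inclusion/exclusion read counts for parents and hybrid.

    Parents are emitted as unsplit totals (allele 'pooled'); the hybrid's
    total depth (``depth_mean * hybrid_depth_factor``) is thinned by
    ``assignability`` and split evenly between the alleles before the
    binomial read-type draw with the informativeness-corrected inclusion
    probability.
    """
    if config.depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    rng = _rng(config, "counts")
    n = len(truth)
    c_inc = np.ones(n)
    c_exc = np.ones(n)
    if catalog is not None:
        c_inc = np.array([catalog[e].c_inclusion for e in truth["event_id"]])
        c_exc = np.array([catalog[e].c_exclusion for e in truth["event_id"]])

    def q(psi):
        return inclusion_probability(psi.to_numpy(), 1.0, 1.0) if np.all(
            (c_inc == 1) & (c_exc == 1)
        ) else psi.to_numpy() * c_inc / (
            psi.to_numpy() * c_inc + (1 - psi.to_numpy()) * c_exc
        )

    frames = []
    for rep in range(1, config.n_replicates + 1):
        for sample, col in (("parent_B", "psi_parent_B"),
                            ("parent_S", "psi_parent_S")):
            tot = _nb_totals(rng, config.depth_mean, config.depth_dispersion, n)
            inc = rng.binomial(tot, q(truth[col]))
            frames.append(pd.DataFrame({
                "event_id": truth["event_id"], "sample": sample,
                "replicate": rep, "allele": "pooled",
                "n_inclusion": inc, "n_exclusion": tot - inc,
            }))
        hyb_tot = _nb_totals(
            rng, config.depth_mean * config.hybrid_depth_factor,
            config.depth_dispersion, n,
        )
        assignable = rng.binomial(hyb_tot, config.assignability)
        n_b = rng.binomial(assignable, 0.5)
        n_s = assignable - n_b
        for allele, tot, col in (("B", n_b, "psi_allele_B"),
                                 ("S", n_s, "psi_allele_S")):
            inc = rng.binomial(tot, q(truth[col]))
            frames.append(pd.DataFrame({
                "event_id": truth["event_id"], "sample": "hybrid",
                "replicate": rep, "allele": allele,
                "n_inclusion": inc, "n_exclusion": tot - inc,
            }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# variants

_BASES = np.array(list("ACGT"))


def _sample_positions(rng, intervals, rate):
    """Positions drawn per-nt Bernoulli(rate) within half-open intervals."""
    pos = []
    for s, e in intervals:
        k = rng.binomial(e - s, rate)
        if k:
            pos.extend(rng.choice(np.arange(s, e), size=k, replace=False))
    return pos


def generate_variants(
    catalog: EventCatalog, truth: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """SNV/indel table with elevated density in cis-divergent flanks.

    Background variants are placed uniformly genome-wide; flanking regions
    of cis-architecture events are topped up to ``variant_rate_cis_flank``;
    a ``splice_site_variant_frac`` fraction of cis events receives one SNV
    inside a randomly chosen splice-site window.  Indel reference spans
    never cross a segment boundary (such draws become SNVs), so isoform
    sequences stay well defined on both haplotypes.
    """
    rng = _rng(config, "variants")
    arch = truth.set_index("event_id")["architecture"]
    cis_ids = {e for e, a in arch.items() if a in ("cis", "cis+trans")}

    cis_flanks: dict[str, list] = {}
    for ev in catalog:
        if ev.event_id in cis_ids:
            regs = flanking_regions(ev).intervals
            cis_flanks.setdefault(ev.chromosome, []).extend(regs)
    cis_flanks = {c: merge_intervals(v) for c, v in cis_flanks.items()}

    extents = catalog.chromosome_extents()
    boundaries: dict[str, set[int]] = {}
    for ev in catalog:
        bset = boundaries.setdefault(ev.chromosome, set())
        for s, e in ev.inclusion_segments + ev.exclusion_segments:
            bset.update((s, e))

    rows = []
    taken: dict[str, set[int]] = {}

    def _bases(k):
        return "".join(rng.choice(_BASES, size=k))

    def _add(chrom, pos, force_snv=False):
        occupied = taken.setdefault(chrom, set())
        if any((pos + d) in occupied for d in range(-config.max_indel - 1,
                                                    config.max_indel + 2)):
            return
        occupied.add(pos)
        if not force_snv and rng.random() < config.indel_frac:
            k = int(rng.integers(1, config.max_indel + 1))
            if rng.random() < 0.5:  # deletion of k nt after the anchor
                span = range(pos, pos + k + 1)
                if not any(b in boundaries.get(chrom, ()) for b in span):
                    ref = _bases(k + 1)
                    rows.append((chrom, pos, ref, ref[0], "deletion"))
                    return
            else:  # insertion of k nt after the anchor
                ref = _bases(1)
                rows.append((chrom, pos, ref, ref + _bases(k), "insertion"))
                return
        ref = _bases(1)
        alt = [b for b in "ACGT" if b != ref][int(rng.integers(0, 3))]
        rows.append((chrom, pos, ref, alt, "SNV"))

    for chrom, extent in extents.items():
        length = extent + 300
        flank_iv = cis_flanks.get(chrom, [])
        background_iv = _complement(flank_iv, length)
        for pos in _sample_positions(rng, background_iv,
                                     config.variant_rate_background):
            _add(chrom, int(pos))
        for pos in _sample_positions(rng, flank_iv,
                                     config.variant_rate_cis_flank):
            _add(chrom, int(pos))

    # guaranteed splice-site SNVs for a fraction of cis events
    for ev in catalog:
        if ev.event_id in cis_ids and rng.random() < config.splice_site_variant_frac:
            windows = splice_site_windows(ev)
            s, e = windows[rng.integers(0, len(windows))]
            _add(ev.chromosome, int(rng.integers(s, e)), force_snv=True)

    if not rows:
        return pd.DataFrame(
            columns=["chromosome", "position", "ref", "alt", "vclass"]
        )
    out = pd.DataFrame(
        rows, columns=["chromosome", "position", "ref", "alt", "vclass"]
    ).sort_values(["chromosome", "position"], ignore_index=True)
    return out


def _complement(intervals, length):
    out, prev = [], 0
    for s, e in merge_intervals(intervals):
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        out.append((prev, length))
    return out


# ---------------------------------------------------------------------------
# reads


def _random_sequence(rng, length):
    return "".join(rng.choice(_BASES, size=length))


def _apply_variants(seq: str, variants: pd.DataFrame):
    """Embed ref alleles in the reference haplotype and build the alternate.

    Returns (ref sequence with ref alleles written in, alt sequence,
    variant-boundary positions, cumulative B->S shifts).
    """
    ref_pieces, alt_pieces = [], []
    positions, shifts = [0], [0]
    prev, shift = 0, 0
    for v in variants.itertuples(index=False):
        pos, ref, alt = int(v.position), str(v.ref), str(v.alt)
        ref_pieces.append(seq[prev:pos])
        ref_pieces.append(ref)
        alt_pieces.append(seq[prev:pos])
        alt_pieces.append(alt)
        prev = pos + len(ref)
        shift += len(alt) - len(ref)
        positions.append(prev)
        shifts.append(shift)
    ref_pieces.append(seq[prev:])
    alt_pieces.append(seq[prev:])
    return "".join(ref_pieces), "".join(alt_pieces), np.array(positions), np.array(shifts)


def _shift_coord(pos, positions, shifts):
    i = np.searchsorted(positions, pos, side="right") - 1
    return int(pos + shifts[i])


def emit_reads(
    catalog: EventCatalog,
    truth: pd.DataFrame,
    variants: pd.DataFrame,
    config: SimConfig,
):
    """Haplotype sequences and truth-labelled reads from isoform transcripts.

    Returns (hap_B, hap_S, reads): chromosome -> sequence dicts for both
    haplotypes and a read table with true allele/isoform labels and origin
    intervals on both haplotypes.  The reference haplotype carries the
    variant table's ref alleles; the alternate carries the alt alleles.

    Reads are drawn from the isoform transcripts of their generating allele
    at the allele's true hybrid PSI, error-free unless ``sequencing_error``
    > 0.  Each read lies within a single isoform segment (guaranteed to fit
    by the read-length precondition), so its genomic footprint is
    contiguous and edit-distance assignment needs no spliced alignment.
    Segments are sampled proportionally to the number of start positions
    they offer.
    """
    rng = _rng(config, "reads")
    extents = catalog.chromosome_extents()
    hap_b: dict[str, str] = {}
    hap_s: dict[str, str] = {}
    shift_tables: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, extent in extents.items():
        seq = _random_sequence(rng, extent + 300)
        sub = variants[variants["chromosome"] == chrom]
        if len(sub) and np.any(
            sub["position"].to_numpy() + sub["ref"].str.len().to_numpy()
            > len(seq)
        ):
            raise ValueError(f"variant outside sequence bounds on {chrom}")
        ref_seq, alt_seq, positions, shifts = _apply_variants(seq, sub)
        hap_b[chrom], hap_s[chrom] = ref_seq, alt_seq
        shift_tables[chrom] = (positions, shifts)

    tr = truth.set_index("event_id")
    min_seg = min(
        e - s
        for ev in catalog
        for s, e in ev.inclusion_segments + ev.exclusion_segments
    )
    if config.read_length >= min_seg:
        raise ValueError(
            f"read_length {config.read_length} must be shorter than the "
            f"shortest isoform segment ({min_seg} nt)"
        )

    read_rows = []
    for ev in catalog:
        chrom = ev.chromosome
        positions, shifts = shift_tables[chrom]
        for allele, psi_col, hap in (("B", "psi_allele_B", hap_b),
                                     ("S", "psi_allele_S", hap_s)):
            psi = float(tr.loc[ev.event_id, psi_col])

            def genomic_segments(segs):
                if allele == "B":
                    return [(s, e) for s, e in segs]
                return [
                    (_shift_coord(s, positions, shifts),
                     _shift_coord(e, positions, shifts))
                    for s, e in segs
                ]

            iso_segs = {
                "inclusion": genomic_segments(ev.inclusion_segments),
                "exclusion": genomic_segments(ev.exclusion_segments),
            }
            n_reads = config.reads_per_event
            take_inc = rng.binomial(n_reads, psi)
            for iso, count in (("inclusion", take_inc),
                               ("exclusion", n_reads - take_inc)):
                segs = iso_segs[iso]
                if count == 0:
                    continue
                # one segment per read, weighted by available start positions
                n_starts = np.array(
                    [e - s - config.read_length + 1 for s, e in segs]
                )
                seg_idx = rng.choice(
                    len(segs), size=count, p=n_starts / n_starts.sum()
                )
                for j, si in enumerate(seg_idx):
                    seg_s, seg_e = segs[si]
                    g_lo = int(rng.integers(seg_s,
                                            seg_e - config.read_length + 1))
                    g_hi = g_lo + config.read_length
                    read = hap[chrom][g_lo:g_hi]
                    if config.sequencing_error > 0:
                        read = _mutate(read, config.sequencing_error, rng)
                    if allele == "B":
                        b_lo, b_hi = g_lo, g_hi
                        s_lo = _shift_coord(g_lo, positions, shifts)
                        s_hi = _shift_coord(g_hi, positions, shifts)
                    else:
                        s_lo, s_hi = g_lo, g_hi
                        b_lo = _unshift_coord(g_lo, positions, shifts)
                        b_hi = _unshift_coord(g_hi, positions, shifts)
                    read_rows.append((
                        f"{ev.event_id}:{allele}:{iso}:{j}", read, chrom,
                        b_lo, b_hi, s_lo, s_hi, allele, iso, ev.event_id,
                    ))
    reads = pd.DataFrame(
        read_rows,
        columns=["read_id", "sequence", "chromosome", "start_B", "end_B",
                 "start_S", "end_S", "true_allele", "isoform", "event_id"],
    )
    return hap_b, hap_s, reads


def _unshift_coord(pos_s, positions, shifts):
    # invert the piecewise-constant B->S shift (monotone)
    s_positions = positions + shifts
    i = np.searchsorted(s_positions, pos_s, side="right") - 1
    return int(pos_s - shifts[i])


def _mutate(read: str, rate: float, rng) -> str:
    arr = np.array(list(read))
    hits = rng.random(arr.size) < rate
    for i in np.flatnonzero(hits):
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    return "".join(arr)


# ---------------------------------------------------------------------------


def simulate_dataset(config: SimConfig, with_reads: bool = False) -> dict:
    """One-call generation of catalog, truth, counts, variants (and reads)."""
    catalog = generate_catalog(config)
    truth = generate_truth(catalog, config)
    counts = sample_counts(truth, config, catalog)
    variants = generate_variants(catalog, truth, config)
    bundle = {
        "config": config, "catalog": catalog, "truth": truth,
        "counts": counts, "variants": variants,
    }
    if with_reads:
        hap_b, hap_s, reads = emit_reads(catalog, truth, variants, config)
        bundle.update(haplotype_B=hap_b, haplotype_S=hap_s, reads=reads)
    return bundle
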