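"""Synthetic-data generator: determinism, ground-truth structure, noise model."""

import numpy as np
import pandas as pd
import pytest

from splicedissect.events import AS_TYPES
from splicedissect.features import compare_groups, flanking_regions
from splicedissect.simulate import (
    SimConfig,
    generate_catalog,
    generate_truth,
    generate_variants,
    sample_counts,
    simulate_dataset,
)


class TestConfig:
    def test_defaults_valid(self):
        SimConfig().validate()

    @pytest.mark.parametrize(
        "kw",
        [
            {"type_mix": (0.5, 0.5, 0.0, 0.0, 0.1)},
            {"depth_mean": 0.0},
            {"assignability": 0.0},
            {"assignability": 1.5},
            {"variant_rate_background": 1.5},
            {"frac_cis": 0.8, "frac_trans": 0.5},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw)

    def test_cast_preset(self):
        assert SimConfig().with_cast_preset().assignability == 0.3

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "sim.yaml"
        path.write_text("n_events: 7\nseed: 3\ntype_mix: [1, 0, 0, 0, 0]\n")
        cfg = SimConfig.from_yaml(path)
        assert cfg.n_events == 7 and cfg.type_mix == (1, 0, 0, 0, 0)


class TestCatalog:
    def test_seeded_determinism(self):
        cfg = SimConfig(n_events=100, seed=1)
        a = generate_catalog(cfg)
        b = generate_catalog(cfg)
        assert [
            (e.event_id, e.as_type, e.chromosome, e.strand,
             e.inclusion_segments, e.exclusion_segments, e.cds)
            for e in a
        ] == [
            (e.event_id, e.as_type, e.chromosome, e.strand,
             e.inclusion_segments, e.exclusion_segments, e.cds)
            for e in b
        ]

    def test_pure_type_mix(self):
        cfg = SimConfig(n_events=50, type_mix=(1, 0, 0, 0, 0), seed=2)
        assert all(ev.as_type == "SE" for ev in generate_catalog(cfg))

    def test_type_counts_within_binomial_bounds(self):
        n = 10_000
        cfg = SimConfig(n_events=n, seed=4)
        counts = pd.Series(
            [ev.as_type for ev in generate_catalog(cfg)]
        ).value_counts()
        for as_type, p in zip(AS_TYPES, cfg.type_mix):
            sd = np.sqrt(n * p * (1 - p))
            assert abs(counts[as_type] - n * p) <= 3 * sd

    def test_zero_events_warns_and_is_empty(self):
        with pytest.warns(UserWarning):
            catalog = generate_catalog(SimConfig(n_events=0, seed=1))
        assert len(catalog) == 0

    def test_events_do_not_overlap(self, small_bundle):
        by_chrom = {}
        for ev in small_bundle["catalog"]:
            by_chrom.setdefault(ev.chromosome, []).append(ev.span)
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans[:-1], spans[1:]):
                assert e1 <= s2


class TestTruth:
    def test_no_cis_means_equal_allelic_psi(self):
        cfg = SimConfig(n_events=200, frac_cis=0.0, frac_both=0.0, seed=6)
        catalog = generate_catalog(cfg)
        truth = generate_truth(catalog, cfg)
        assert (truth["delta_cis"] == 0).all()
        assert np.allclose(truth["psi_allele_B"], truth["psi_allele_S"])

    def test_symmetric_split_around_base(self):
        cfg = SimConfig(
            n_events=50, frac_cis=1.0, frac_trans=0.0, seed=6,
            psi_base_range=(0.5, 0.5), effect_size_dist=("fixed", 0.3),
        )
        truth = generate_truth(generate_catalog(cfg), cfg)
        assert set(np.round(truth["psi_allele_B"], 10)) <= {0.65, 0.35}
        assert np.allclose(
            truth["psi_allele_B"] - truth["psi_allele_S"], truth["delta_cis"]
        )

    def test_deltas_consistent_away_from_clipping(self, small_bundle):
        truth = small_bundle["truth"]
        # events whose base PSI leaves room for the +-0.15 split
        mid = truth[(truth["psi_base"] > 0.25) & (truth["psi_base"] < 0.75)]
        assert np.allclose(
            mid["psi_allele_B"] - mid["psi_allele_S"], mid["delta_cis"]
        )
        assert np.allclose(
            mid["psi_parent_B"] - mid["psi_parent_S"],
            mid["delta_cis"] + mid["delta_trans"],
        )

    def test_conserved_events_identical_everywhere(self, small_bundle):
        truth = small_bundle["truth"]
        cons = truth[truth["architecture"] == "conserved"]
        for col in ("psi_parent_B", "psi_parent_S", "psi_allele_B",
                    "psi_allele_S"):
            assert np.allclose(cons[col], cons["psi_base"])

    def test_effect_size_moments(self):
        cfg = SimConfig(
            n_events=5000, frac_cis=1.0, frac_trans=0.0, seed=8,
            effect_size_dist=("uniform", 0.1, 0.5),
        )
        truth = generate_truth(generate_catalog(cfg), cfg)
        mags = truth["delta_cis"].abs()
        se = mags.std() / np.sqrt(len(mags))
        assert abs(mags.mean() - 0.3) <= 3 * se

    def test_empty_catalog_rejected(self):
        from splicedissect.events import EventCatalog

        with pytest.raises(ValueError):
            generate_truth(EventCatalog([]), SimConfig(seed=1))


class TestCounts:
    def test_full_inclusion_gives_zero_exclusion(self):
        cfg = SimConfig(n_events=5, seed=9)
        truth = pd.DataFrame(
            {
                "event_id": [f"ev{i}" for i in range(5)],
                "psi_parent_B": 1.0, "psi_parent_S": 1.0,
                "psi_allele_B": 1.0, "psi_allele_S": 1.0,
            }
        )
        counts = sample_counts(truth, cfg)
        assert (counts["n_exclusion"] == 0).all()

    def test_assignability_thinning_expectation(self):
        cfg = SimConfig(
            n_events=400, seed=10, assignability=0.5, depth_mean=200,
            hybrid_depth_factor=1.0, n_replicates=3,
        )
        truth = generate_truth(generate_catalog(cfg), cfg)
        counts = sample_counts(truth, cfg)
        hyb = counts[counts["sample"] == "hybrid"]
        per_rep = hyb.groupby(["event_id", "replicate"])[
            ["n_inclusion", "n_exclusion"]
        ].sum().sum(axis=1)
        # var of NB-thinned total ~ mean + mean^2/disp; conservative SE bound
        se = per_rep.std() / np.sqrt(len(per_rep))
        assert abs(per_rep.mean() - 100.0) <= 3 * se

    def test_seeded_determinism(self):
        cfg = SimConfig(n_events=50, seed=12)
        truth = generate_truth(generate_catalog(cfg), cfg)
        assert sample_counts(truth, cfg).equals(sample_counts(truth, cfg))

    def test_pooled_empirical_psi_converges(self):
        cfg = SimConfig(n_events=100, seed=13, depth_mean=3500,
                        n_replicates=3, hybrid_depth_factor=1.0)
        truth = generate_truth(generate_catalog(cfg), cfg)
        counts = sample_counts(truth, cfg)
        pooled = counts[counts["sample"] == "parent_B"].groupby("event_id")[
            ["n_inclusion", "n_exclusion"]
        ].sum()
        emp = pooled["n_inclusion"] / pooled.sum(axis=1)
        true = truth.set_index("event_id")["psi_parent_B"].loc[emp.index]
        assert (emp - true).abs().max() < 0.02


class TestVariants:
    def test_zero_rates_empty_table(self):
        cfg = SimConfig(
            n_events=30, seed=14, variant_rate_background=0.0,
            variant_rate_cis_flank=0.0, splice_site_variant_frac=0.0,
        )
        catalog = generate_catalog(cfg)
        truth = generate_truth(catalog, cfg)
        assert len(generate_variants(catalog, truth, cfg)) == 0

    def test_determinism(self, small_bundle):
        cfg = small_bundle["config"]
        again = generate_variants(
            small_bundle["catalog"], small_bundle["truth"], cfg
        )
        assert again.equals(small_bundle["variants"])

    def test_elevated_cis_flank_density_detectable(self):
        cfg = SimConfig(
            n_events=500, seed=15, variant_rate_background=0.003,
            variant_rate_cis_flank=0.03, indel_frac=0.0,
        )
        catalog = generate_catalog(cfg)
        truth = generate_truth(catalog, cfg)
        variants = generate_variants(catalog, truth, cfg)
        p = _flank_density_pvalue(catalog, truth, variants)
        assert p < 0.01

    def test_equal_rates_calibrated_null(self):
        # with no density contrast the comparison should rarely reject
        rejections = 0
        n_runs = 60
        for seed in range(n_runs):
            cfg = SimConfig(
                n_events=150, seed=1000 + seed, variant_rate_background=0.01,
                variant_rate_cis_flank=0.01, splice_site_variant_frac=0.0,
                indel_frac=0.0,
            )
            catalog = generate_catalog(cfg)
            truth = generate_truth(catalog, cfg)
            variants = generate_variants(catalog, truth, cfg)
            if _flank_density_pvalue(catalog, truth, variants) < 0.05:
                rejections += 1
        assert rejections / n_runs <= 0.10


def _flank_density_pvalue(catalog, truth, variants):
    from splicedissect.features import variant_density

    arch = truth.set_index("event_id")["architecture"]
    dens = {"cis": [], "conserved": []}
    for ev in catalog:
        a = arch[ev.event_id]
        if a not in ("cis", "conserved"):
            continue
        sub = variants[variants["chromosome"] == ev.chromosome]
        dens[a].append(variant_density(flanking_regions(ev), sub))
    return compare_groups(dens["cis"], dens["conserved"])


class TestReads:
    def test_read_table_structure(self, read_bundle):
        reads = read_bundle["reads"]
        assert (reads["end_B"] - reads["start_B"] >= 80).all()
        assert set(reads["true_allele"]) == {"B", "S"}

    def test_reads_match_their_haplotype_exactly(self, read_bundle):
        hap = {"B": read_bundle["haplotype_B"], "S": read_bundle["haplotype_S"]}
        for r in read_bundle["reads"].sample(200, random_state=0).itertuples():
            seq = hap[r.true_allele][r.chromosome]
            lo = r.start_S if r.true_allele == "S" else r.start_B
            assert seq[lo: lo + len(r.sequence)] == r.sequence

    def test_no_variants_means_identical_haplotypes(self):
        cfg = SimConfig(
            n_events=10, seed=16, variant_rate_background=0.0,
            variant_rate_cis_flank=0.0, splice_site_variant_frac=0.0,
        )
        bundle = simulate_dataset(cfg, with_reads=True)
        assert bundle["haplotype_B"] == bundle["haplotype_S"]

    def test_variant_coverage_fraction_matches_enumeration(self, read_bundle):
        """Reads overlapping >=1 variant at the enumerated per-base rate."""
        reads = read_bundle["reads"]
        variants = read_bundle["variants"]
        pos_by_chrom = {
            c: np.sort(g["position"].to_numpy())
            for c, g in variants.groupby("chromosome")
        }
        # observed fraction (on the generating haplotype's coordinates)
        def overlaps(row):
            pos = pos_by_chrom.get(row.chromosome)
            if pos is None:
                return False
            lo, hi = row.start_B, row.end_B
            i = np.searchsorted(pos, lo)
            return bool(i < len(pos) and pos[i] < hi)

        hit = np.array([overlaps(r) for r in reads.itertuples()])
        # expectation: average over events of the exact probability that a
        # uniformly placed segment-read covers a variant position
        assert 0.05 < hit.mean() < 0.95
        se = np.sqrt(hit.mean() * (1 - hit.mean()) / len(hit))
        expected = _expected_overlap_fraction(read_bundle)
        assert abs(hit.mean() - expected) <= 4 * se

    def test_read_length_precondition(self):
        with pytest.raises(ValueError):
            cfg = SimConfig(n_events=5, seed=17, read_length=120,
                            exon_length_range=(100, 119))
            simulate_dataset(cfg, with_reads=True)


def _expected_overlap_fraction(bundle):
    """Enumeration oracle for the fraction of reads covering a variant."""
    cfg = bundle["config"]
    L = cfg.read_length
    variants = bundle["variants"]
    pos_by_chrom = {
        c: np.sort(g["position"].to_numpy())
        for c, g in variants.groupby("chromosome")
    }
    truth = bundle["truth"].set_index("event_id")
    probs = []
    for ev in bundle["catalog"]:
        pos = pos_by_chrom.get(ev.chromosome, np.array([]))
        psi = float(
            (truth.loc[ev.event_id, "psi_allele_B"]
             + truth.loc[ev.event_id, "psi_allele_S"]) / 2.0
        )
        iso_p = []
        for segs in (ev.inclusion_segments, ev.exclusion_segments):
            n_starts = np.array([e - s - L + 1 for s, e in segs])
            p_hit = []
            for s, e in segs:
                starts = np.arange(s, e - L + 1)
                i = np.searchsorted(pos, starts)
                hit = (i < len(pos)) & (np.take(pos, np.minimum(i, len(pos) - 1))
                                        < starts + L)
                p_hit.append(hit.mean())
            iso_p.append(np.average(p_hit, weights=n_starts))
        probs.append(psi * iso_p[0] + (1 - psi) * iso_p[1])
    return float(np.mean(probs))


class TestBundleDeterminism:
    def test_two_runs_identical(self):
        cfg = SimConfig(n_events=60, seed=18)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert a["counts"].equals(b["counts"])
        assert a["truth"].equals(b["truth"])
        assert a["variants"].equals(b["variants"])
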