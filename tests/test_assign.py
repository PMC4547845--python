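"""Edit-distance allele assignment and the mock/downsampling constructions."""

import numpy as np
import pandas as pd
import pytest

from splicedissect.assign import (
    assign_read,
    assign_reads,
    build_mock_f1_counts,
    build_mock_f1_reads,
    downsample_parental,
    infix_distance,
    levenshtein,
)


from dp_oracles import dp_infix, dp_levenshtein


class TestDistances:
    def test_levenshtein_against_dp_oracle(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        for _ in range(60):
            a = "".join(rng.choice(bases, size=rng.integers(1, 40)))
            b = "".join(rng.choice(bases, size=rng.integers(1, 40)))
            assert levenshtein(a, b) == dp_levenshtein(a, b)

    def test_infix_against_dp_oracle(self):
        rng = np.random.default_rng(8)
        bases = np.array(list("ACGT"))
        for _ in range(60):
            locus = "".join(rng.choice(bases, size=rng.integers(30, 80)))
            read = "".join(rng.choice(bases, size=rng.integers(10, 25)))
            assert infix_distance(read, locus) == dp_infix(read, locus)

    def test_exact_substring_distance_zero(self):
        locus = "ACGTACGTACGTACGT"
        assert infix_distance("GTACGT", locus) == 0

    def test_n_matches_nothing(self):
        assert levenshtein("N", "N") == 1
        assert levenshtein("AN", "AN") == 1
        assert levenshtein("AN", "AC") == 1

    def test_invalid_bases_rejected(self):
        with pytest.raises(ValueError):
            levenshtein("AXG", "ACG")


class TestAssignRead:
    def test_substring_of_b_wins(self):
        locus_b = "AAACCCGGGTTTAAA"
        locus_s = "AAACCCGAGTTTAAA"  # one mismatch inside
        a = assign_read("CCCGGGTTT", locus_b, locus_s)
        assert a.allele == "B"
        assert (a.edit_distance_B, a.edit_distance_S) == (0, 1)

    def test_no_variant_overlap_is_unassigned(self):
        locus = "AAACCCGGGTTTAAA"
        a = assign_read("CCCGGGTTT", locus, locus)
        assert a.allele == "unassigned"
        assert a.edit_distance_B == a.edit_distance_S

    def test_nine_nt_insertion_assigns_to_s(self):
        # T-free locus + poly-T insert: every inserted base must cost an edit
        left, right = "ACGGCAGGAC", "CAGCCGGAAC"
        ins = "T" * 9
        locus_b = "GGCCAA" + left + right + "AACCGG"
        locus_s = "GGCCAA" + left + ins + right + "AACCGG"
        read = left + ins + right  # spans the insertion, drawn from S
        a = assign_read(read, locus_b, locus_s)
        assert a.allele == "S"
        assert a.edit_distance_S == 0
        assert a.edit_distance_B == dp_infix(read, locus_b) == 9

    def test_swap_symmetry(self):
        locus_b = "AAACCCGGGTTTAAA"
        locus_s = "AAACCCGAGTTTAAA"
        fwd = assign_read("CCCGGGTTT", locus_b, locus_s)
        rev = assign_read("CCCGGGTTT", locus_s, locus_b)
        assert (fwd.allele, rev.allele) == ("B", "S")
        assert fwd.edit_distance_B == rev.edit_distance_S

    def test_empty_read_rejected(self):
        with pytest.raises(ValueError):
            assign_read("", "ACGT", "ACGT")


class TestAssignReadsTable:
    def test_zero_error_truth_recovery(self, read_bundle):
        report = assign_reads(
            read_bundle["reads"], read_bundle["haplotype_B"],
            read_bundle["haplotype_S"],
        )
        merged = report.merge(
            read_bundle["reads"][["read_id", "true_allele"]], on="read_id"
        )
        assigned = merged[merged["allele"] != "unassigned"]
        # misassignment is exactly zero without sequencing error
        assert (assigned["allele"] == assigned["true_allele"]).all()
        # every read matches its own haplotype exactly
        assert (assigned[["dist_B", "dist_S"]].min(axis=1) == 0).all()
        # unassigned reads are exactly the ones without variant overlap
        unassigned = merged[merged["allele"] == "unassigned"]
        assert ((unassigned["dist_B"] == 0) & (unassigned["dist_S"] == 0)).all()


class TestMockF1:
    def test_equal_amounts_read_level(self):
        reads_b = pd.DataFrame({"read_id": [f"b{i}" for i in range(1000)]})
        reads_s = pd.DataFrame({"read_id": [f"s{i}" for i in range(4000)]})
        mock = build_mock_f1_reads(reads_b, reads_s, seed=1)
        assert len(mock) == 2000
        assert mock["read_id"].str.startswith("b").sum() == 1000

    def test_full_assignability_preserves_parental_counts(self):
        counts = pd.DataFrame(
            {
                "event_id": ["e1"] * 2, "sample": ["parent_B", "parent_S"],
                "replicate": [1, 1], "allele": ["pooled"] * 2,
                "n_inclusion": [30, 30], "n_exclusion": [10, 10],
            }
        )
        mock = build_mock_f1_counts(counts, 1.0, seed=2)
        for allele, parent_inc in (("B", 30), ("S", 30)):
            rec = mock[mock["allele"] == allele].iloc[0]
            assert rec["n_inclusion"] == parent_inc
            assert rec["n_exclusion"] == 10

    def test_mixing_downsamples_larger_parent(self):
        counts = pd.DataFrame(
            {
                "event_id": ["e1"] * 2, "sample": ["parent_B", "parent_S"],
                "replicate": [1, 1], "allele": ["pooled"] * 2,
                "n_inclusion": [400, 40], "n_exclusion": [100, 10],
            }
        )
        mock = build_mock_f1_counts(counts, 1.0, seed=3)
        totals = mock.groupby("allele")[["n_inclusion", "n_exclusion"]].sum().sum(axis=1)
        assert (totals == 50).all()

    def test_replicate_mismatch_rejected(self):
        counts = pd.DataFrame(
            {
                "event_id": ["e1", "e1", "e1"],
                "sample": ["parent_B", "parent_B", "parent_S"],
                "replicate": [1, 2, 1], "allele": ["pooled"] * 3,
                "n_inclusion": [5, 5, 5], "n_exclusion": [5, 5, 5],
            }
        )
        with pytest.raises(ValueError):
            build_mock_f1_counts(counts, 0.5, seed=4)


def _parental_frame(inc, exc, n_events=1, reps=(1,)):
    rows = []
    for i in range(n_events):
        for rep in reps:
            for sample in ("parent_B", "parent_S"):
                rows.append((f"e{i}", sample, rep, "pooled", inc, exc))
    return pd.DataFrame(
        rows, columns=["event_id", "sample", "replicate", "allele",
                       "n_inclusion", "n_exclusion"],
    )


def _mock_frame(total, n_events=1, reps=(1,)):
    rows = []
    for i in range(n_events):
        for rep in reps:
            for allele in ("B", "S"):
                rows.append((f"e{i}", "mock", rep, allele, total, 0))
    return pd.DataFrame(
        rows, columns=["event_id", "sample", "replicate", "allele",
                       "n_inclusion", "n_exclusion"],
    )


class TestDownsampleParental:
    def test_identity_at_full_coverage(self):
        par = _parental_frame(80, 20)
        mock = _mock_frame(100)
        down = downsample_parental(par, mock, seed=5)
        assert (down["n_inclusion"] == 80).all()
        assert (down["n_exclusion"] == 20).all()

    def test_hypergeometric_mean(self):
        par = _parental_frame(80, 20, n_events=5000)
        mock = _mock_frame(25, n_events=5000)
        down = downsample_parental(par, mock, seed=6)
        sub = down[down["allele"] == "B"]
        se = sub["n_inclusion"].std() / np.sqrt(len(sub))
        assert abs(sub["n_inclusion"].mean() - 20.0) <= 3 * se

    def test_zero_target_gives_empty_record(self):
        par = _parental_frame(80, 20)
        mock = _mock_frame(0)
        down = downsample_parental(par, mock, seed=7)
        assert (down[["n_inclusion", "n_exclusion"]] == 0).all().all()

    def test_excess_target_raises_with_event_name(self):
        par = _parental_frame(8, 2)
        mock = _mock_frame(100)
        with pytest.raises(ValueError, match="e0"):
            downsample_parental(par, mock, seed=8)


class TestMockPsiConcordance:
    def test_unbiased_mock_tracks_parental_psi(self):
        """Squared correlation of mock-allelic vs parental PSI >= 0.95."""
        from splicedissect.simulate import SimConfig, generate_catalog, \
            generate_truth, sample_counts

        cfg = SimConfig(n_events=500, seed=19, depth_mean=150)
        truth = generate_truth(generate_catalog(cfg), cfg)
        counts = sample_counts(truth, cfg)
        mock = build_mock_f1_counts(counts, 0.6, seed=20)
        for allele, parent in (("B", "parent_B"), ("S", "parent_S")):
            par = counts[counts["sample"] == parent].groupby("event_id")[
                ["n_inclusion", "n_exclusion"]
            ].sum()
            mk = mock[mock["allele"] == allele].groupby("event_id")[
                ["n_inclusion", "n_exclusion"]
            ].sum()
            psi_p = par["n_inclusion"] / par.sum(axis=1)
            psi_m = mk["n_inclusion"] / mk.sum(axis=1)
            r = np.corrcoef(psi_p, psi_m.loc[psi_p.index])[0, 1]
            assert r**2 >= 0.95
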