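"""Regulatory-element annotation: density profiles, nucleotide enrichment,
promoter element scanning, UTR statistics, U-richness and heptamer repeats."""

import numpy as np
import pytest

from tucall.element_annotator import (
    annotate_promoters,
    find_heptamer_repeats,
    iupac_incompatibilities,
    nucleotide_enrichment,
    read_density,
    sample_intergenic_background,
    u_richness,
    utr_statistics,
)
from tucall.genome_model import COVERAGE, EndProfile, GeneAnnotation, Genome
from tucall.tep_caller import TEPRecord
from tucall.tss_caller import TSSRecord


def coverage_profile(plus=None, minus=None, length=2000):
    return EndProfile.from_dicts("g", length, COVERAGE, "rnaseq", plus=plus, minus=minus)


class TestReadDensity:
    def test_constant_window_is_all_ones(self):
        prof = coverage_profile(plus={p: 5 for p in range(1, 2001)})
        dp = read_density([(1000, "+")], prof)
        assert np.allclose(dp.density, 1.0)

    def test_single_spike(self):
        prof = coverage_profile(plus={1000: 10})
        dp = read_density([(1000, "+")], prof)
        assert dp.at(0) == 1.0
        assert dp.density.sum() == 1.0

    def test_two_anchor_average(self):
        prof = coverage_profile(plus={1000: 10}, minus={520: 10})
        dp = read_density([(1000, "+"), (510, "-")], prof)
        # anchor 1: spike at offset 0; anchor 2 (minus strand): position 520
        # is 10 nt upstream of 510, so its spike lands at offset -10
        assert dp.at(0) == pytest.approx(0.5)
        assert dp.at(-10) == pytest.approx(0.5)
        assert dp.n_positions == 2

    def test_bounds_and_empty_window_skipped(self):
        prof = coverage_profile(plus={1000: 10})
        dp = read_density([(1000, "+"), (1900, "+")], prof)  # second window empty
        assert dp.n_positions == 1
        assert dp.density.min() >= 0.0 and dp.density.max() <= 1.0

    def test_empty_anchor_list_rejected(self):
        with pytest.raises(Exception):
            read_density([], coverage_profile())


class TestEnrichment:
    def test_ratio_against_background(self):
        # anchors all T at offset 0, background has A/C/G/T equally
        genome = Genome("g", "ACGT" * 300)
        anchors = [(p, "+") for p in range(100, 140) if genome.sequence[p - 1] == "T"]
        background = [(p, "+") for p in range(100, 300)]
        m = nucleotide_enrichment(anchors, genome, background, window=(0, 0))
        assert m.ratios.loc[0, "U"] == pytest.approx(4.0)

    def test_identity_when_anchors_equal_background(self):
        genome = Genome("g", "ACGT" * 300)
        pts = [(p, "+") for p in range(100, 200)]
        m = nucleotide_enrichment(pts, genome, pts, window=(-5, 5))
        np.testing.assert_allclose(m.ratios.to_numpy()[m.ratios.to_numpy() > 0], 1.0)

    def test_minus_strand_reverse_complement(self):
        genome = Genome("g", "A" * 200)
        m = nucleotide_enrichment(
            [(100, "-")], genome, [(110, "-")], window=(0, 0)
        )
        # A on the plus strand reads U on the minus-strand transcript
        assert m.ratios.loc[0, "U"] == pytest.approx(1.0)

    def test_zero_background_frequency_raises(self):
        genome = Genome("g", "A" * 100 + "C" * 100)
        with pytest.raises(Exception, match="background"):
            nucleotide_enrichment([(150, "+")], genome, [(50, "+")], window=(0, 0))


class TestBackgroundSampling:
    GENOME = Genome("g", "ACGT" * 500)

    def test_fully_genic_genome_errors(self):
        genes = [GeneAnnotation("g1", 1, 2000, "+")]
        with pytest.raises(Exception):
            sample_intergenic_background(genes, self.GENOME, 5, seed=0)

    def test_deterministic_under_seed(self):
        genes = [GeneAnnotation("g1", 1, 1000, "+")]
        a = sample_intergenic_background(genes, self.GENOME, 50, seed=3)
        b = sample_intergenic_background(genes, self.GENOME, 50, seed=3)
        assert a == b

    def test_all_positions_intergenic(self):
        genes = [GeneAnnotation("g1", 1, 1000, "+")]
        pts = sample_intergenic_background(genes, self.GENOME, 500, seed=1)
        assert all(p > 1000 for p, _ in pts)
        assert len({p for p, _ in pts}) == 500  # without replacement


class TestPromoters:
    # TTGACA at -40..-35, 19-nt spacer, TATAAT at -15..-10, then 9 nt to +1
    PROMOTER_40 = "TTGACA" + "G" * 19 + "TATAAT" + "C" * 9

    def test_constructed_promoter_and_spacer(self):
        genome = Genome("g", "A" * 60 + self.PROMOTER_40 + "A" + "C" * 60)
        tss_pos = 60 + len(self.PROMOTER_40) + 1
        a = annotate_promoters([TSSRecord(tss_pos, "+", 9, 0, "P")], genome)[0]
        assert a.minus10 == (-15, "TATAAT")
        assert a.minus35 == (-40, "TTGACA")
        assert a.spacer_length == 19

    def test_all_c_window_has_no_minus10(self):
        genome = Genome("g", "C" * 200)
        anns = annotate_promoters([TSSRecord(100, "+", 9, 0, "P")], genome)
        assert anns[0].minus10 is None

    def test_n_wildcards_match_anything(self):
        assert iupac_incompatibilities("TAGGGT", "TANNNT") == 0
        assert iupac_incompatibilities("CCCCCC", "TANNNT") == 3
        assert iupac_incompatibilities("TTGACA", "BTGACN") == 0

    def test_edge_tss_skipped_with_warning(self):
        genome = Genome("g", "A" * 100)
        with pytest.warns(UserWarning):
            anns = annotate_promoters([TSSRecord(5, "+", 9, 0, "P")], genome)
        assert anns == []

    def test_shift_equivariance(self):
        for pad in (0, 17):
            genome = Genome("g", "A" * (50 + pad) + self.PROMOTER_40 + "A" + "T" * 60)
            tss_pos = 50 + pad + len(self.PROMOTER_40) + 1
            a = annotate_promoters([TSSRecord(tss_pos, "+", 9, 0, "P")], genome)[0]
            assert a.minus10[0] == -15 and a.minus35[0] == -40
            assert a.spacer_length == 19


class TestUTRStats:
    def test_binning_and_flags(self):
        tss = [
            TSSRecord(1, "+", 9, 0, "P", "g1", 35, False),
            TSSRecord(2, "+", 9, 0, "P", "g2", 8, True),
            TSSRecord(3, "+", 9, 0, "P", "g3", 151, False),
            TSSRecord(4, "+", 9, 0, "S", "g1", 400, None),  # secondary: excluded
        ]
        teps = [TEPRecord(9, "+", 5, "P", "g1", 62)]
        stats = utr_statistics(tss, teps)
        h5 = stats["utr5_histogram"]
        assert int(h5.loc[h5["bin_start"] == 30, "count"].iloc[0]) == 1
        assert stats["n_leaderless"] == 1  # 8 < 9
        assert stats["n_long_leader"] == 1  # 151 > 150
        assert stats["n_primary_tss"] == 3
        h3 = stats["utr3_histogram"]
        assert int(h3.loc[h3["bin_start"] == 60, "count"].iloc[0]) == 1


class TestURichness:
    def test_u_count_threshold(self):
        genome = Genome("g", "A" * 92 + "TTCTTTGT" + "A" * 100)  # ends at pos 100
        [rec] = u_richness([TEPRecord(100, "+", 5)], genome)
        assert rec.u_rich is True
        genome = Genome("g", "A" * 92 + "GCGCGCGC" + "A" * 100)
        [rec] = u_richness([TEPRecord(100, "+", 5)], genome)
        assert rec.u_rich is False

    def test_minus_strand_window(self):
        # minus-strand transcript ending at 100 reads positions 100..107 revcomp
        genome = Genome("g", "G" * 99 + "AAAAAAAA" + "G" * 100)
        [rec] = u_richness([TEPRecord(100, "-", 5)], genome)
        assert rec.u_rich is True

    def test_planted_u_rich_teps_flagged(self, default_dataset):
        ds = default_dataset
        truth_flags = {
            (t.position, t.strand): t.u_rich for t in ds.truth.tep_truth
        }
        recs = [
            TEPRecord(t.position, t.strand, 10) for t in ds.truth.tep_truth
        ]
        flagged = u_richness(recs, ds.genome)
        planted = [r for r in flagged if truth_flags[(r.position, r.strand)]]
        assert planted, "generator should plant U-rich terminators"
        frac = sum(r.u_rich for r in planted) / len(planted)
        assert frac >= 0.9


class TestHeptamers:
    def build_genome(self, window):
        assert len(window) == 150
        return Genome("g", "G" * 50 + window + "A" * 50), 201  # TSS right after window

    def test_planted_repeat_with_4nt_spacing(self):
        window = ("TGAGCGA" + "ACGT" + "TGAGCGA").ljust(150, "C")
        genome, tss_pos = self.build_genome(window)
        sites = find_heptamer_repeats(
            [TSSRecord(tss_pos, "+", 9, 0, "P")], genome, "TGAGCGA"
        )
        assert any(s.spacing == 4 for s in sites)
        assert sites[0].heptamers == ("TGAGCGA", "TGAGCGA")

    def test_wrong_spacing_rejected(self):
        window = ("TGAGCGA" + "ACGTACGTAC" + "TGAGCGA").ljust(150, "C")
        genome, tss_pos = self.build_genome(window)
        sites = find_heptamer_repeats(
            [TSSRecord(tss_pos, "+", 9, 0, "P")], genome, "TGAGCGA"
        )
        assert sites == []

    def test_mismatch_bound(self):
        # second heptamer has 2 mismatches; max_mismatch=1 rejects the pair
        window = ("TGAGCGA" + "ACGT" + "TGAGAAA").ljust(150, "C")
        genome, tss_pos = self.build_genome(window)
        sites = find_heptamer_repeats(
            [TSSRecord(tss_pos, "+", 9, 0, "P")], genome, "TGAGCGA", max_mismatch=1
        )
        assert sites == []
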