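"""TEP calling: modified z-score, intergenic clustering, replicate
reconciliation and C/P/S/A/N classification."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tucall.genome_model import EndProfile, THREE_PRIME, GeneAnnotation
from tucall.tep_caller import (
    TEPCandidate,
    TEPRecord,
    call_teps_single_replicate,
    classify_tep,
    cluster_3prime_positions,
    modified_zscore,
    reconcile_replicates,
    span_intersection,
)
from tucall.tss_caller import TSSRecord


def brute_force_zscore(counts, index):
    """Direct evaluation of the printed equations (leave-one-out in both
    the first and second moment, with the N - 1 prefactor)."""
    n = len(counts)
    r = counts[index]
    mu = (-r + sum(counts)) / (n - 1)
    mu2 = (-r * r + sum(c * c for c in counts)) / (n - 1)
    sigma = math.sqrt(mu2 - mu * mu)
    return (r - mu) / sigma


def profile_from(plus=None, minus=None, length=3000):
    return EndProfile.from_dicts("g", length, THREE_PRIME, "ts", plus=plus, minus=minus)


class TestModifiedZscore:
    def test_worked_arithmetic(self):
        # others of 10 are [1,2,3]: mu=2, mu2=14/3, Z=(10-2)/sqrt(14/3-4)
        z = modified_zscore([1, 2, 3, 10], 3)
        assert z == pytest.approx(8 / math.sqrt(14 / 3 - 4))
        assert z == pytest.approx(9.798, abs=1e-3)

    def test_uniform_cluster_scores_zero(self):
        assert modified_zscore([5, 5, 5], 1) == 0.0

    def test_zero_sigma_enriched_is_infinite(self):
        assert modified_zscore([3, 3, 12], 2) == math.inf

    def test_singleton_is_infinite(self):
        assert modified_zscore([7], 0) == math.inf

    def test_index_out_of_range(self):
        with pytest.raises(Exception):
            modified_zscore([1, 2], 5)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.lists(st.integers(min_value=0, max_value=100), min_size=2, max_size=30),
        st.data(),
    )
    def test_matches_printed_equations(self, counts, data):
        index = data.draw(st.integers(min_value=0, max_value=len(counts) - 1))
        others = counts[:index] + counts[index + 1 :]
        z = modified_zscore(counts, index)
        if len(set(others)) > 1:
            assert abs(z - brute_force_zscore(counts, index)) < 1e-9
        else:  # sigma = 0 edge contract
            assert z == (math.inf if counts[index] > others[0] else 0.0)


class TestCluster3Prime:
    def test_gap_rule(self):
        clusters = cluster_3prime_positions(
            profile_from(plus={1000: 1, 1005: 1, 1020: 1}), [], "+"
        )
        assert [list(c.positions) for c in clusters] == [[1000, 1005], [1020]]

    def test_invasion_allowance(self):
        gene = GeneAnnotation("g", 1000, 2000, "+")
        # 8 nt inside the gene's 5' end: retained (within the 10-bp invasion)
        clusters = cluster_3prime_positions(profile_from(plus={1007: 5}), [gene], "+")
        assert [list(c.positions) for c in clusters] == [[1007]]

    def test_mid_orf_excluded(self):
        gene = GeneAnnotation("g", 1000, 2000, "+")
        assert cluster_3prime_positions(profile_from(plus={1500: 5}), [gene], "+") == []

    def test_minus_strand_invasion_is_at_gene_end(self):
        gene = GeneAnnotation("g", 1000, 2000, "-")  # 5' end at coordinate 2000
        clusters = cluster_3prime_positions(profile_from(plus={1993: 5}), [gene], "+")
        # plus-strand mask unaffected by a minus-strand gene
        assert len(clusters) == 1
        clusters = cluster_3prime_positions(profile_from(minus={1993: 5}), [gene], "-")
        assert [list(c.positions) for c in clusters] == [[1993]]
        assert cluster_3prime_positions(profile_from(minus={1500: 5}), [gene], "-") == []


class TestSingleReplicate:
    def test_spike_survives_small_fail_count(self):
        cands = call_teps_single_replicate(
            profile_from(plus={100: 1, 102: 1, 104: 20}), []
        )
        assert [c.position for c in cands] == [104]
        assert cands[0].zscore == math.inf

    def test_uniform_cluster_all_fail_z(self):
        cands = call_teps_single_replicate(profile_from(plus={100: 3, 102: 3, 104: 3}), [])
        assert cands == []

    def test_isolated_position_survives(self):
        cands = call_teps_single_replicate(profile_from(plus={500: 5}), [])
        assert len(cands) == 1 and cands[0].cluster_span == (500, 500)


class TestReconcile:
    def cand(self, pos, count, span, strand="+"):
        return TEPCandidate(pos, strand, count, math.inf, span)

    def test_selection_restricted_to_intersection(self):
        # clusters 103-125 and 113-142 -> selection only within 113-125
        c1 = [self.cand(104, 50, (103, 125)), self.cand(118, 5, (103, 125))]
        c2 = [self.cand(130, 40, (113, 142))]
        out = reconcile_replicates(c1, c2)
        assert len(out) == 1
        assert out[0].position == 118  # 104 and 130 are outside 113..125

    def test_disjoint_spans_yield_nothing(self):
        out = reconcile_replicates(
            [self.cand(105, 9, (100, 110))], [self.cand(205, 9, (200, 210))]
        )
        assert out == []

    def test_argmax_of_summed_counts(self):
        c1 = [self.cand(118, 3, (103, 125)), self.cand(121, 5, (103, 125))]
        c2 = [self.cand(118, 4, (113, 142)), self.cand(121, 7, (113, 142))]
        out = reconcile_replicates(c1, c2)
        assert out[0].position == 121 and out[0].count == 12

    def test_tie_takes_smaller_coordinate(self):
        c1 = [self.cand(118, 6, (103, 125)), self.cand(121, 6, (103, 125))]
        c2 = [self.cand(119, 1, (113, 142))]
        out = reconcile_replicates(c1, c2)
        assert out[0].position == 118

    def test_span_intersection(self):
        assert span_intersection((103, 125), (113, 142)) == (113, 125)
        assert span_intersection((1, 5), (6, 9)) is None


class TestClassifyTEP:
    GENES = [GeneAnnotation("g1", 1000, 2000, "+")]
    TSS = [TSSRecord(900, "+", 30, 0, "P", "g1", 100, False)]

    def rec(self, pos, count=10, strand="+"):
        return TEPRecord(pos, strand, count)

    def test_cis_regulatory_distance_rule(self):
        out = classify_tep([self.rec(985)], self.TSS, self.GENES)
        assert out[0].category == "C" and out[0].gene_id == "g1"
        out = classify_tep([self.rec(960)], self.TSS, self.GENES)
        # 60 nt from the primary TSS: too close for a terminator hairpin
        assert out[0].category != "C"

    def test_only_highest_count_cis_kept(self):
        out = classify_tep(
            [self.rec(985, count=3), self.rec(990, count=30)], self.TSS, self.GENES
        )
        assert len(out) == 1
        assert out[0].position == 990 and out[0].category == "C"

    def test_primary_secondary_by_count(self):
        out = classify_tep(
            [self.rec(2100, count=30), self.rec(2350, count=5)], self.TSS, self.GENES
        )
        by_pos = {r.position: r for r in out}
        assert by_pos[2100].category == "P" and by_pos[2100].utr3_length == 100
        assert by_pos[2350].category == "S" and by_pos[2350].utr3_length == 350
        assert by_pos[2100].gene_id == "g1"

    def test_distance_threshold_to_intergenic(self):
        out = classify_tep([self.rec(2600)], self.TSS, self.GENES)
        assert out[0].category == "N"

    def test_antisense(self):
        out = classify_tep([self.rec(1500, strand="-")], self.TSS, self.GENES)
        assert out[0].category == "A"

    def test_category_partition_on_synthetic(self, default_dataset):
        from tucall.pipeline import run_on_dataset

        res = run_on_dataset(default_dataset)
        assert all(r.category in "PSCAN" for r in res.teps)
        primaries = [r.gene_id for r in res.teps if r.category == "P"]
        assert len(primaries) == len(set(primaries))
        cis = [r.gene_id for r in res.teps if r.category == "C"]
        assert len(cis) == len(set(cis))
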