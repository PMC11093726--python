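import random

import pytest

from isocurate import fixtures
from isocurate.classify import (assign_fsm_subcategory, assign_ism_subcategory,
                                classify_all, classify_transcript,
                                match_splice_chain)
from isocurate.models import ReferenceIndex

from _oracle import oracle_classify
from conftest import make_tx, mirror_bundle


REF_BLOCKS = [(1000, 1200), (1500, 1700), (2000, 2200), (2500, 2700)]


class TestSpliceChainMatch:
    def setup_method(self):
        self.ref = make_tx("R", REF_BLOCKS)

    def test_identical_chains_are_full(self):
        q = make_tx("q", [(900, 1200), (1500, 1700), (2000, 2200),
                          (2500, 2600)])
        assert match_splice_chain(q, self.ref) == "full"

    def test_contiguous_subchain(self):
        q = make_tx("q", [(1600, 1700), (2000, 2200), (2500, 2700)])
        assert match_splice_chain(q, self.ref) == "consecutive_subchain"

    def test_non_contiguous_subset_is_none(self):
        # junctions 1 and 3 of the reference, skipping junction 2
        q = make_tx("q", [(1000, 1200), (1500, 2200), (2500, 2700)])
        assert match_splice_chain(q, self.ref) == "none"

    def test_mono_exon_input_rejected(self):
        with pytest.raises(ValueError):
            match_splice_chain(make_tx("q", [(0, 500)]), self.ref)


class TestFsmSubcategory:
    @pytest.mark.parametrize("d5,d3,expected", [
        (0, 0, "reference_match"),
        (50, 50, "reference_match"),      # inclusive window boundary
        (51, 0, "alternative_5end"),
        (0, 51, "alternative_3end"),
        (200, 300, "alternative_3end5end"),
    ])
    def test_window_boundaries(self, d5, d3, expected):
        ref = make_tx("R", REF_BLOCKS)
        q = make_tx("q", [(1000 - d5, 1200), (1500, 1700), (2000, 2200),
                          (2500, 2700 + d3)])
        assert assign_fsm_subcategory(q, ref) == expected

    def test_signs_are_strand_aware(self):
        ref = make_tx("R", REF_BLOCKS, strand="-")
        # on the minus strand the genomic left end is the TTS
        q = make_tx("q", [(1000 - 80, 1200), (1500, 1700), (2000, 2200),
                          (2500, 2700)], strand="-")
        assert assign_fsm_subcategory(q, ref) == "alternative_3end"


class TestIsmSubcategory:
    def setup_method(self):
        self.ref = make_tx("R", REF_BLOCKS)

    def test_missing_five_prime_junction_is_3prime_fragment(self):
        q = make_tx("q", [(1500, 1700), (2000, 2200), (2500, 2700)])
        assert assign_ism_subcategory(q, self.ref) == "3prime_fragment"

    def test_missing_three_prime_junction_is_5prime_fragment(self):
        q = make_tx("q", [(1000, 1200), (1500, 1700), (2000, 2200)])
        assert assign_ism_subcategory(q, self.ref) == "5prime_fragment"

    def test_missing_both_sides_is_internal(self):
        q = make_tx("q", [(1500, 1700), (2000, 2200)])
        assert assign_ism_subcategory(q, self.ref) == "internal_fragment"

    def test_exon_bridging_reference_junction_is_intron_retention(self):
        q = make_tx("q", [(1000, 1200), (1500, 1700), (2000, 2600)])
        assert assign_ism_subcategory(q, self.ref) == "intron_retention"

    def test_minus_strand_fragment_sides_swap(self):
        ref = make_tx("R", REF_BLOCKS, strand="-")
        q = make_tx("q", [(1500, 1700), (2000, 2200), (2500, 2700)],
                    strand="-")
        assert assign_ism_subcategory(q, ref) == "5prime_fragment"


class TestCategoryCalls:
    def test_exact_copy_is_fsm_with_associated_transcript(self, simple_gene):
        ref, idx = simple_gene
        q = make_tx("q", [(1000, 1200), (1500, 1700), (2000, 2200)])
        call = classify_transcript(q, idx)
        assert call.category == "FSM"
        assert call.associated_transcript == "R1"
        assert call.diff_to_TSS == 0 and call.diff_to_TTS == 0

    def test_novel_donor_is_nnc(self, simple_gene):
        _, idx = simple_gene
        q = make_tx("q", [(1000, 1210), (1500, 1700), (2000, 2200)])
        call = classify_transcript(q, idx)
        assert call.category == "NNC"
        assert call.subcategory == "at_least_one_novel_splicesite"

    def test_known_sites_novel_junction_is_nic(self, simple_gene):
        _, idx = simple_gene
        q = make_tx("q", [(1000, 1200), (2000, 2200)])  # skips middle exon
        call = classify_transcript(q, idx)
        assert (call.category, call.subcategory) == \
            ("NIC", "combination_of_known_splicesites")

    def test_spliced_query_inside_intron_is_genic(self, simple_gene):
        _, idx = simple_gene
        q = make_tx("q", [(1210, 1290), (1400, 1480)])
        call = classify_transcript(q, idx)
        assert (call.category, call.subcategory) == \
            ("genic_genomic", "multi-exon")

    def test_chain_spanning_two_disjoint_loci_is_fusion(self):
        a = make_tx("A1", [(0, 210), (500, 800)], gene="GA")
        b = make_tx("B1", [(5000, 5210), (5500, 5800)], gene="GB")
        idx = ReferenceIndex.build([a, b], min_ref_len=0)
        q = make_tx("q", [(500, 800), (5000, 5210)])
        assert classify_transcript(q, idx).category == "fusion"

    def test_opposite_strand_overlap_is_antisense(self, simple_gene):
        _, idx = simple_gene
        q = make_tx("q", [(1100, 1300), (1600, 1800)], strand="-")
        assert classify_transcript(q, idx).category == "antisense"

    def test_no_overlap_is_intergenic(self, simple_gene):
        _, idx = simple_gene
        q = make_tx("q", [(50_000, 50_300)])
        assert classify_transcript(q, idx).category == "intergenic"


class TestMonoExon:
    def test_contained_in_exon_of_multi_exon_reference_is_ism(self,
                                                              simple_gene):
        _, idx = simple_gene
        q = make_tx("q", [(1520, 1680)])
        call = classify_transcript(q, idx)
        assert (call.category, call.subcategory) == ("ISM", "mono-exon")
        assert call.associated_transcript == "R1"

    def test_overlapping_mono_exon_reference_is_fsm(self):
        ref = make_tx("R", [(1000, 1400)])
        idx = ReferenceIndex.build([ref], min_ref_len=0)
        q = make_tx("q", [(1100, 1500)])
        call = classify_transcript(q, idx)
        assert (call.category, call.subcategory) == ("FSM", "mono-exon")

    def test_bridging_full_intron_is_nic_intron_retention(self, simple_gene):
        _, idx = simple_gene
        q = make_tx("q", [(1100, 1600)])
        call = classify_transcript(q, idx)
        assert (call.category, call.subcategory) == \
            ("NIC", "mono-exon_by_intron_retention")

    def test_crossing_one_exon_boundary_is_nic_mono(self, simple_gene):
        _, idx = simple_gene
        q = make_tx("q", [(1100, 1300)])
        call = classify_transcript(q, idx)
        assert (call.category, call.subcategory) == ("NIC", "mono-exon")

    def test_inside_intron_is_genic(self, simple_gene):
        _, idx = simple_gene
        q = make_tx("q", [(1250, 1450)])
        call = classify_transcript(q, idx)
        assert (call.category, call.subcategory) == \
            ("genic_genomic", "mono-exon")


class TestDeterminism:
    def test_fsm_tie_break_prefers_closest_then_lexicographic_id(self):
        r1 = make_tx("RB", [(1000, 1200), (1500, 1700)], gene="g")
        r2 = make_tx("RA", [(990, 1200), (1500, 1710)], gene="g")
        idx = ReferenceIndex.build([r1, r2], min_ref_len=0)
        q = make_tx("q", [(1000, 1200), (1500, 1700)])
        assert classify_transcript(q, idx).associated_transcript == "RB"
        # exact tie: both refs equally distant -> lexicographic id
        r3 = make_tx("RC", [(990, 1200), (1500, 1710)], gene="g")
        idx2 = ReferenceIndex.build([r2, r3], min_ref_len=0)
        q2 = make_tx("q2", [(995, 1200), (1500, 1705)])
        assert classify_transcript(q2, idx2).associated_transcript == "RA"

    def test_output_independent_of_query_order(self, label_bundle,
                                               label_index):
        queries = list(label_bundle.queries)
        shuffled = list(queries)
        random.Random(7).shuffle(shuffled)
        a = classify_all(queries, label_index)
        b = classify_all(shuffled, label_index)
        assert {k: (v.category, v.subcategory) for k, v in a.items()} == \
            {k: (v.category, v.subcategory) for k, v in b.items()}


class TestAgainstPlantedTruthAndOracle:
    def test_truth_agreement_is_exact_at_zero_jitter(self, label_bundle,
                                                     label_index):
        truth = label_bundle.truth.set_index("isoform")
        for tx in label_bundle.queries:
            call = classify_transcript(tx, label_index)
            row = truth.loc[tx.transcript_id]
            assert (call.category, call.subcategory) == \
                (row["category"], row["subcategory"]), tx.transcript_id

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        bundle = fixtures.generate(fixtures.FixtureSpec(seed=100 + seed))
        idx = ReferenceIndex.build(bundle.reference, min_ref_len=200)
        for tx in bundle.queries:
            call = classify_transcript(tx, idx)
            expected = oracle_classify(tx, bundle.reference)
            assert (call.category, call.subcategory) == expected, \
                tx.transcript_id

    def test_strand_antisymmetry(self, label_bundle):
        _, ref, queries = mirror_bundle(label_bundle)
        idx = ReferenceIndex.build(ref, min_ref_len=200)
        truth = label_bundle.truth.set_index("isoform")
        for tx in queries:
            call = classify_transcript(tx, idx)
            row = truth.loc[tx.transcript_id]
            assert (call.category, call.subcategory) == \
                (row["category"], row["subcategory"]), tx.transcript_id
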