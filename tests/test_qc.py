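import pytest

from isocurate.models import CoverageTrack, Junction, PeakSet, revcomp
from isocurate.qc import (compute_intrapriming, compute_tss_ratio,
                          find_polya_motif, junction_qc, peak_support,
                          rts_flag, splice_motif)


def plateau(chrom="chr1", segments=()):
    return CoverageTrack("r", [(chrom, s, e, v) for s, e, v in segments])


class TestTssRatio:
    def test_equal_coverage_gives_exactly_one(self):
        cov = plateau(segments=[(0, 10_000, 7.0)])
        assert compute_tss_ratio(5000, "+", "chr1", [cov]) == 1.0

    def test_zero_coverage_gives_exactly_one(self):
        cov = plateau(segments=[])
        assert compute_tss_ratio(5000, "+", "chr1", [cov]) == 1.0

    def test_printed_formula_values(self):
        cov = plateau(segments=[(4900, 5000, 0.99), (5000, 5100, 2.99)])
        assert compute_tss_ratio(5000, "+", "chr1", [cov]) == \
            pytest.approx(3.0, abs=1e-12)

    def test_replicate_aggregation(self):
        # replicate ratios 1.2 and 3.4 exactly, via the pseudocount formula
        def track(r):
            inside = r * 1.01 - 0.01
            return plateau(segments=[(4900, 5000, 1.0), (5000, 5100, inside)])
        tracks = [track(1.2), track(3.4)]
        args = (5000, "+", "chr1")
        assert compute_tss_ratio(*args, tracks) == pytest.approx(3.4)
        assert compute_tss_ratio(*args, tracks, aggregate="mean") == \
            pytest.approx(2.3)
        assert compute_tss_ratio(*args, tracks, aggregate="median") == \
            pytest.approx(2.3)
        assert compute_tss_ratio(*args, tracks, aggregate="q3") == \
            pytest.approx(2.85)

    def test_minus_strand_windows_mirror(self):
        cov = plateau(segments=[(4901, 5001, 10.0), (5001, 5101, 1.0)])
        r = compute_tss_ratio(5000, "-", "chr1", [cov])
        assert r == pytest.approx(10.01 / 1.01, abs=1e-12)

    def test_window_width_is_100(self):
        # a 10x plateau of width W downstream of the TSS gives the analytic
        # plateau ratio only when W >= the implementation window
        expected = (10.0 + 0.01) / (1.0 + 0.01)
        widths = {}
        for w in (99, 100, 101):
            cov = plateau(segments=[(0, 5000, 1.0), (5000, 5000 + w, 10.0),
                                    (5000 + w, 20_000, 1.0)])
            widths[w] = compute_tss_ratio(5000, "+", "chr1", [cov])
        assert widths[99] != pytest.approx(expected, abs=1e-9)
        assert widths[100] == pytest.approx(expected, abs=1e-12)
        assert widths[101] == pytest.approx(expected, abs=1e-12)

    def test_pseudocount_vanishes_at_scale(self):
        # scaling both windows leaves the no-pseudocount ratio fixed; the
        # computed ratio approaches it monotonically
        target = 3.0
        last_gap = None
        for c in (1.0, 10.0, 100.0, 1000.0):
            cov = plateau(segments=[(4900, 5000, c), (5000, 5100, 3 * c)])
            gap = abs(compute_tss_ratio(5000, "+", "chr1", [cov]) - target)
            if last_gap is not None:
                assert gap < last_gap
            last_gap = gap


class TestIntrapriming:
    def _genome(self, downstream):
        return {"chr1": "C" * 100 + downstream + "C" * 100}

    def test_all_adenine_window_is_flagged(self):
        perc, flag = compute_intrapriming(99, "+", "chr1",
                                          self._genome("A" * 20))
        assert perc == 1.0 and flag

    @pytest.mark.parametrize("n_a,flagged", [(12, True), (11, False)])
    def test_sixty_percent_boundary_is_inclusive(self, n_a, flagged):
        window = "A" * n_a + "C" * (20 - n_a)
        perc, flag = compute_intrapriming(99, "+", "chr1",
                                          self._genome(window))
        assert perc == pytest.approx(n_a / 20)
        assert flag is flagged

    def test_minus_strand_reads_reverse_complement(self):
        # downstream of a minus-strand TTS at position 100: bases [80, 100)
        genome = {"chr1": "C" * 80 + "T" * 20 + "C" * 100}
        perc, flag = compute_intrapriming(100, "-", "chr1", genome)
        assert perc == 1.0 and flag

    def test_chromosome_edge_clips_window(self):
        genome = {"chr1": "C" * 95 + "AAAAA"}
        perc, flag = compute_intrapriming(94, "+", "chr1", genome)
        assert perc == 1.0 and flag
        perc, flag = compute_intrapriming(99, "+", "chr1", genome)
        assert perc == 0.0 and not flag


class TestPolyaMotif:
    def test_planted_motif_and_distance(self):
        seq = "C" * 100 + "AATAAA" + "G" * 18
        assert find_polya_motif(seq, ["AATAAA"]) == ("AATAAA", 18)

    @pytest.mark.parametrize("dist,found", [(50, True), (51, False)])
    def test_terminal_window_boundary(self, dist, found):
        seq = "C" * 100 + "AATAAA" + "G" * dist
        hit = find_polya_motif(seq, ["AATAAA"])
        assert (hit is not None) is found

    def test_no_motif_returns_none(self):
        assert find_polya_motif("C" * 200, ["AATAAA", "ATTAAA"]) is None

    def test_closest_to_end_wins_then_list_order(self):
        seq = "C" * 40 + "AATAAA" + "C" * 10 + "ATTAAA" + "C" * 5
        assert find_polya_motif(seq, ["AATAAA", "ATTAAA"]) == ("ATTAAA", 5)
        tie = "C" * 40 + "ATTAAA" + "C" * 8
        # both motifs scanned; only one occurs
        assert find_polya_motif(tie, ["AATAAA", "ATTAAA"]) == ("ATTAAA", 8)

    def test_short_sequence_scanned_whole(self):
        assert find_polya_motif("AATAAACC", ["AATAAA"]) == ("AATAAA", 2)


class TestPeakSupport:
    def test_end_inside_peak(self):
        peaks = PeakSet([("chr1", 980, 1030, "+")], kind="five_prime")
        within, dist = peak_support(1000, "+", "chr1", peaks, "five_prime")
        assert within
        assert dist == 5  # midpoint 1005, downstream of the end

    def test_upstream_peak_distance_is_negative(self):
        peaks = PeakSet([("chr1", 950, 991, "+")])
        within, dist = peak_support(1000, "+", "chr1", peaks, "five_prime")
        assert not within and dist == -30

    def test_downstream_only_peak_ineligible_for_five_prime(self):
        peaks = PeakSet([("chr1", 1100, 1140, "+")])
        within, dist = peak_support(1000, "+", "chr1", peaks, "five_prime")
        assert not within and dist is None

    def test_three_prime_side_wants_downstream(self):
        peaks = PeakSet([("chr1", 1020, 1060, "+")])
        within, dist = peak_support(1000, "+", "chr1", peaks, "three_prime")
        assert dist == 40
        within, dist = peak_support(1000, "+", "chr1", peaks, "five_prime")
        assert dist is None

    def test_minus_strand_flips_direction(self):
        # genomic right of a minus-strand TSS is upstream
        peaks = PeakSet([("chr1", 1020, 1060, "-")])
        _, dist = peak_support(1000, "-", "chr1", peaks, "five_prime")
        assert dist == -40


class TestJunctionQc:
    def _genome_with_intron(self, donor="GT", acceptor="AG"):
        intron = donor + "C" * 96 + acceptor
        return {"chr1": "A" * 100 + intron + "A" * 100}

    @pytest.mark.parametrize("donor,acceptor,canonical", [
        ("GT", "AG", True), ("GC", "AG", True), ("AT", "AC", True),
        ("CT", "AC", False), ("GT", "AC", False)])
    def test_canonical_motif_set(self, donor, acceptor, canonical):
        genome = self._genome_with_intron(donor, acceptor)
        j = Junction("chr1", "+", 100, 200)
        qc = junction_qc(j, genome)
        assert qc.splice_motif == f"{donor}-{acceptor}"
        assert qc.canonical is canonical

    def test_minus_strand_motif_is_strand_corrected(self):
        # forward CT...AC reads as GT-AG on the minus strand
        genome = self._genome_with_intron("CT", "AC")
        j = Junction("chr1", "-", 100, 200)
        assert splice_motif(j, genome) == "GT-AG"

    def test_absent_junction_has_zero_coverage(self):
        genome = self._genome_with_intron()
        qc = junction_qc(Junction("chr1", "+", 100, 200), genome, sj=None)
        assert qc.total_cov == 0


class TestRtsFlag:
    def test_planted_repeat_at_both_boundaries(self):
        rep = "GATCGATC"
        seq = ("C" * 92 + rep + "GT" + "A" * 80 + rep[:6] + "AG" +
               "C" * 100)
        # windows around intron start 100 and intron end 190 share no 8-mer
        genome = {"chr1": seq}
        j = Junction("chr1", "+", 100, 190)
        assert not rts_flag(j, genome)
        planted = ("C" * 92 + rep + "GT" + "A" * 78 + rep + "C" * 100)
        j2 = Junction("chr1", "+", 100, 180)
        assert rts_flag(j2, {"chr1": planted})

    def test_random_background_without_repeat_is_clean(self):
        seq = "ACGTACGG" + "GT" + "TTGCAATC" * 10 + "AG" + "CCGGATCA"
        genome = {"chr1": seq}
        assert not rts_flag(Junction("chr1", "+", 8, len(seq) - 8), genome)

    def test_repeat_longer_than_window_is_false(self):
        genome = {"chr1": "A" * 6}
        assert not rts_flag(Junction("chr1", "+", 2, 4), genome,
                            repeat_len=8)


class TestReverseComplementInvariance:
    def test_attributes_survive_genome_mirroring(self):
        genome = {"chr1": "C" * 40 + "AATAAA" + "C" * 17 + "A" * 20 +
                  "G" * 40}
        L = len(genome["chr1"])
        mirrored = {"chr1": revcomp(genome["chr1"])}
        # transcript ends at position 62 on + == position L-63 on -
        perc_f, flag_f = compute_intrapriming(62, "+", "chr1", genome)
        perc_r, flag_r = compute_intrapriming(L - 63, "-", "chr1", mirrored)
        assert perc_f == perc_r == 1.0 and flag_f and flag_r
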