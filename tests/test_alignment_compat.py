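import numpy as np
import pytest

from isoem.alignment_compat import (
    Alignment,
    MateAln,
    ParseStats,
    alignment_base_prob,
    compute_weights,
    compute_weights_bruteforce,
    fragment_factor_paired,
    fragment_factor_single,
    orientation_factor,
    parse_alignments,
    phred_to_eps,
    single_end_length_bound,
    weight_term,
)
from isoem.fragment_model import make_length_dist
from isoem.simulator import assign_true_frequencies, simulate_reads, simulate_transcriptome
from isoem.transcript_model import Isoform, Transcriptome

from conftest import make_transcriptome


@pytest.fixture(scope="module")
def dist():
    return make_length_dist(250, 25, k_min=150, k_max=350)


def single(blocks, strand="+", q=1.0, chrom="chr1"):
    return Alignment(chrom=chrom, mates=(MateAln(tuple(blocks), strand),), q=q)


class TestBaseProb:
    def test_two_matches(self):
        assert alignment_base_prob([True, True], [0.01, 0.1]) == pytest.approx(0.891)

    def test_match_and_mismatch(self):
        assert alignment_base_prob([True, False], [0.01, 0.1]) == pytest.approx(0.099)

    def test_empty_product(self):
        assert alignment_base_prob([], []) == 1.0

    def test_phred_conversion_clamped(self):
        eps = phred_to_eps([30, 2, 60], 3)
        assert eps[0] == pytest.approx(1e-3)
        assert eps[1] == pytest.approx(0.63095734, abs=1e-6)
        assert eps[2] == 1e-4  # floored

    def test_missing_quals_default_phred30(self):
        assert phred_to_eps(None, 2) == [pytest.approx(1e-3)] * 2


class TestOrientation:
    def test_single_nondirectional_antisense_is_one(self, two_exon_isoform):
        a = single([(150, 175)], strand="-")
        assert orientation_factor(a, two_exon_isoform, paired=False, directional=False) == 1

    def test_single_directional_antisense_is_zero(self, two_exon_isoform):
        a = single([(150, 175)], strand="-")
        assert orientation_factor(a, two_exon_isoform, paired=False, directional=True) == 0

    def test_paired_same_strand_is_zero(self, two_exon_isoform):
        a = Alignment(
            chrom="chr1",
            mates=(MateAln(((110, 135),), "+"), MateAln(((320, 345),), "+")),
            q=1.0,
        )
        assert orientation_factor(a, two_exon_isoform, paired=True, directional=True) == 0

    def test_proper_pair_is_one(self, two_exon_isoform):
        a = Alignment(
            chrom="chr1",
            mates=(MateAln(((110, 135),), "+"), MateAln(((320, 345),), "-")),
            q=1.0,
        )
        assert orientation_factor(a, two_exon_isoform, paired=True, directional=False) == 1

    def test_outward_pointing_pair_is_zero(self, two_exon_isoform):
        # antisense mate 5'-most on the transcript: mates point away
        a = Alignment(
            chrom="chr1",
            mates=(MateAln(((110, 135),), "-"), MateAln(((320, 345),), "+")),
            q=1.0,
        )
        assert orientation_factor(a, two_exon_isoform, paired=True, directional=False) == 0

    def test_directional_pair_needs_sense_first_mate(self, two_exon_isoform):
        a = Alignment(
            chrom="chr1",
            mates=(MateAln(((320, 345),), "-"), MateAln(((110, 135),), "+")),
            q=1.0,
        )
        assert orientation_factor(a, two_exon_isoform, paired=True, directional=True) == 0
        assert orientation_factor(a, two_exon_isoform, paired=True, directional=False) == 1


class TestLengthBound:
    def test_sense_counts_to_three_prime(self):
        assert single_end_length_bound((100, 125), mate_sense=True, l=1000) == 900

    def test_antisense_counts_to_five_prime(self):
        assert single_end_length_bound((375, 400), mate_sense=False, l=1000) == 400

    def test_sense_at_origin_gives_full_length(self):
        assert single_end_length_bound((0, 25), mate_sense=True, l=1000) == 1000


class TestFragmentFactor:
    def test_paired_modal_length(self, dist):
        assert fragment_factor_paired(dist, 250) == dist.p(250) == dist.pmf.max()

    def test_single_saturated_cdf(self, dist):
        assert fragment_factor_single(dist, 900) == 1.0

    def test_single_below_support(self, dist):
        assert fragment_factor_single(dist, 100) == 0.0


class TestWeightTerm:
    def test_perfect_single_alignment(self, dist):
        iso = Isoform(id="A", gene_id="G", chrom="chr1", strand="+", exons=((0, 1000),))
        a = single([(100, 125)], q=0.9)
        expected = 0.9 * dist.cdf(900)
        assert weight_term(a, iso, dist) == pytest.approx(expected)

    def test_incompatible_gives_zero(self, dist, two_exon_isoform):
        a = single([(150, 210)])
        assert weight_term(a, two_exon_isoform, dist) == 0.0

    def test_symmetric_isoforms_equal_weight(self, dist):
        iso_a = Isoform(id="A", gene_id="G", chrom="chr1", strand="+", exons=((0, 1000),))
        iso_b = Isoform(id="B", gene_id="G", chrom="chr1", strand="+", exons=((0, 1000),))
        a = single([(100, 125)])
        assert weight_term(a, iso_a, dist) == weight_term(a, iso_b, dist)

    def test_nondirectional_revcomp_invariance_away_from_ends(self, dist):
        # deep inside a long isoform both orientations saturate the cdf
        iso = Isoform(id="A", gene_id="G", chrom="chr1", strand="+", exons=((0, 10000),))
        fwd = single([(5000, 5025)], strand="+", q=0.8)
        rev = single([(5000, 5025)], strand="-", q=0.8)
        assert weight_term(fwd, iso, dist) == weight_term(rev, iso, dist)

    def test_paired_fragment_length_from_coordinates(self, dist):
        iso = Isoform(id="A", gene_id="G", chrom="chr1", strand="+", exons=((0, 1000),))
        a = Alignment(
            chrom="chr1",
            mates=(MateAln(((100, 125),), "+"), MateAln(((325, 350),), "-")),
            q=1.0,
        )
        assert weight_term(a, iso, dist) == pytest.approx(dist.p(250))


def write_sam(path, sq, records):
    lines = ["@HD\tVN:1.6"] + [f"@SQ\tSN:{n}\tLN:{l}" for n, l in sq] + records
    path.write_text("\n".join(lines) + "\n")


class TestParseAlignments:
    def test_transcript_to_genome_conversion(self, tmp_path, two_exon_isoform):
        tr = make_transcriptome(two_exon_isoform)
        sam = tmp_path / "a.sam"
        seq = "A" * 60
        write_sam(sam, [("T1", 200)], [f"r1\t0\tT1\t51\t60\t60M\t*\t0\t0\t{seq}\t{'I' * 60}"])
        groups = parse_alignments(str(sam), tr)
        assert len(groups) == 1
        assert groups[0].alignments[0].mates[0].blocks == ((150, 200), (300, 310))
        assert groups[0].alignments[0].mates[0].strand == "+"

    def test_equivalent_transcript_hits_deduplicated(self, tmp_path, two_exon_isoform):
        twin = Isoform(id="T2", gene_id="G1", chrom="chr1", strand="+",
                       exons=two_exon_isoform.exons)
        tr = make_transcriptome(two_exon_isoform, twin)
        sam = tmp_path / "a.sam"
        rec = "r1\t0\t{ref}\t11\t60\t25M\t*\t0\t0\t" + "A" * 25 + "\t" + "I" * 25
        write_sam(sam, [("T1", 200), ("T2", 200)],
                  [rec.format(ref="T1"), rec.format(ref="T2")])
        groups = parse_alignments(str(sam), tr)
        assert len(groups[0].alignments) == 1

    def test_unknown_reference_fatal(self, tmp_path, two_exon_isoform):
        tr = make_transcriptome(two_exon_isoform)
        sam = tmp_path / "a.sam"
        write_sam(sam, [("TX", 200)], ["r1\t0\tTX\t1\t60\t5M\t*\t0\t0\tAAAAA\tIIIII"])
        with pytest.raises(ValueError, match="TX"):
            parse_alignments(str(sam), tr)

    def test_empty_input(self, tmp_path, two_exon_isoform):
        tr = make_transcriptome(two_exon_isoform)
        sam = tmp_path / "a.sam"
        write_sam(sam, [("T1", 200)], [])
        assert parse_alignments(str(sam), tr) == []

    def test_gapped_alignment_rejected(self, tmp_path, two_exon_isoform):
        tr = make_transcriptome(two_exon_isoform)
        sam = tmp_path / "a.sam"
        write_sam(sam, [("T1", 200)],
                  ["r1\t0\tT1\t1\t60\t10M5D10M\t*\t0\t0\t" + "A" * 20 + "\t" + "I" * 20])
        stats = ParseStats()
        assert parse_alignments(str(sam), tr, stats=stats) == []
        assert stats.rejected_records == 1

    def test_mismatch_probabilities_from_fasta(self, tmp_path):
        iso = Isoform(id="T1", gene_id="G", chrom="c", strand="+", exons=((0, 100),))
        tr = make_transcriptome(iso)
        seqs = {"T1": "A" * 100}
        sam = tmp_path / "a.sam"
        # one mismatch (C) at phred 20, rest at phred 20
        qual = chr(33 + 20) * 5
        write_sam(sam, [("T1", 100)], [f"r1\t0\tT1\t1\t60\t5M\t*\t0\t0\tACAAA\t{qual}"])
        groups = parse_alignments(str(sam), tr, transcript_seqs=seqs)
        q = groups[0].alignments[0].q
        assert q == pytest.approx(0.99**4 * 0.01)


class TestComputeWeights:
    def test_single_isoform_weight(self, dist, tmp_path):
        iso = Isoform(id="A", gene_id="G", chrom="chr1", strand="+", exons=((0, 1000),))
        tr = make_transcriptome(iso)
        group_aln = single([(100, 125)], q=0.7)
        from isoem.alignment_compat import AlignmentGroup

        groups = [AlignmentGroup(read_id="r1", alignments=[group_aln])]
        weighted, dropped = compute_weights(groups, tr, dist)
        assert dropped == 0
        assert weighted[0].entries == [("A", pytest.approx(0.7 * dist.cdf(900)))]

    def test_incompatible_read_dropped(self, dist, two_exon_isoform):
        from isoem.alignment_compat import AlignmentGroup

        tr = make_transcriptome(two_exon_isoform)
        groups = [AlignmentGroup(read_id="r1", alignments=[single([(250, 275)])])]
        weighted, dropped = compute_weights(groups, tr, dist)
        assert weighted == [] and dropped == 1

    @pytest.mark.parametrize("seed", range(12))
    @pytest.mark.parametrize("paired", [False, True])
    def test_sweep_matches_bruteforce(self, seed, paired, dist, tmp_path):
        synth = simulate_transcriptome(n_genes=6, max_isoforms=4, seed=seed)
        truth = assign_true_frequencies(synth.transcriptome, seed=seed)
        reads = simulate_reads(
            synth, truth, n_reads=40, read_len=25, dist=dist,
            paired=paired, error_rate=0.01, seed=seed,
        )
        sam = tmp_path / f"{seed}_{paired}.sam"
        reads.write_sam(str(sam))
        groups = parse_alignments(str(sam), synth.transcriptome, synth.sequences)
        got, got_drop = compute_weights(groups, synth.transcriptome, dist)
        exp, exp_drop = compute_weights_bruteforce(groups, synth.transcriptome, dist)
        assert got_drop == exp_drop
        assert [(w.read_id, w.entries) for w in got] == [
            (w.read_id, w.entries) for w in exp
        ]
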