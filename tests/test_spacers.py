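"""crRNA spacer design modes and QC screens."""

import random

import pytest

from phagedit.fixtures import FixtureSpec, make_host_decoy, make_toy_phage
from phagedit.genome import AnnotatedGenome, GeneFeature, GenomeInterval
from phagedit.spacers import (
    RFP_SPACER,
    DesignError,
    MatureCrRNA,
    design_cds_start_spacer,
    design_custom_spacer,
    design_deletion_verify_spacer,
    design_rbs_spacer,
    hairpin_screen,
    longest_hairpin_stem,
    longest_host_match,
    non_targeting_spacer,
    offtarget_screen,
)


class TestCdsStart:
    def test_spacer_is_revcomp_of_first_31(self, toy, revcomp_oracle):
        d = design_cds_start_spacer(toy, "degA")
        first31 = toy.sequence[toy.feature("degA").start :][:31]
        assert d.protospacer == first31
        assert d.spacer == revcomp_oracle(first31)
        assert len(d) == 31 and d.mode == "CDS_START"

    def test_protospacer_begins_with_start_codon(self, toy_mixed):
        for f in toy_mixed.features:
            assert design_cds_start_spacer(toy_mixed, f.gene_id).protospacer[:3] == "ATG"

    def test_minus_strand_reads_reverse_complement_strand(self, toy_mixed, revcomp_oracle):
        f = next(x for x in toy_mixed.features if x.strand == "-")
        d = design_cds_start_spacer(toy_mixed, f.gene_id)
        assert d.protospacer == revcomp_oracle(toy_mixed.sequence[f.end - 31 : f.end])

    def test_printed_rfp_spacer_recovered(self, revcomp_oracle):
        # a transcript opening with the reverse complement of the published
        # RFP control spacer yields exactly that spacer
        cds = revcomp_oracle(RFP_SPACER) + "GATAA"
        seq = "AAAA" + cds + "TTTT"
        g = AnnotatedGenome(
            id="rfp", sequence=seq, features=[GeneFeature("rfp", 4, 4 + 36, "+")]
        )
        assert design_cds_start_spacer(g, "rfp").spacer == RFP_SPACER

    def test_short_cds_rejected(self):
        g = AnnotatedGenome(
            id="s", sequence="A" * 10 + "ATGAAATAA" + "A" * 10,
            features=[GeneFeature("tiny", 10, 19, "+")],
        )
        with pytest.raises(DesignError):
            design_cds_start_spacer(g, "tiny")

    def test_window_with_n_rejected(self):
        g = AnnotatedGenome(
            id="n", sequence="ATGNAA" + "ACG" * 20,
            features=[GeneFeature("g", 0, 33, "+")],
        )
        with pytest.raises(DesignError):
            design_cds_start_spacer(g, "g")


class TestRbs:
    def test_offset_minus4_covers_4_upstream_plus_27_cds(self, toy):
        f = toy.feature("degA")
        d = design_rbs_spacer(toy, "degA", -4)
        assert d.protospacer == toy.sequence[f.start - 4 : f.start + 27]
        assert d.mode == "RBS"

    @pytest.mark.parametrize("offset", [-7, -3, 0])
    def test_offset_out_of_range(self, toy, offset):
        with pytest.raises(DesignError):
            design_rbs_spacer(toy, "degA", offset)

    def test_minus_strand_window_in_transcript_coordinates(self, toy_mixed, revcomp_oracle):
        f = next(x for x in toy_mixed.features if x.strand == "-")
        d = design_rbs_spacer(toy_mixed, f.gene_id, -6)
        # transcript-sense: 6 nt upstream of the start codon then 25 nt of CDS
        expected = revcomp_oracle(toy_mixed.sequence[f.end - 25 : f.end + 6])
        assert d.protospacer == expected


class TestDeletionVerify:
    def test_offset_zero_abuts_the_deletion_end(self, toy):
        f = toy.feature("gene3")
        deleted = GenomeInterval(f.start + 3, f.end - 3, "+")
        d = design_deletion_verify_spacer(toy, deleted, 0)
        # window ends exactly at the deletion's 3' end: fully inside it
        assert d.target.end == deleted.end
        assert d.protospacer == toy.sequence[deleted.end - 31 : deleted.end]

    def test_offset_15_extends_15_past_the_end(self, toy):
        f = toy.feature("gene3")
        deleted = GenomeInterval(f.start + 3, f.end - 3, "+")
        d = design_deletion_verify_spacer(toy, deleted, 15)
        assert d.target.end == deleted.end + 15
        # still overlaps 16 nt of to-be-deleted sequence
        assert d.target.start < deleted.end

    @pytest.mark.parametrize("offset", [-1, 16])
    def test_offset_bounds(self, toy, offset):
        f = toy.feature("gene3")
        deleted = GenomeInterval(f.start + 3, f.end - 3, "+")
        with pytest.raises(DesignError):
            design_deletion_verify_spacer(toy, deleted, offset)

    def test_minus_strand_junction(self, toy_mixed, revcomp_oracle):
        f = next(x for x in toy_mixed.features if x.strand == "-")
        deleted = GenomeInterval(f.start + 3, f.end - 3, "-")
        d = design_deletion_verify_spacer(toy_mixed, deleted, 5)
        # transcript-sense 3' end of a minus-strand interval is its genomic start
        assert d.target.start == deleted.start - 5
        assert d.protospacer == revcomp_oracle(
            toy_mixed.sequence[deleted.start - 5 : deleted.start + 26]
        )


class TestInvariants:
    def test_every_mode_emits_configured_length_and_duality(self, toy_mixed, revcomp_oracle):
        designs = [
            design_cds_start_spacer(toy_mixed, "degA"),
            design_rbs_spacer(toy_mixed, "gene5", -5),
            design_custom_spacer(toy_mixed, "gene5", 12),
            non_targeting_spacer(),
        ]
        for d in designs:
            assert len(d.spacer) == 31
            assert d.spacer == revcomp_oracle(d.protospacer)

    def test_non_targeting_carries_no_interval(self):
        assert non_targeting_spacer().target is None


def _brute_force_longest_match(proto, host, revcomp_oracle):
    best = 0
    for q in (proto, revcomp_oracle(proto)):
        for i in range(len(q)):
            for j in range(i + best + 1, len(q) + 1):
                if q[i:j] in host:
                    best = j - i
                else:
                    break
    return best


class TestOfftarget:
    def test_full_31mer_in_host_flags(self, toy):
        d = design_cds_start_spacer(toy, "degA")
        host_seq, pos = make_host_decoy(FixtureSpec(seed=9), embed=d.protospacer)
        assert host_seq[pos : pos + 31] == d.protospacer
        host = AnnotatedGenome(id="h", sequence=host_seq)
        out = offtarget_screen(d, host, min_flag_match=15)
        assert out.offtarget_flag and out.offtarget_len == 31

    def test_partial_10mer_below_threshold_not_flagged(self, toy, revcomp_oracle):
        d = design_cds_start_spacer(toy, "degA")
        host_seq, _ = make_host_decoy(FixtureSpec(seed=11), embed=d.protospacer[:10])
        host = AnnotatedGenome(id="h", sequence=host_seq)
        out = offtarget_screen(d, host, min_flag_match=15)
        assert not out.offtarget_flag
        assert out.offtarget_len == _brute_force_longest_match(
            d.protospacer, host_seq, revcomp_oracle
        )

    def test_empty_host_matches_nothing(self):
        assert longest_host_match("ACGTACGT", "") == 0

    def test_agrees_with_bruteforce_oracle(self, revcomp_oracle):
        rng = random.Random(42)
        for _ in range(30):
            proto = "".join(rng.choice("ACGT") for _ in range(31))
            host = "".join(rng.choice("ACGT") for _ in range(800))
            if rng.random() < 0.5:  # sometimes plant a partial match
                k = rng.randrange(5, 25)
                p = rng.randrange(0, len(host) - k)
                host = host[:p] + proto[:k] + host[p + k :]
            assert longest_host_match(proto, host) == _brute_force_longest_match(
                proto, host, revcomp_oracle
            )


def _oracle_stem(seq, min_loop, revcomp_oracle):
    """Exhaustive O(n^3) stem search."""
    n = len(seq)
    best = 0
    for L in range(1, n // 2 + 1):
        for i in range(n - L + 1):
            for j in range(i + L + min_loop, n - L + 1):
                if seq[j : j + L] == revcomp_oracle(seq[i : i + L]):
                    best = max(best, L)
    return best


class TestHairpin:
    def test_homopolymer_has_no_stem(self):
        flag, stem = hairpin_screen(MatureCrRNA("", "A" * 40), min_stem=8)
        assert not flag and stem == 0

    def test_planted_10bp_stem_detected(self, revcomp_oracle):
        x = "ACGGTCAGTT"
        seq = x + "AAAA" + revcomp_oracle(x)
        flag, stem = hairpin_screen(MatureCrRNA("", seq), min_stem=8, min_loop=3)
        assert flag and stem >= 10

    def test_random_sequences_match_exhaustive_oracle(self, revcomp_oracle):
        rng = random.Random(7)
        for _ in range(25):
            seq = "".join(rng.choice("ACGT") for _ in range(60))
            assert longest_hairpin_stem(seq, min_loop=3) == _oracle_stem(
                seq, 3, revcomp_oracle
            )

    def test_degrades_to_spacer_when_repeat_missing(self, toy):
        d = design_cds_start_spacer(toy, "degA")
        flag, stem = hairpin_screen(d, min_stem=8)
        assert stem == longest_hairpin_stem(d.spacer, min_loop=3)
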