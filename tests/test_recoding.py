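"""Silent recoding: silence, scope restriction, maximality, escape calls."""

import itertools
import random

import pytest
from Bio.Seq import Seq

from phagedit.fixtures import FixtureSpec, make_toy_phage
from phagedit.genome import AnnotatedGenome, GeneFeature
from phagedit.recoding import (
    TABLE1_REFERENCE_SNPS,
    CodonUsageTable,
    RecodingError,
    predict_escape,
    recode,
    seed_to_protospacer_window,
    synonyms,
    table1_reference,
)
from phagedit.spacers import design_cds_start_spacer, design_custom_spacer


def _gene_genome(codons, name="g", pad=40):
    """Single plus-strand gene genome from an explicit codon list."""
    rng = random.Random(5)
    cds = "".join(codons)
    left = "".join(rng.choice("ACGT") for _ in range(pad))
    right = "".join(rng.choice("ACGT") for _ in range(pad))
    return AnnotatedGenome(
        id="mini",
        sequence=left + cds + right,
        features=[GeneFeature(name, pad, pad + len(cds), "+")],
    )


class TestUsageTable:
    def test_shipped_table_is_complete_and_normalized(self, usage):
        assert len(usage.usage) == 64
        assert usage["CTG"] > usage["CTA"]  # E. coli Leu bias

    def test_unnormalized_family_rejected(self):
        bad = {c: 0.5 for c in ("TTT", "TTC")}
        bad["TTT"] = 0.6
        with pytest.raises(RecodingError):
            CodonUsageTable("x", bad)


class TestSeedWindowMapping:
    def test_spacer_5prime_pairs_protospacer_3prime(self):
        # spacer positions 5-12 on a 31-nt spacer pair protospacer
        # positions 20-27 (1-based), i.e. [19, 27) 0-based
        assert seed_to_protospacer_window((5, 12), 31) == (19, 27)
        assert seed_to_protospacer_window((1, 1), 31) == (30, 31)

    def test_window_outside_spacer_rejected(self):
        with pytest.raises(RecodingError):
            seed_to_protospacer_window((5, 40), 31)


class TestScopes:
    def test_single_codon_forced_single_change(self):
        # one Lys codon among Met/Trp: AAA -> AAG is the only silent move
        g = _gene_genome(["ATG"] + ["TGG"] * 4 + ["AAA"] + ["TGG"] * 5 + ["TAA"])
        sp = design_cds_start_spacer(g, "g")
        d = recode(g, sp, "C")
        assert d.snp_count == 1
        assert d.changes[0].old == "AAA" and d.changes[0].new == "AAG"

    def test_no_degenerate_codon_errors_for_C_warns_for_F(self, toy):
        sp = design_cds_start_spacer(toy, "stiffB")  # ATG/TGG-rich gene
        with pytest.raises(RecodingError):
            recode(toy, sp, "C")
        d = recode(toy, sp, "F")
        assert d.snp_count == 0 and d.warnings

    def test_substitutions_confined_to_scope(self, toy_mixed):
        sp = design_cds_start_spacer(toy_mixed, "degA")
        lo, hi = seed_to_protospacer_window((5, 12), 31)
        d = recode(toy_mixed, sp, "S")
        for p, (a, b) in enumerate(zip(d.original, d.recoded)):
            if a != b:
                assert lo <= p < hi
        # flanking codon context outside the protospacer untouched
        off = d.original_context.find(d.original)
        assert d.recoded_context[:off] == d.original_context[:off]

    def test_scope_nesting_monotonicity(self, toy_mixed):
        sp = design_cds_start_spacer(toy_mixed, "degA")
        dC = recode(toy_mixed, sp, "C")
        dS = recode(toy_mixed, sp, "S")
        dF = recode(toy_mixed, sp, "F")
        assert dF.snp_count >= dS.snp_count
        assert dF.snp_count >= dC.snp_count
        lo, hi = seed_to_protospacer_window((5, 12), 31)
        if all(lo <= p < hi for p in dC.changes[0].positions):
            assert dS.snp_count >= dC.snp_count

    def test_frame_offset_reported_for_mid_cds_target(self, toy):
        sp = design_custom_spacer(toy, "gene3", 7, spacer_len=24)
        d = recode(toy, sp, "F")
        assert d.frame_offset == 1
        assert d.snp_count >= 1


class TestSilence:
    def test_translation_identical_over_random_designs(self):
        rng = random.Random(13)
        for trial in range(40):
            g = make_toy_phage(FixtureSpec(seed=100 + trial, n_genes=3))
            gene = rng.choice([f.gene_id for f in g.features])
            sp = design_cds_start_spacer(g, gene)
            for mode in "SF":
                d = recode(g, sp, mode)
                assert Seq(d.original_context).translate() == Seq(
                    d.recoded_context
                ).translate()
                assert d.snp_count == sum(
                    a != b for a, b in zip(d.original, d.recoded)
                )


def _exhaustive_optimum(d, usage, rare_threshold=0.10):
    """Brute force over all synonymous codon combinations of the recoded
    context, subject to silence, out-of-scope preservation and the rare-codon
    rule; returns the maximum total protospacer change count."""
    ctx = d.original_context
    off = ctx.find(d.original)
    L = len(d.original)
    options = []
    for ci in range(len(ctx) // 3):
        codon = ctx[3 * ci : 3 * ci + 3]
        cands = set()
        for alt in synonyms(codon):
            ok_scope = all(
                alt[i] == codon[i]
                for i in range(3)
                if not 0 <= 3 * ci + i - off < L
            )
            if ok_scope and usage[alt] >= rare_threshold:
                cands.add(alt)
        if not any(
            any(a[i] != codon[i] for i in range(3)) for a in cands
        ):  # immutable under the rarity rule: allow the rare fallback
            for alt in synonyms(codon):
                if all(
                    alt[i] == codon[i]
                    for i in range(3)
                    if not 0 <= 3 * ci + i - off < L
                ):
                    cands.add(alt)
        cands.add(codon)
        options.append(sorted(cands))
    size = 1
    for o in options:
        size *= len(o)
    if size > 250_000:  # keep the enumeration honest but bounded
        return None
    best = 0
    for combo in itertools.product(*options):
        s = "".join(combo)
        best = max(best, sum(a != b for a, b in zip(ctx[off : off + L], s[off : off + L])))
    return best


class TestExhaustiveOracle:
    def test_full_recode_attains_bruteforce_maximum(self, usage):
        rng = random.Random(99)
        checked = 0
        for trial in range(60):
            if checked >= 25:
                break
            g = make_toy_phage(FixtureSpec(seed=300 + trial, n_genes=3))
            gene = rng.choice([f.gene_id for f in g.features])
            spacer_len = rng.choice((12, 15, 18, 21))
            sp = design_cds_start_spacer(g, gene, spacer_len=spacer_len)
            d = recode(g, sp, "F", seed_window=(1, spacer_len))
            optimum = _exhaustive_optimum(d, usage)
            if optimum is None:
                continue
            assert d.snp_count == optimum
            checked += 1
        assert checked >= 25


def _oracle_longest_seed_run(original, recoded, lo, hi):
    run = best = 0
    for p in range(len(original)):
        if lo <= p < hi and original[p] != recoded[p]:
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


class TestPredictEscape:
    def test_zero_seed_changes_is_at_risk(self):
        g = _gene_genome(["ATG", "AAA"] + ["TGG"] * 8 + ["TAA"])
        sp = design_cds_start_spacer(g, "g")
        d = recode(g, sp, "C")  # only change lands at protospacer 5' end
        assert all(p < 19 for p in d.changes[0].positions)
        assert predict_escape(d) == "AT_RISK"

    def test_three_contiguous_seed_changes_escape(self):
        # a Ser codon inside the seed admits a 3-nt silent flip (TCT->AGC)
        g = _gene_genome(["ATG"] + ["AAA"] * 6 + ["TCT"] + ["AAA"] * 3 + ["TAA"])
        sp = design_cds_start_spacer(g, "g")
        d = recode(g, sp, "C")
        assert d.changes[0].old == "TCT" and d.snp_count == 3
        assert predict_escape(d, min_contiguous_seed_changes=3) == "ESCAPES"
        assert _oracle_longest_seed_run(d.original, d.recoded, 19, 27) == 3

    def test_scattered_seed_changes_stay_at_risk(self, toy_mixed):
        # third-position-only families give isolated seed substitutions
        sp = design_cds_start_spacer(toy_mixed, "degA")
        d = recode(toy_mixed, sp, "S")
        lo, hi = seed_to_protospacer_window((5, 12), 31)
        run = _oracle_longest_seed_run(d.original, d.recoded, lo, hi)
        assert (predict_escape(d) == "ESCAPES") == (run >= 3)


class TestReferenceComparison:
    def test_reference_report_structure(self):
        # synthetic stand-in genome with soc/dnap-named genes; the real
        # comparison uses a locally supplied T4 GenBank record
        g = make_toy_phage(FixtureSpec(seed=5, n_genes=3))
        g.features[0].gene_id = "soc"
        g.features[2].gene_id = "43"
        report = table1_reference(g)
        assert set(report) == set(TABLE1_REFERENCE_SNPS)
        for key, row in report.items():
            assert row["reference_snps"] == TABLE1_REFERENCE_SNPS[key]
            assert row["package_snps"] >= 0
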