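# phagedit

Design and quantification toolkit for **Cas13a-counterselected
bacteriophage genome engineering** in *E. coli*.

Type VI CRISPR effectors such as LbuCas13a recognise phage *transcripts*
rather than DNA: a crRNA (direct repeat + 31-nt spacer) base-pairs with a
protospacer on a phage mRNA and triggers abortive infection, restricting
plaque formation by ~10⁵–10⁶-fold without any PAM/PFS constraint. Because
only the transcript sequence matters, any phage edit that disrupts the
protospacer — a gene deletion, a multi-gene deletion or even a few silent
SNPs — lets the edited genome escape counterselection. Two infection
steps (homologous recombination on an editing strain, then enrichment on
a Cas13a counterselection strain) therefore turn a rare recombinant into
essentially the whole population, markerlessly. `phagedit` is the desk
half of that workflow, for phage biologists who design the constructs and
quantify the plaque assays:

* **Spacer design** — 31-nt crRNA spacers against predicted phage
  transcripts: CDS-start (default), RBS window (−4 to −6 relative to the
  start codon), mid-CDS, and junction-spanning deletion-verification
  guides (0–15 nt past the deletion's 3′ end); RFP non-targeting
  control; host off-target and crRNA hairpin QC flags.
* **Silent recoding** — synonymous protospacer recoding at three scopes
  (single codon `-C`, seed region `-S`, full protospacer `-F`),
  maximising nucleotide changes while avoiding rare codons (*E. coli*
  K-12 usage table shipped), with an advisory escape prediction based on
  contiguous seed-region changes.
* **HR donor design** — 250 bp-arm deletion donors that retain native
  start/stop codons around a verification primer-binding cassette,
  coordinate-span deletion donors with removed/truncated gene reports,
  and 52-nt-arm recoding donors; BsaI/BbsI golden-gate oligo and
  fragment emission with overhangs derived from enzyme cut geometry.
* **In-silico verification** — apply a donor to the genome
  (`apply_edit`) and check which spacers are DISRUPTED/INTACT
  (`verify_escape`).
* **Assay quantification** — serial-dilution titres with the
  lysis-from-without upper-bound rule, EOP
  (`mean pfu_condition / mean pfu_control`), editing penetrance
  (`pfu_enrichment / pfu_negative`, averaged over editing attempts), and
  MOI arithmetic.
* **Enrichment simulator** — a small passage model,
  `f′ = f / (f + (1 − f)·p_escape)`, to sanity-check penetrance
  expectations.

## Worked example

Generate a toy annotated phage genome, design a spacer against gene
`degA`, recode its full protospacer, and simulate enrichment:

```sh
$ phagedit fixtures make --seed 1 --outdir demo
wrote toyphage_seed1: 1480 bp, 4 genes

$ phagedit design spacer --genome demo/toyphage_seed1.gb --gene degA
gene  mode       start  end  strand  spacer                           protospacer ...
degA  CDS_START  321    351  +       AGCCGCCTGCGGTCAGCAGAACAACGGTCAT  ATGACCGTTGTTCTGCTGACCGCAGGCGGCT ...
```

The spacer is the 31-nt reverse complement of the first 31 nt of the
`degA` transcript (coordinates are 1-based inclusive).

```sh
$ phagedit design recode --genome demo/toyphage_seed1.gb --gene degA --mode F
{
  "gene": "degA",
  "mode": "F",
  "original": "ATGACCGTTGTTCTGCTGACCGCAGGCGGCT",
  "recoded":  "ATGACGGTGGTGTTATTAACGGCGGGTGGTT",
  "snp_count": 11,
  "escape_prediction": "AT_RISK",
  "warnings": []
}
```

Eleven silent SNPs disrupt the protospacer while the encoded peptide is
unchanged. The escape call is advisory: this window's codons only permit
scattered (non-contiguous) seed changes, the situation observed to be
risky for evading Cas13a during infection.

```sh
$ phagedit quant eop --condition 1e3,2e3,1.5e3 --control 1e8,0.8e8,1.2e8
{ "eop": 1.5e-05, "fold_restriction": 66666.7, ... }

$ phagedit simulate --f0 0.001 --escape 1e-5 --passages 2
passage  edited_fraction
0        0.001
1        0.990108812958544
2        0.99999990010001
```

An EOP of 1.5 × 10⁻⁵ is a ~10⁵-fold restriction. In the passage model, a
0.1 % edited population jumps to ~99 % after one counterselection
passage when wildtype escape is rare (10⁻⁵) — the regime the two-step
editing workflow exploits.

With a locally supplied T4 GenBank record,
`phagedit.recoding.table1_reference` reports this package's soc/dnap
`-C/-S/-F` SNP counts side-by-side with the published reference designs
(1, 3, 11, 3, 5, 9); exact agreement is not expected because the
published codon choices are under-specified.

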