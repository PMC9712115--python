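# Methods

This note records the models, conventions, defaults and known
limitations behind `phagedit`, in the order a design flows through the
package.

## Coordinates and genome model

Internally every interval is 0-based half-open on the top strand;
everything user-facing (CLI, reports, coordinate tables) is 1-based
inclusive. The inclusive convention is what phage coordinate spans use
in practice — a span reported as 165,257–168,510 has length
168,510 − 165,257 + 1 = 3,254 bp — and `span_length` implements exactly
that arithmetic. Sequences are uppercased on load; only A/C/G/T/N are
accepted (IUPAC ambiguity codes other than N are rejected with an
explicit error, since a design over an ambiguous base would be
meaningless). N is tolerated in a genome but disqualifies any design
window containing it. Topology defaults to linear; circular records
support wrap-around slicing. Annotations must be supplied (GenBank
features or a TSV coordinate table for FASTA input); there is no gene
prediction. Each annotated CDS, plus optional flanks, is treated as the
targetable transcript — operon structure is not modelled, which matters
only if a target must be restricted to a transcribed region boundary.

## Spacer design

Cas13a/Cas13d spacers are modelled as DNA strings of configurable
length (default 31 nt), antisense to the transcript: the protospacer is
the transcript-sense window, the spacer its reverse complement. Modes:

* **CDS-start** (default): protospacer = first 31 nt of the CDS.
* **RBS**: window starts at offset −4…−6 relative to the A of the start
  codon (position 1), covering the ribosome-binding region.
* **Custom**: any transcript offset (e.g. mid-CDS targets).
* **Deletion-verify**: the window *ends* 0–15 nt past the deleted
  interval's transcript-sense 3′ end, so it always straddles the
  wildtype deletion junction. This is the one way a "0–15 nt downstream"
  guide can both target the wildtype locus and be destroyed by the edit,
  which is its entire purpose; a window placed fully downstream would
  survive the deletion and verify nothing.
* **Non-targeting**: the RFP control spacer constant.

No PFS/anti-tag or thermodynamic scoring is attempted (LbuCas13a has no
PAM requirement, and folding models would add a dependency without an
oracle to test against). QC is deliberately flag-only:

* **Off-target**: longest exact substring shared between the
  protospacer (either strand) and a host genome, found by binary search
  over k-mer length (exact-match length is monotone). Default flag
  threshold 15 nt — half-spacer identity as a conservative proxy for
  cross-reactivity; the threshold used for the original manual designs
  is not recoverable, so this is a package default, not a fact.
* **Hairpin**: longest perfect Watson–Crick stem closable
  with a loop ≥ 3 nt, by an O(n²) run-length DP over antiparallel base
  pairs, validated against an O(n³) exhaustive oracle. Defaults
  min_stem = 8 bp, min_loop = 3 nt, no wobble pairs: a simple,
  testable proxy for the self-complementary crRNA fold observed to be
  toxic. The direct repeat is effector-specific and not shipped; when
  absent the screen degrades to the spacer alone.

## Silent recoding

The protospacer must lie inside an annotated CDS in known frame. Scope
windows: `-C` a single codon, `-S` the seed region, `-F` the full
protospacer. The seed default is spacer positions 5–12 (1-based from
the spacer 5′ end; spacer position *k* pairs protospacer position
L − k + 1, so on a 31-mer the seed maps to protospacer positions
20–27). This window is a documented assumption taken from in-vitro
mismatch-sensitivity precedent, configurable per effector.

Codons partially overlapping the scope are eligible but must keep their
out-of-scope bases, so flanking context (which doubles as recombination
homology) is never altered. Per codon, the synonymous candidate with
relative usage ≥ 0.10 maximising in-scope nucleotide changes is chosen;
ties break to higher usage, then lexicographically (determinism for
testing). If the rarity rule makes a codon immutable, the best rare
synonym is used and a warning recorded. Because codons are independent,
the per-codon maximum equals the exhaustive optimum over all synonymous
combinations — the test suite verifies this against a literal product
enumeration on small windows. `-C` picks the codon admitting the most
silent changes, ties toward the protospacer 5′ end; on a window of only
ATG/TGG codons it raises ("no silent change possible") while `-S`/`-F`
degrade to a warning. The shipped usage table is a standard *E. coli*
K-12 relative-synonymous-usage table (two-decimal fractions, each
amino-acid family summing to 1.00).

`predict_escape` is advisory: a design ESCAPES when ≥ 3 *contiguous*
substitutions fall inside the seed window, else AT_RISK. Three is the
smallest threshold consistent with the published outcome pattern
(single-SNP and scattered-seed designs failed enrichment; a
three-contiguous-SNP single-codon design succeeded). Reference SNP
counts for the published soc/dnap series are carried as data
(`table1_reference`) for side-by-side reporting only — the codon and
rarity choices behind them are under-specified, so they are a
comparison point, not a target.

## Donor design and golden gate

Gene-deletion donors take `arm_len` = 250 bp arms in transcript
orientation: the UP arm ends with the start codon, the DN arm begins
with the stop codon, and the constant 32-nt verification primer-binding
cassette sits between them (in transcript orientation; the published
cassette orientation is unstated, so this is the package's choice). The
edit interval is the CDS interior (codon 2 through the base before the
stop). Span-deletion donors flank an arbitrary 1-based inclusive span
and report genes fully contained (removed) versus breakpoint-overlapping
(truncated). Recoding donors take 52-nt wildtype flanks around the
protospacer with the recoded protospacer as payload.

Donors are stored in transcript orientation so the start/stop invariants
hold literally; the orientation flag records the mapping to the genome
top strand (`top_strand_sequence` emits the flipped form), and
`apply_edit` accepts either orientation. Arms are located by exact,
unique string match — near-matching arms are out of scope, and
ambiguous or inverted matches are hard errors. Features downstream of a
length-changing edit are shifted; features overlapping it are dropped
(same-length recodes keep their features).

Type IIS chemistry is simulated from first principles: BsaI
(GGTCTC, cut N1/N5) and BbsI (GAAGAC, N2/N6) leave 4-nt 5′ overhangs.
Destination overhangs for spacer cloning are *derived* by digesting the
shipped dropout placeholder
(`aaacAGAGACCTCGTTTACCTATCGGTCTCatgct`) rather than transcribed from
annotation: the geometry yields AAAC (left) and TGCT (right), so spacer
oligos are `AAAC + spacer` / `AGCA + revcomp(spacer)`. Donor fragments
carry the 5′-TATC top overhang and the bottom-strand 5′-TCCT overhang
complementary to the vector's AGGA end. Ligation is modelled on duplex
fragments with explicit top/bottom strand extents; junctions must pair
exactly, and correct assemblies retain no recognition site — internal
sites already present in a donor core are reported as domestication
warnings instead (synthetic arms can contain one by chance, exactly as
real phage homology can).

## Assay quantification

Titres: the least-diluted spot with a countable count (default window
1–50 plaques per 2 µl spot — the countable window is unstated in
practice and configurable here) gives
pfu/ml = count / (volume_ml × dilution). Clearing without discrete
plaques is lysis from without: the estimate becomes an explicit upper
bound of 1 p.f.u. at the most concentrated plaque-free dilution, never
an NA. All-TNTC series raise ("increase dilution"); all-empty series
return 0 with a below-detection flag.

EOP aggregates by the printed formula — mean p.f.u. before the ratio —
while penetrance averages per-replicate ratios across independent
editing attempts (mean ± sample s.d.; zero-denominator replicates are
excluded with a warning). MOI arithmetic is exact:
pfu = cfu × moi; a 10× dilution series added at fixed volume gives
MOI_i = stock × 10⁻ⁱ × volume / cfu. No hypothesis testing is provided
beyond mean ± s.d.

## Enrichment passage model

A package-invented sanity check, not a result: per passage every edited
virion infects productively, a wildtype virion escapes with probability
*p*, and both amplify identically (so amplification cancels in the
fraction and the expectation obeys f′ = f / (f + (1 − f)p)). The
stochastic mode draws survivor counts binomially at an explicit
population size (default 10⁵ virions per passage; the field is needed
for sampling even though it cancels in expectation). The model omits
burst-size dynamics, within-host MOI structure and de-novo escape
mutation; it reproduces the qualitative percent-to-near-100 % jump of a
single enrichment passage and nothing more.

## Synthetic fixtures

`make_toy_phage` builds small linear genomes (default 4 genes of
90–150 nt on mixed strands, 60–120 nt intergenic gaps, 320 nt end
margins so 250 bp arms always fit) with codons sampled from the shipped
usage table, guaranteed stop-free ORFs, one gene opening with a run of
4-fold/6-fold-degenerate codons (`degA`, recoding-friendly) and one
ATG/TGG-rich gene (`stiffB`, recoding-hostile). Host decoys are random
sequences with an optionally embedded k-mer at a reported position.
Everything is driven by an explicit seed; same spec + seed gives
byte-identical files. These fixtures exercise coordinate, frame,
strand and chemistry logic; they say nothing about real-genome scale,
repeat content, operon structure or actual recombination/escape rates,
so passing tests demonstrate correctness of the design arithmetic, not
wet-lab outcomes.

## Problem sizes and determinism

The test and acceptance workloads are sized for a laptop-scale run:
1,000 random recodings for the silence invariant, 200 brute-force QC
oracle comparisons, 100 random donors for scarlessness, 100 random
deletion designs for the edit→verify pipeline, and 10⁴ replicates for
the stochastic/closed-form agreement (3 standard errors). All
randomness flows from explicit seeds; `scripts/acceptance.py --seed`
seeds every stream and its non-stochastic outputs are identical across
seeds.

## Known limitations

* Exact-match arm location and protospacer verification only; a single
  mismatch in an arm is "not found", and `verify_escape` treats a
  1-SNP recode as DISRUPTED even though such an edit is biologically
  AT_RISK — the two calls are deliberately separate.
* No mRNA folding, codon-pair or expression-level modelling in
  recoding; no primer Tm or vendor-constraint checks in donor design.
* The direct repeat, the in-vivo seed window and the published designs'
  exact codon choices are configuration/reference data, not derivable
  facts; defaults are documented above.
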