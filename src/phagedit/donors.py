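"""Homologous-recombination donor design, golden-gate emission and
in-silico edit verification.

Three donor kinds are supported:

* ``GENE_DELETION`` — 250 bp arms (default) flanking a CDS interior, with
  the native start and stop codons retained (the UP arm ends with the
  start codon, the DN arm begins with the stop codon) and a constant
  verification primer-binding cassette between them;
* ``SPAN_DELETION`` — arms flanking an arbitrary coordinate span
  (reported 1-based inclusive), e.g. a multi-gene deletion;
* ``RECODE`` — 52-nt arms (default) flanking a protospacer, with the
  silently recoded protospacer as payload.

Donor sequences are stored in the orientation of the edited transcript
(so the start/stop invariants read literally); the recorded orientation
flag says how that maps onto the genome's top strand, and apply_edit
accepts either orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .genome import (
    AnnotatedGenome,
    GeneFeature,
    GenomeError,
    GenomeInterval,
    revcomp,
    span_length,
    to_internal,
    transcript_sequence,
    STOP_CODONS,
)
from .goldengate import (
    BBSI_DONOR_OVERHANGS,
    BSAI_SPACER_DROPOUT,
    AssemblyError,
    Fragment,
    cut_boundaries,
    domestication_warnings,
    find_sites,
)
from .recoding import RecodeDesign
from .spacers import SpacerDesign

#: Constant primer-binding site inserted between deletion-donor arms so a
#: single primer pair verifies any edit.
VERIFICATION_CASSETTE = "GATAAGAGACGGCTCAACGCCCGTCTCACAGC"

DONOR_KINDS = ("GENE_DELETION", "SPAN_DELETION", "RECODE")


class DonorError(ValueError):
    """Donor design or edit application that cannot be satisfied."""


@dataclass
class DonorDesign:
    kind: str
    up_arm: str
    payload: str
    dn_arm: str
    edit: GenomeInterval  # genome interval removed/replaced
    arm_len: int
    orientation: str = "+"  # strand of the donor sequence vs the genome top strand
    gene_id: Optional[str] = None
    removed_genes: list[str] = field(default_factory=list)
    truncated_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in DONOR_KINDS:
            raise DonorError(f"unknown donor kind {self.kind!r}")
        if len(self.up_arm) != self.arm_len or len(self.dn_arm) != self.arm_len:
            raise DonorError("homology arms must match the configured arm length")

    @property
    def sequence(self) -> str:
        return self.up_arm + self.payload + self.dn_arm

    @property
    def top_strand_sequence(self) -> str:
        """Donor 5'->3' on the genome's top strand."""
        return self.sequence if self.orientation == "+" else revcomp(self.sequence)


def design_gene_deletion_donor(
    genome: AnnotatedGenome,
    gene_id: str,
    arm_len: int = 250,
    cassette: str = VERIFICATION_CASSETTE,
) -> DonorDesign:
    """Deletion donor removing a CDS interior while retaining the native
    start and stop codons, with the verification cassette between the arms."""
    f = genome.feature(gene_id)
    if f.kind != "CDS":
        raise DonorError(f"{gene_id} is not a CDS")
    if len(f) < 9:
        raise DonorError(f"{gene_id} is shorter than 3 codons; nothing to delete")
    m = len(f)
    # transcript coordinates: arms end at the start codon / begin at the stop
    flank = arm_len - 3
    if flank < 0:
        raise DonorError("arm length must be at least one codon")
    try:
        extended = transcript_sequence(genome, gene_id, upstream=flank, downstream=flank)
    except GenomeError as exc:
        raise DonorError(f"insufficient flank for {arm_len} bp arms: {exc}") from exc
    up_arm = extended[:arm_len]  # ends with the start codon
    dn_arm = extended[flank + m - 3 : flank + m - 3 + arm_len]  # begins with the stop
    edit = GenomeInterval(f.start + 3, f.end - 3, f.strand)  # CDS interior
    return DonorDesign(
        kind="GENE_DELETION",
        up_arm=up_arm,
        payload=cassette,
        dn_arm=dn_arm,
        edit=edit,
        arm_len=arm_len,
        orientation=f.strand,
        gene_id=gene_id,
    )


def design_span_deletion_donor(
    genome: AnnotatedGenome,
    start: int,
    end: int,
    arm_len: int = 250,
    cassette: str = VERIFICATION_CASSETTE,
) -> DonorDesign:
    """Deletion donor for a 1-based inclusive coordinate span; reports genes
    fully removed and genes truncated at the breakpoints."""
    s0, e0 = to_internal(start, end)
    if e0 > len(genome):
        raise DonorError(f"span ({start}, {end}) out of bounds")
    if s0 - arm_len < 0 or e0 + arm_len > len(genome):
        raise DonorError(f"insufficient flank for {arm_len} bp arms")
    up_arm = genome.sequence[s0 - arm_len : s0]
    dn_arm = genome.sequence[e0 : e0 + arm_len]
    removed = [f.gene_id for f in genome.features if s0 <= f.start and f.end <= e0]
    truncated = [
        f.gene_id
        for f in genome.features
        if (f.start < s0 < f.end) or (f.start < e0 < f.end)
    ]
    return DonorDesign(
        kind="SPAN_DELETION",
        up_arm=up_arm,
        payload=cassette,
        dn_arm=dn_arm,
        edit=GenomeInterval(s0, e0, "+"),
        arm_len=arm_len,
        orientation="+",
        removed_genes=removed,
        truncated_genes=truncated,
    )


def design_recode_donor(
    genome: AnnotatedGenome, design: RecodeDesign, arm_len: int = 52
) -> DonorDesign:
    """Recoding donor: the recoded protospacer flanked by wildtype homology."""
    f = genome.feature(design.gene_id)
    iv = design.target
    off = iv.start - f.start if f.strand == "+" else f.end - iv.end
    L = len(design.original)
    try:
        up_start = off - arm_len
        upstream_needed = max(0, -up_start)
        downstream_needed = max(0, off + L + arm_len - len(f))
        ext = transcript_sequence(
            genome, design.gene_id, upstream=upstream_needed, downstream=downstream_needed
        )
    except GenomeError as exc:
        raise DonorError(f"insufficient flank for {arm_len} nt arms: {exc}") from exc
    shift = upstream_needed
    up_arm = ext[shift + off - arm_len : shift + off]
    dn_arm = ext[shift + off + L : shift + off + L + arm_len]
    if len(up_arm) != arm_len or len(dn_arm) != arm_len:
        raise DonorError(f"insufficient flank for {arm_len} nt arms")
    return DonorDesign(
        kind="RECODE",
        up_arm=up_arm,
        payload=design.recoded,
        dn_arm=dn_arm,
        edit=iv,
        arm_len=arm_len,
        orientation=f.strand,
        gene_id=design.gene_id,
    )


# ---------------------------------------------------------------------------
# Golden-gate emission


@dataclass
class OligoPair:
    """Annealable spacer duplex with 4-nt 5' overhangs."""

    top: str
    bottom: str
    overhangs: tuple[str, str]  # destination overhang regions, top-coordinate

    def fragment(self) -> Fragment:
        return Fragment.from_oligos(self.top, self.bottom)


def destination_overhangs(dropout: str, enzyme: str = "BsaI") -> tuple[str, str]:
    """Derive the destination overhangs by simulating digestion geometry on
    a dropout placeholder carrying two opposing recognition sites."""
    sites = find_sites(dropout, enzyme)
    if len(sites) != 2 or {o for _, o in sites} != {"+", "-"}:
        raise AssemblyError(
            f"dropout must contain exactly two opposing {enzyme} sites, "
            f"found {sites}"
        )
    (left_top, left_bottom), (right_top, right_bottom) = cut_boundaries(dropout, enzyme)
    s = dropout.upper()
    return s[left_top:left_bottom], s[right_top:right_bottom]


def emit_spacer_oligos(
    spacer: SpacerDesign, dropout: str = BSAI_SPACER_DROPOUT
) -> OligoPair:
    """Spacer duplex oligos whose 5' overhangs complement the BsaI-digested
    destination's staggered ends (overhangs derived from cut geometry)."""
    left, right = destination_overhangs(dropout, "BsaI")
    return OligoPair(
        top=left + spacer.spacer,
        bottom=revcomp(right) + revcomp(spacer.spacer),
        overhangs=(left, right),
    )


@dataclass
class GoldenGateFragment:
    """A donor insert with explicit 4-nt 5' overhangs at both ends."""

    core: str
    enzyme: str
    left_overhang: str  # top-strand 5' extension
    right_overhang: str  # bottom-strand 5' extension (5'->3')
    destination: tuple[str, str]
    warnings: list[str] = field(default_factory=list)

    @property
    def top(self) -> str:
        return self.left_overhang + self.core

    @property
    def bottom(self) -> str:
        return self.right_overhang + revcomp(self.core)

    def fragment(self) -> Fragment:
        return Fragment.from_oligos(self.top, self.bottom)


def emit_donor_fragment(
    donor: DonorDesign, overhangs: tuple[str, str] = BBSI_DONOR_OVERHANGS
) -> GoldenGateFragment:
    """BbsI golden-gate insert for the RFP-dropout HR entry vector: left
    overhang TATC, right end complementary to the vector's AGGA overhang.
    Internal BsaI/BbsI sites are reported as domestication warnings."""
    left, vector_right = overhangs
    core = donor.sequence
    return GoldenGateFragment(
        core=core,
        enzyme="BbsI",
        left_overhang=left,
        right_overhang=revcomp(vector_right),
        destination=(revcomp(left), vector_right),
        warnings=domestication_warnings(core),
    )


def simulate_vector_ligation(
    fragment: GoldenGateFragment, vector_left: str, vector_right: str
) -> str:
    """Top strand of the insert ligated between vector ends presenting the
    destination overhangs (vector_left ends just before the insert's left
    overhang region; vector_right begins with the vector's top-strand
    overhang)."""
    return vector_left + fragment.top + vector_right


# ---------------------------------------------------------------------------
# Edit application and verification


def _find_unique(haystack: str, needle: str) -> int:
    first = haystack.find(needle)
    if first == -1:
        return -1
    if haystack.find(needle, first + 1) != -1:
        raise DonorError("homology arm found at multiple loci")
    return first


def apply_edit(genome: AnnotatedGenome, donor: DonorDesign) -> AnnotatedGenome:
    """Apply a donor edit in silico: locate both arms (exact, unique, either
    orientation), replace the intervening sequence with the payload, and
    shift downstream feature coordinates."""
    seq = genome.sequence
    for up, payload, dn in (
        (donor.up_arm, donor.payload, donor.dn_arm),
        (revcomp(donor.dn_arm), revcomp(donor.payload), revcomp(donor.up_arm)),
    ):
        i = _find_unique(seq, up)
        j = _find_unique(seq, dn)
        if i == -1 or j == -1:
            continue
        if j < i + len(up):
            raise DonorError("homology arms found in inverted order")
        edit_start = i + len(up)
        edit_end = j
        new_seq = seq[:edit_start] + payload + seq[edit_end:]
        delta = len(payload) - (edit_end - edit_start)
        feats = []
        for f in genome.features:
            if f.end <= edit_start:
                feats.append(f)
            elif f.start >= edit_end:
                feats.append(
                    GeneFeature(
                        f.gene_id, f.start + delta, f.end + delta, f.strand, f.kind, f.partial
                    )
                )
            elif delta == 0:
                feats.append(f)  # same-length replacement keeps the feature
            # length-changing edits drop features overlapping the window
        return AnnotatedGenome(
            id=f"{genome.id}_edited",
            sequence=new_seq,
            topology=genome.topology,
            features=feats,
        )
    raise DonorError("homology arm not found in genome")


def verify_escape(
    edited: AnnotatedGenome, spacers: list[SpacerDesign]
) -> dict[str, str]:
    """Per-spacer call: DISRUPTED iff the exact protospacer no longer occurs
    in the edited genome on either strand, else INTACT. An editing plan is
    valid when enrichment and verification spacers are DISRUPTED and the
    positive control stays INTACT."""
    seq = edited.sequence
    out = {}
    for i, sp in enumerate(spacers):
        present = sp.protospacer in seq or revcomp(sp.protospacer) in seq
        key = sp.gene_id or f"{sp.mode}_{i}"
        out[key] = "INTACT" if present else "DISRUPTED"
    return out


def deletion_report(donor: DonorDesign) -> dict:
    """1-based summary of a deletion donor for user-facing output."""
    s1, e1 = donor.edit.one_based
    return {
        "kind": donor.kind,
        "start": s1,
        "end": e1,
        "deletion_length": span_length(s1, e1),
        "removed_genes": donor.removed_genes,
        "truncated_genes": donor.truncated_genes,
    }
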