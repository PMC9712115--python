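"""Cas13 crRNA spacer design against phage transcripts.

Cas13a/Cas13d guides are RNA-targeting: the spacer is the reverse
complement of a window of the (predicted) transcript, here expressed in
DNA alphabet. The default spacer length is 31 nt. Four targeting modes
are supported:

* ``CDS_START`` — the first 31 nt of a CDS transcript (the default mode);
* ``RBS`` — a window starting at position -4 to -6 relative to the A of
  the start codon, covering the ribosome-binding region;
* ``CUSTOM`` — any transcript offset (e.g. mid-CDS);
* ``DELETION_VERIFY`` — a guide spanning a deletion junction, extending
  0-15 nt past the deleted interval's transcript-sense 3' end so the
  wildtype locus is targeted but the designed edit disrupts the site;
* ``NON_TARGETING`` — the RFP control spacer, carrying no genome target.

QC is advisory (flags, never hard failures): longest exact host match
(off-target proxy) and longest perfect hairpin stem in the mature crRNA
(self-complementarity proxy for the toxic fold observed with some
verification guides).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .genome import (
    AnnotatedGenome,
    GeneFeature,
    GenomeError,
    GenomeInterval,
    revcomp,
    transcript_window_to_genome,
)

#: Non-targeting negative-control spacer directed at an RFP transcript
#: absent from phage infections.
RFP_SPACER = "AACTCTTTGATAACGTCTTCGCTACTCGCCA"

MODES = ("CDS_START", "RBS", "CUSTOM", "DELETION_VERIFY", "NON_TARGETING")


class DesignError(ValueError):
    """Spacer design request that cannot be satisfied."""


@dataclass
class SpacerDesign:
    """A designed crRNA spacer and the protospacer it targets.

    ``protospacer`` is transcript-sense; ``spacer`` is its reverse
    complement (the sequence carried by the crRNA, DNA alphabet).
    """

    spacer: str
    protospacer: str
    mode: str
    gene_id: Optional[str] = None
    target: Optional[GenomeInterval] = None
    offtarget_flag: bool = False
    offtarget_len: int = 0
    hairpin_flag: bool = False
    hairpin_stem: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise DesignError(f"unknown mode {self.mode!r}")
        if self.spacer != revcomp(self.protospacer):
            raise DesignError("spacer must be the reverse complement of the protospacer")
        if self.mode == "NON_TARGETING" and self.target is not None:
            raise DesignError("non-targeting designs carry no genome interval")
        if self.target is not None and len(self.target) != len(self.spacer):
            raise DesignError("target interval length must equal spacer length")

    def __len__(self) -> int:
        return len(self.spacer)


@dataclass
class MatureCrRNA:
    """Direct repeat + spacer. The repeat is effector-specific and must be
    supplied by the user (it is a required configuration value)."""

    repeat: str
    spacer: str
    full: str = field(init=False)

    def __post_init__(self) -> None:
        self.full = self.repeat + self.spacer


def _window_protospacer(
    genome: AnnotatedGenome, feature: GeneFeature, a: int, b: int
) -> tuple[str, GenomeInterval]:
    iv = transcript_window_to_genome(feature, a, b)
    if genome.topology == "linear" and (iv.start < 0 or iv.end > len(genome)):
        raise DesignError(
            f"design window out of bounds for gene {feature.gene_id} on linear genome"
        )
    proto = genome.interval_sequence(iv)
    if "N" in proto:
        raise DesignError(
            f"design window for gene {feature.gene_id} contains N; pick another window"
        )
    return proto, iv


def design_custom_spacer(
    genome: AnnotatedGenome,
    gene_id: str,
    transcript_offset: int,
    spacer_len: int = 31,
    mode: str = "CUSTOM",
) -> SpacerDesign:
    """Spacer whose protospacer starts at ``transcript_offset`` (0 = first
    base of the start codon; negative = upstream) on the gene's transcript."""
    f = genome.feature(gene_id)
    proto, iv = _window_protospacer(
        genome, f, transcript_offset, transcript_offset + spacer_len
    )
    return SpacerDesign(
        spacer=revcomp(proto), protospacer=proto, mode=mode, gene_id=gene_id, target=iv
    )


def design_cds_start_spacer(
    genome: AnnotatedGenome, gene_id: str, spacer_len: int = 31
) -> SpacerDesign:
    """Default design: target the first ``spacer_len`` nt of the CDS."""
    f = genome.feature(gene_id)
    if len(f) < spacer_len:
        raise DesignError(
            f"CDS {gene_id} ({len(f)} nt) shorter than spacer length {spacer_len}"
        )
    return design_custom_spacer(genome, gene_id, 0, spacer_len, mode="CDS_START")


def design_rbs_spacer(
    genome: AnnotatedGenome, gene_id: str, offset: int, spacer_len: int = 31
) -> SpacerDesign:
    """RBS-mode design: protospacer begins ``offset`` nt relative to the
    start codon, with offset restricted to [-6, -4]."""
    if not -6 <= offset <= -4:
        raise DesignError(f"RBS offset must be in [-6, -4], got {offset}")
    d = design_custom_spacer(genome, gene_id, offset, spacer_len, mode="RBS")
    return d


def design_deletion_verify_spacer(
    genome: AnnotatedGenome,
    deleted: GenomeInterval,
    downstream_offset: int,
    spacer_len: int = 31,
) -> SpacerDesign:
    """Junction-spanning verification guide for a planned deletion.

    The protospacer window ends ``downstream_offset`` nt (0-15) past the
    deleted interval's transcript-sense 3' end, so it covers
    ``spacer_len - downstream_offset`` nt of to-be-deleted sequence plus the
    retained downstream flank: present in wildtype, destroyed by the edit.
    """
    if not 0 <= downstream_offset <= 15:
        raise DesignError(
            f"downstream offset must be in [0, 15], got {downstream_offset}"
        )
    if downstream_offset >= spacer_len:
        raise DesignError("offset must be smaller than the spacer length")
    if deleted.strand == "+":
        start = deleted.end + downstream_offset - spacer_len
        iv = GenomeInterval(start, start + spacer_len, "+")
    else:
        end = deleted.start - downstream_offset + spacer_len
        iv = GenomeInterval(end - spacer_len, end, "-")
    if genome.topology == "linear" and (iv.start < 0 or iv.end > len(genome)):
        raise DesignError("verification window out of bounds on linear genome")
    proto = genome.interval_sequence(iv)
    if "N" in proto:
        raise DesignError("verification window contains N")
    return SpacerDesign(
        spacer=revcomp(proto),
        protospacer=proto,
        mode="DELETION_VERIFY",
        gene_id=None,
        target=iv,
    )


def non_targeting_spacer(spacer: str = RFP_SPACER) -> SpacerDesign:
    """The RFP negative-control design: a functional spacer whose target
    transcript is absent from the experiment."""
    return SpacerDesign(
        spacer=spacer, protospacer=revcomp(spacer), mode="NON_TARGETING"
    )


# ---------------------------------------------------------------------------
# QC screens


def longest_host_match(protospacer: str, host_sequence: str) -> int:
    """Length of the longest exact substring shared between the protospacer
    (either strand) and the host genome sequence."""
    host = host_sequence.upper()
    if not host or not protospacer:
        return 0
    queries = (protospacer, revcomp(protospacer))

    def any_match(k: int) -> bool:
        seen = set()
        for q in queries:
            for i in range(len(q) - k + 1):
                seen.add(q[i : i + k])
        return any(kmer in host for kmer in seen)

    lo, hi, best = 1, len(protospacer), 0
    while lo <= hi:  # match length is monotone, so bisect
        mid = (lo + hi) // 2
        if any_match(mid):
            best = mid
            lo = mid + 1
        else:
            hi = mid - 1
    return best


def offtarget_screen(
    design: SpacerDesign, host: AnnotatedGenome, min_flag_match: int = 15
) -> SpacerDesign:
    """Flag a design whose protospacer shares an exact match of at least
    ``min_flag_match`` nt with the host genome (advisory, never a failure)."""
    match = longest_host_match(design.protospacer, host.sequence)
    return replace(
        design, offtarget_len=match, offtarget_flag=match >= min_flag_match
    )


def longest_hairpin_stem(seq: str, min_loop: int = 3) -> int:
    """Longest perfect Watson-Crick stem closable with a loop of at least
    ``min_loop`` nt, by dynamic programming over base-pair runs."""
    s = seq.upper()
    n = len(s)
    pair = {"A": "T", "T": "A", "C": "G", "G": "C"}
    best = 0
    # run[q] at iteration p = length of contiguous paired run ending at (p, q)
    run = [0] * n
    for p in range(n - 1, -1, -1):
        new = [0] * n
        for q in range(p + 1, n):
            if pair.get(s[p]) == s[q]:
                inner = run[q - 1] if q - 1 > p else 0
                new[q] = inner + 1
                # stem of length L pairs (p..p+L-1) with (q-L+1..q); valid if
                # the enclosed loop (q-L+1)-(p+L-1)-1 >= min_loop
                L = new[q]
                usable = min(L, (q - p + 1 - min_loop) // 2)
                if usable > best:
                    best = usable
        run = new
    return max(best, 0)


def hairpin_screen(
    crrna: MatureCrRNA | SpacerDesign,
    min_stem: int = 8,
    min_loop: int = 3,
) -> tuple[bool, int]:
    """Self-complementarity screen on the mature crRNA (repeat + spacer).

    When only a spacer is available (no direct repeat configured) the
    screen degrades gracefully to the spacer alone.
    """
    seq = crrna.full if isinstance(crrna, MatureCrRNA) else crrna.spacer
    stem = longest_hairpin_stem(seq, min_loop=min_loop)
    return stem >= min_stem, stem


def apply_hairpin_screen(
    design: SpacerDesign,
    repeat: Optional[str] = None,
    min_stem: int = 8,
    min_loop: int = 3,
) -> SpacerDesign:
    target = MatureCrRNA(repeat, design.spacer) if repeat else design
    flag, stem = hairpin_screen(target, min_stem=min_stem, min_loop=min_loop)
    return replace(design, hairpin_flag=flag, hairpin_stem=stem)
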