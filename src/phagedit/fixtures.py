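"""Deterministic synthetic phage genomes and host decoys.

Every designed sequence in the test suite comes from here: small
annotated "phage" genomes whose CDSs translate cleanly, carry mixed
strands, and include genes engineered for recoding edge cases (one
opening with a run of maximally degenerate codons, one packed with
non-degenerate ATG/TGG codons). Not a realistic phage simulator — no
promoters, terminators or operon structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from random import Random
from typing import Optional

from .genome import AnnotatedGenome, GeneFeature, revcomp, write_genome
from .recoding import GENETIC_CODE, default_usage_table


class FixtureError(ValueError):
    """Infeasible fixture specification."""


@dataclass
class FixtureSpec:
    seed: int = 0
    n_genes: int = 4
    gene_len_range: tuple[int, int] = (90, 150)  # nt, rounded to codons
    intergenic_range: tuple[int, int] = (60, 120)
    margin: int = 320  # flank at both genome ends (room for 250 bp arms)
    minus_strand_fraction: float = 0.4
    include_degenerate_gene: bool = True
    include_stiff_gene: bool = True
    host_len: int = 2000

    def __post_init__(self) -> None:
        if self.gene_len_range[0] < 45 or self.gene_len_range[0] > self.gene_len_range[1]:
            raise FixtureError("gene length range must be sane and allow >= 45 nt")
        if self.n_genes < 1:
            raise FixtureError("need at least one gene")


_SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")
#: codons whose amino acids have 4+ synonyms, for the degenerate test gene
_DEGENERATE_CODONS = ("CTG", "GTT", "TCT", "CCG", "ACC", "GCA", "CGT", "GGC")


def _weighted_codons(rng: Random, n: int) -> list[str]:
    usage = default_usage_table().usage
    weights = [usage[c] for c in _SENSE_CODONS]
    return rng.choices(_SENSE_CODONS, weights=weights, k=n)


def _random_gene(rng: Random, length_nt: int) -> str:
    n_codons = length_nt // 3
    if n_codons < 3:
        raise FixtureError("gene shorter than 3 codons")
    body = _weighted_codons(rng, n_codons - 2)
    return "ATG" + "".join(body) + rng.choice(("TAA", "TAG", "TGA"))


def _degenerate_gene(rng: Random, length_nt: int) -> str:
    """Gene opening with a run of maximally degenerate codons."""
    n_codons = length_nt // 3
    head = [rng.choice(_DEGENERATE_CODONS) for _ in range(min(12, n_codons - 2))]
    tail = _weighted_codons(rng, n_codons - 2 - len(head))
    return "ATG" + "".join(head + tail) + "TAA"


def _stiff_gene(rng: Random, length_nt: int) -> str:
    """Gene rich in non-degenerate codons (Met/Trp) for failure-mode tests."""
    n_codons = length_nt // 3
    head = [rng.choice(("ATG", "TGG")) for _ in range(min(12, n_codons - 2))]
    tail = _weighted_codons(rng, n_codons - 2 - len(head))
    return "ATG" + "".join(head + tail) + "TAA"


def _random_dna(rng: Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def make_toy_phage(spec: FixtureSpec) -> AnnotatedGenome:
    """Deterministic annotated toy phage genome (same spec + seed =>
    byte-identical output)."""
    rng = Random(spec.seed)
    chunks: list[str] = [_random_dna(rng, spec.margin)]
    features: list[GeneFeature] = []
    pos = spec.margin
    for i in range(spec.n_genes):
        lo, hi = spec.gene_len_range
        length = rng.randrange(lo // 3, hi // 3 + 1) * 3
        if i == 0 and spec.include_degenerate_gene:
            gene_seq, name = _degenerate_gene(rng, length), "degA"
        elif i == 1 and spec.include_stiff_gene:
            gene_seq, name = _stiff_gene(rng, length), "stiffB"
        else:
            gene_seq, name = _random_gene(rng, length), f"gene{i + 1}"
        strand = "-" if rng.random() < spec.minus_strand_fraction and i >= 2 else "+"
        genomic = revcomp(gene_seq) if strand == "-" else gene_seq
        chunks.append(genomic)
        features.append(
            GeneFeature(name, pos, pos + len(genomic), strand, kind="CDS")
        )
        pos += len(genomic)
        gap = rng.randrange(*spec.intergenic_range)
        chunks.append(_random_dna(rng, gap))
        pos += gap
    chunks.append(_random_dna(rng, spec.margin))
    return AnnotatedGenome(
        id=f"toyphage_seed{spec.seed}",
        sequence="".join(chunks),
        topology="linear",
        features=features,
    )


def write_toy_phage(spec: FixtureSpec, path: str | Path) -> AnnotatedGenome:
    genome = make_toy_phage(spec)
    write_genome(genome, path, format="genbank")
    return genome


def make_host_decoy(
    spec: FixtureSpec,
    embed: Optional[str] = None,
    embed_pos: Optional[int] = None,
) -> tuple[str, Optional[int]]:
    """Random host decoy sequence, optionally embedding a chosen k-mer
    (e.g. a protospacer) at a reported position for off-target tests."""
    rng = Random(spec.seed + 7919)  # decoupled from the phage stream
    seq = _random_dna(rng, spec.host_len)
    if not embed:
        return seq, None
    if len(embed) > spec.host_len:
        raise FixtureError("embedded k-mer longer than the decoy")
    if embed_pos is None:
        embed_pos = rng.randrange(0, spec.host_len - len(embed) + 1)
    seq = seq[:embed_pos] + embed.upper() + seq[embed_pos + len(embed) :]
    return seq, embed_pos
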