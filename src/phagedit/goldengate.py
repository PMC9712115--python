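"""Type IIS (golden-gate) digestion geometry and ligation simulation.

BsaI (GGTCTC, cuts N1/N5) and BbsI (GAAGAC, N2/N6) cleave outside their
recognition sites, leaving programmable 4-nt 5' overhangs. Because the
sites are excised with the dropout piece, correct assemblies carry no
residual recognition site: digestion/re-ligation is one-way (scarless).

Fragments are modelled as duplexes in top-strand coordinates: the top
strand covers ``[t0, t1)`` and the bottom strand covers top coordinates
``[b0, b1)``; whichever strand extends further at an end forms a 5'
overhang. Two ends anneal when their overhang regions carry identical
top-coordinate sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import revcomp

#: enzyme -> (recognition site, spacer nt to top-strand cut, overhang length)
ENZYMES = {
    "BsaI": ("GGTCTC", 1, 4),
    "BbsI": ("GAAGAC", 2, 4),
}

#: The BsaI crRNA-spacer dropout placeholder: two opposing BsaI sites whose
#: digestion reveals the destination overhangs for spacer duplex insertion.
BSAI_SPACER_DROPOUT = "aaacAGAGACCTCGTTTACCTATCGGTCTCatgct"

#: BbsI destination overhangs of the RFP-dropout HR entry vector: the left
#: vector end pairs a 5'-TATC insert overhang, the right vector end presents
#: a 5'-AGGA overhang pairing the insert's bottom-strand 5'-TCCT.
BBSI_DONOR_OVERHANGS = ("TATC", "AGGA")


class AssemblyError(ValueError):
    """Digestion or ligation request that is chemically impossible."""


def find_sites(seq: str, enzyme: str) -> list[tuple[int, str]]:
    """All recognition sites as (0-based position, orientation '+'|'-')."""
    site, _, _ = ENZYMES[enzyme]
    s = seq.upper()
    rc = revcomp(site)
    hits = []
    for i in range(len(s) - len(site) + 1):
        window = s[i : i + len(site)]
        if window == site:
            hits.append((i, "+"))
        if window == rc:
            hits.append((i, "-"))
    return sorted(hits)


def count_sites(seq: str, enzyme: str) -> int:
    return len(find_sites(seq, enzyme))


def cut_boundaries(seq: str, enzyme: str) -> list[tuple[int, int]]:
    """(top cut, bottom cut) boundaries, in top coordinates, per site."""
    site, spacer, ovh = ENZYMES[enzyme]
    k = len(site)
    cuts = []
    for pos, orient in find_sites(seq, enzyme):
        if orient == "+":
            top = pos + k + spacer
            bottom = top + ovh
        else:
            top = pos - spacer - ovh
            bottom = pos - spacer
        if top < 0 or bottom > len(seq):
            raise AssemblyError(
                f"{enzyme} site at {pos + 1} cuts outside the sequence"
            )
        cuts.append((top, bottom))
    return sorted(cuts)


@dataclass
class Fragment:
    """A duplex DNA fragment with possibly protruding 5' ends.

    ``seq`` is the top-strand reference over the union of both strands;
    top covers [t0, t1), bottom covers [b0, b1) of ``seq``'s coordinates.
    """

    seq: str
    t0: int
    t1: int
    b0: int
    b1: int

    @property
    def top(self) -> str:
        return self.seq[self.t0 : self.t1]

    @property
    def bottom(self) -> str:
        """Bottom strand, 5'->3'."""
        return revcomp(self.seq[self.b0 : self.b1])

    @property
    def left_overhang(self) -> str:
        """Single-stranded region at the left end (top-coordinate sequence)."""
        return self.seq[min(self.t0, self.b0) : max(self.t0, self.b0)]

    @property
    def right_overhang(self) -> str:
        return self.seq[min(self.t1, self.b1) : max(self.t1, self.b1)]

    @classmethod
    def from_oligos(cls, top_oligo: str, bottom_oligo: str, ovh: int = 4) -> "Fragment":
        """Annealed duplex of two oligos carrying ``ovh``-nt 5' overhangs."""
        top = top_oligo.upper()
        bottom = bottom_oligo.upper()
        core = top[ovh:]
        if revcomp(bottom[ovh:]) != core:
            raise AssemblyError("oligos do not anneal: cores are not complementary")
        seq = top + revcomp(bottom[:ovh])
        return cls(seq=seq, t0=0, t1=len(top), b0=ovh, b1=len(seq))

    @classmethod
    def blunt(cls, seq: str) -> "Fragment":
        return cls(seq=seq, t0=0, t1=len(seq), b0=0, b1=len(seq))


def digest(seq: str, enzyme: str) -> list[Fragment]:
    """Digest a linear duplex, returning fragments left to right."""
    cuts = cut_boundaries(seq, enzyme)
    tops = [0] + [c[0] for c in cuts] + [len(seq)]
    bottoms = [0] + [c[1] for c in cuts] + [len(seq)]
    s = seq.upper()
    return [
        Fragment(seq=s, t0=tops[i], t1=tops[i + 1], b0=bottoms[i], b1=bottoms[i + 1])
        for i in range(len(tops) - 1)
    ]


def ligate(fragments: list[Fragment]) -> str:
    """Join fragments in order through complementary 5' overhangs; returns
    the product's top strand."""
    if not fragments:
        raise AssemblyError("nothing to ligate")
    for a, b in zip(fragments, fragments[1:]):
        right = a.right_overhang
        left = b.left_overhang
        if right != left:
            raise AssemblyError(
                f"incompatible junction: {right or '(blunt)'} vs {left or '(blunt)'}"
            )
        # one end must protrude on the top strand and the other on the bottom
        if (a.t1 > a.b1) == (b.b0 > b.t0):
            raise AssemblyError("both overhangs are on the same strand")
    top = fragments[0].top
    for b in fragments[1:]:
        top += b.top
    return top


def residual_sites(product: str, enzymes: tuple[str, ...] = ("BsaI", "BbsI")) -> dict[str, int]:
    """Recognition-site census of an assembly product (0 everywhere for a
    correct golden-gate assembly)."""
    return {e: count_sites(product, e) for e in enzymes}


def domestication_warnings(core: str, enzymes: tuple[str, ...] = ("BsaI", "BbsI")) -> list[str]:
    """Internal recognition sites that would interfere with assembly,
    reported at 1-based positions."""
    out = []
    for e in enzymes:
        for pos, orient in find_sites(core, e):
            out.append(f"internal {e} site ({orient}) at position {pos + 1}")
    return out
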