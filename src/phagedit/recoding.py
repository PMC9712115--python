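"""Silent (synonymous) recoding of Cas13 protospacers.

A recoded homologous-recombination donor must (i) leave the encoded
protein untouched, (ii) change as many nucleotides inside the chosen
scope as possible so the edited transcript escapes crRNA recognition,
and (iii) avoid rare codons so the recoding itself is phenotypically
neutral. Three scopes are supported, mirroring the -C/-S/-F design
series:

* ``C`` — a single codon (by default the one admitting the most silent
  changes, ties resolved toward the protospacer 5' end);
* ``S`` — the seed region of the spacer (default spacer positions 5-12,
  a documented assumption configurable per effector);
* ``F`` — the full protospacer.

Codons only partially inside the scope are eligible, but substitutions
are restricted to in-scope positions; flanking context (which doubles as
recombination homology) is never touched. Codon choice is per-codon
exhaustive: because codons do not interact, the per-codon maximum equals
the global maximum over all synonymous combinations.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .genome import AnnotatedGenome, GenomeInterval, transcript_sequence
from .spacers import SpacerDesign

_STANDARD = unambiguous_dna_by_id[1]
#: codon -> amino acid (one letter; '*' for stop), standard genetic code
GENETIC_CODE = dict(_STANDARD.forward_table)
GENETIC_CODE.update({c: "*" for c in _STANDARD.stop_codons})
_SYNONYMS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in GENETIC_CODE.items():
    _SYNONYMS.setdefault(_aa, ())
for _codon, _aa in sorted(GENETIC_CODE.items()):
    _SYNONYMS[_aa] = _SYNONYMS[_aa] + (_codon,)


def synonyms(codon: str) -> tuple[str, ...]:
    """All codons encoding the same amino acid (including the input)."""
    return _SYNONYMS[GENETIC_CODE[codon]]


class RecodingError(ValueError):
    """Recoding request that cannot be satisfied silently."""


@dataclass
class CodonUsageTable:
    """Relative synonymous codon usage: fractions sum to 1 per family."""

    organism: str
    usage: dict[str, float]

    def __post_init__(self) -> None:
        families: dict[str, float] = {}
        for codon, frac in self.usage.items():
            if codon not in GENETIC_CODE:
                raise RecodingError(f"unknown codon {codon!r} in usage table")
            if not 0.0 <= frac <= 1.0:
                raise RecodingError(f"usage fraction for {codon} out of [0, 1]")
            families[GENETIC_CODE[codon]] = families.get(GENETIC_CODE[codon], 0.0) + frac
        for aa, total in families.items():
            if abs(total - 1.0) > 1e-6:
                raise RecodingError(
                    f"usage fractions for amino acid {aa!r} sum to {total}, not 1"
                )

    def __getitem__(self, codon: str) -> float:
        return self.usage[codon]

    @classmethod
    def from_tsv(cls, path: str | Path, organism: str = "") -> "CodonUsageTable":
        usage = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                usage[row["codon"].upper()] = float(row["fraction"])
        return cls(organism=organism or Path(path).stem, usage=usage)


def default_usage_table() -> CodonUsageTable:
    """The E. coli K-12 table shipped as package data."""
    ref = resources.files("phagedit.data") / "ecoli_k12_codon_usage.tsv"
    with resources.as_file(ref) as path:
        return CodonUsageTable.from_tsv(path, organism="E. coli K-12")


def seed_to_protospacer_window(
    seed_window: tuple[int, int], spacer_len: int
) -> tuple[int, int]:
    """Convert 1-based inclusive spacer positions to 0-based half-open
    protospacer positions. Spacer position 1 (its 5' end) base-pairs with
    the protospacer's 3'-most base."""
    lo, hi = seed_window
    if not 1 <= lo <= hi <= spacer_len:
        raise RecodingError(f"seed window {seed_window} outside spacer of length {spacer_len}")
    return spacer_len - hi, spacer_len - lo + 1


@dataclass
class CodonChange:
    codon_index: int  # 0-based, within the codon-aligned context
    old: str
    new: str
    positions: tuple[int, ...]  # changed positions, 0-based in the protospacer


@dataclass
class RecodeDesign:
    """A silent recoding of one protospacer."""

    mode: str  # C | S | F
    gene_id: str
    frame_offset: int  # 0|1|2: protospacer start within its codon
    original: str  # protospacer, transcript sense
    recoded: str  # same length
    changes: list[CodonChange]
    snp_count: int
    seed_window: tuple[int, int]  # spacer positions, 1-based inclusive
    target: GenomeInterval
    original_context: str = ""  # codon-aligned context covering the protospacer
    recoded_context: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.original) != len(self.recoded):
            raise RecodingError("recoded protospacer must keep its length")
        ham = sum(a != b for a, b in zip(self.original, self.recoded))
        if ham != self.snp_count:
            raise RecodingError("snp_count must equal the Hamming distance")


def _locate_in_cds(
    genome: AnnotatedGenome, design: SpacerDesign
) -> tuple[str, int]:
    """Return (gene_id, transcript offset of the protospacer start)."""
    if design.target is None:
        raise RecodingError("cannot recode a non-targeting design")
    iv = design.target
    for f in genome.features:
        if f.kind != "CDS" or f.strand != iv.strand:
            continue
        if f.start <= iv.start and iv.end <= f.end:
            off = iv.start - f.start if f.strand == "+" else f.end - iv.end
            return f.gene_id, off
    raise RecodingError(
        "protospacer does not lie within an annotated CDS on its strand"
    )


def _best_synonym(
    codon: str,
    in_scope: tuple[int, ...],
    table: CodonUsageTable,
    rare_threshold: float,
) -> tuple[str, int, bool]:
    """Pick the synonymous codon maximizing changes at in-scope positions.

    Positions outside ``in_scope`` must be preserved. Returns
    (codon, n_changes, used_rare_fallback). Preference order: non-rare
    codons by change count, then usage, then lexicographic; a rare codon
    is used only when no non-rare synonym changes anything.
    """
    candidates = []
    for alt in synonyms(codon):
        if any(alt[i] != codon[i] for i in range(3) if i not in in_scope):
            continue
        n = sum(alt[i] != codon[i] for i in in_scope)
        candidates.append((alt, n))
    non_rare = [(a, n) for a, n in candidates if table[a] >= rare_threshold]
    pool, fallback = (non_rare, False) if any(n > 0 for _, n in non_rare) else (candidates, True)
    best = max(pool, key=lambda c: (c[1], table[c[0]], [-ord(x) for x in c[0]]))
    if best[1] == 0:
        return codon, 0, False
    return best[0], best[1], fallback and best[1] > 0


def recode(
    genome: AnnotatedGenome,
    spacer: SpacerDesign,
    mode: str,
    table: Optional[CodonUsageTable] = None,
    rare_threshold: float = 0.10,
    seed_window: tuple[int, int] = (5, 12),
) -> RecodeDesign:
    """Silently recode the protospacer of ``spacer`` at the given scope."""
    if mode not in ("C", "S", "F"):
        raise RecodingError(f"mode must be C, S or F, got {mode!r}")
    if table is None:
        table = default_usage_table()
    gene_id, off = _locate_in_cds(genome, spacer)
    proto = spacer.protospacer
    L = len(proto)
    frame_offset = off % 3

    # codon-aligned context covering the protospacer
    first_codon = off // 3
    last_codon = (off + L - 1) // 3
    cds = transcript_sequence(genome, gene_id)
    context = cds[3 * first_codon : 3 * (last_codon + 1)]
    ctx_off = off - 3 * first_codon  # protospacer start within the context

    if mode == "F":
        scope = (0, L)  # protospacer positions, 0-based half-open
    elif mode == "S":
        scope = seed_to_protospacer_window(seed_window, L)
    else:
        scope = (0, L)  # candidate region; a single codon is chosen below

    def in_scope_positions(ci: int) -> tuple[int, ...]:
        """In-scope protospacer positions (0-based within codon) of codon ci."""
        out = []
        for i in range(3):
            p = 3 * ci + i - ctx_off  # protospacer coordinate
            if 0 <= p < L and scope[0] <= p < scope[1]:
                out.append(i)
        return tuple(out)

    n_codons = len(context) // 3
    picks: dict[int, tuple[str, int, bool]] = {}
    for ci in range(n_codons):
        pos = in_scope_positions(ci)
        if not pos:
            continue
        codon = context[3 * ci : 3 * ci + 3]
        picks[ci] = _best_synonym(codon, pos, table, rare_threshold)

    warnings: list[str] = []
    if mode == "C":
        # keep only the single codon with the most achievable silent changes,
        # ties resolved toward the protospacer 5' end (smallest index)
        best_ci = max(picks, key=lambda ci: (picks[ci][1], -ci), default=None)
        if best_ci is None or picks[best_ci][1] == 0:
            raise RecodingError(
                "no silent change possible in any protospacer codon (-C)"
            )
        picks = {best_ci: picks[best_ci]}

    recoded_ctx = list(context)
    changes: list[CodonChange] = []
    for ci in sorted(picks):
        new, n, fallback = picks[ci]
        if n == 0:
            continue
        old = context[3 * ci : 3 * ci + 3]
        positions = tuple(
            3 * ci + i - ctx_off for i in range(3) if new[i] != old[i]
        )
        recoded_ctx[3 * ci : 3 * ci + 3] = new
        changes.append(CodonChange(ci, old, new, positions))
        if fallback:
            warnings.append(
                f"codon {ci}: only rare synonyms available; used {new} "
                f"(usage {table[new]:.2f} < {rare_threshold:.2f})"
            )
    recoded_context = "".join(recoded_ctx)
    recoded = recoded_context[ctx_off : ctx_off + L]
    snp = sum(a != b for a, b in zip(proto, recoded))
    if mode in ("S", "F") and snp == 0:
        warnings.append("scope contains only non-degenerate codons; no change made")
    return RecodeDesign(
        mode=mode,
        gene_id=gene_id,
        frame_offset=frame_offset,
        original=proto,
        recoded=recoded,
        changes=changes,
        snp_count=snp,
        seed_window=seed_window,
        target=spacer.target,
        original_context=context,
        recoded_context=recoded_context,
        warnings=warnings,
    )


def predict_escape(
    design: RecodeDesign,
    seed_window: Optional[tuple[int, int]] = None,
    min_contiguous_seed_changes: int = 3,
) -> str:
    """Advisory escape call: ``ESCAPES`` when at least
    ``min_contiguous_seed_changes`` contiguous substitutions fall inside the
    seed window, else ``AT_RISK`` (single or scattered seed changes have been
    observed to be insufficient to evade Cas13a during infection)."""
    window = seed_window or design.seed_window
    lo, hi = seed_to_protospacer_window(window, len(design.original))
    changed = [
        lo <= p < hi and design.original[p] != design.recoded[p]
        for p in range(len(design.original))
    ]
    run = best = 0
    for c in changed:
        run = run + 1 if c else 0
        best = max(best, run)
    return "ESCAPES" if best >= min_contiguous_seed_changes else "AT_RISK"


#: Published reference SNP counts for the T4 soc/dnap design series (the
#: codon and rarity choices behind them are under-specified, so these are a
#: comparison point, not ground truth for the default algorithm).
TABLE1_REFERENCE_SNPS = {
    "soc-C": 1,
    "soc-S": 3,
    "soc-F": 11,
    "dnap-C": 3,
    "dnap-S": 5,
    "dnap-F": 9,
}


def table1_reference(
    genome: AnnotatedGenome,
    soc_gene: str = "soc",
    dnap_gene: str = "43",
    table: Optional[CodonUsageTable] = None,
) -> dict[str, dict[str, int]]:
    """Side-by-side SNP counts: this package's defaults vs the published
    reference designs, for a user-supplied T4 genome (not required for any
    test; run it when NC_000866.4 is available locally)."""
    from .spacers import design_cds_start_spacer

    out = {}
    for label, gene in (("soc", soc_gene), ("dnap", dnap_gene)):
        sp = design_cds_start_spacer(genome, gene)
        for mode in "CSF":
            d = recode(genome, sp, mode, table=table)
            key = f"{label}-{mode}"
            out[key] = {
                "package_snps": d.snp_count,
                "reference_snps": TABLE1_REFERENCE_SNPS[key],
            }
    return out
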