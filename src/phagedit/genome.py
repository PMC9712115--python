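"""Genome container with strand- and frame-aware coordinate services.

All internal coordinates are 0-based half-open on the top (plus) strand.
Everything user-facing (reports, CLI, coordinate tables) is 1-based
inclusive, the convention used throughout the phage-genetics literature:
a deletion reported as positions 165,257-168,510 spans
168,510 - 165,257 + 1 = 3,254 bp.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_CHARS = frozenset("ACGTN")
STOP_CODONS = ("TAA", "TAG", "TGA")


class GenomeError(ValueError):
    """Malformed genome input or invalid coordinate request."""


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def span_length(start: int, end: int) -> int:
    """Length in bp of a 1-based inclusive span, e.g. (165257, 168510) -> 3254."""
    if start > end:
        raise GenomeError(f"invalid span: start {start} > end {end}")
    return end - start + 1


def to_internal(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    if start < 1 or start > end:
        raise GenomeError(f"invalid 1-based interval ({start}, {end})")
    return start - 1, end


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    if start < 0 or start >= end:
        raise GenomeError(f"invalid 0-based interval ({start}, {end})")
    return start + 1, end


@dataclass(frozen=True)
class GenomeInterval:
    """0-based half-open interval on the top strand, with a strand tag."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise GenomeError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise GenomeError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def one_based(self) -> tuple[int, int]:
        return to_one_based(self.start, self.end)

    def overlaps(self, other: "GenomeInterval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class GeneFeature:
    """An annotated gene: half-open top-strand coordinates plus strand."""

    gene_id: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"
    partial: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise GenomeError(
                f"feature {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise GenomeError(f"feature {self.gene_id}: invalid strand {self.strand!r}")
        if self.kind == "CDS" and not self.partial and (self.end - self.start) % 3:
            raise GenomeError(
                f"feature {self.gene_id}: CDS length {self.end - self.start} "
                "is not a multiple of 3 (flag partial to allow)"
            )

    @property
    def interval(self) -> GenomeInterval:
        return GenomeInterval(self.start, self.end, self.strand)

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedGenome:
    """A phage (or host) genome plus its gene annotations."""

    id: str
    sequence: str
    topology: str = "linear"
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise GenomeError(f"genome {self.id}: empty sequence")
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            raise GenomeError(
                f"genome {self.id}: invalid characters {sorted(bad)}; "
                "only A, C, G, T and N are accepted"
            )
        if self.topology not in ("linear", "circular"):
            raise GenomeError(f"genome {self.id}: invalid topology {self.topology!r}")
        for f in self.features:
            if f.end > len(self.sequence):
                raise GenomeError(
                    f"feature {f.gene_id} [{f.start}, {f.end}) out of bounds "
                    f"for genome of length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, gene_id: str) -> GeneFeature:
        for f in self.features:
            if f.gene_id == gene_id:
                return f
        raise GenomeError(f"unknown gene id {gene_id!r} in genome {self.id}")

    def slice(self, start: int, end: int) -> str:
        """Top-strand slice; wraps around the origin on circular genomes."""
        if start >= end:
            raise GenomeError(f"invalid slice [{start}, {end})")
        n = len(self.sequence)
        if 0 <= start and end <= n:
            return self.sequence[start:end]
        if self.topology != "circular":
            raise GenomeError(
                f"slice [{start}, {end}) out of bounds on linear genome {self.id}"
            )
        if end - start > n:
            raise GenomeError("slice longer than circular genome")
        return "".join(self.sequence[i % n] for i in range(start, end))

    def interval_sequence(self, iv: GenomeInterval) -> str:
        """Strand-aware sequence of an interval (revcomp for minus strand)."""
        s = self.slice(iv.start, iv.end)
        return revcomp(s) if iv.strand == "-" else s


def transcript_window_to_genome(
    feature: GeneFeature, a: int, b: int
) -> GenomeInterval:
    """Map a transcript-coordinate window [a, b) (0 = first base of the start
    codon; negative = upstream of it) onto genome coordinates."""
    if a >= b:
        raise GenomeError(f"invalid transcript window [{a}, {b})")
    if feature.strand == "+":
        return GenomeInterval(feature.start + a, feature.start + b, "+")
    return GenomeInterval(feature.end - b, feature.end - a, "-")


def transcript_sequence(
    genome: AnnotatedGenome,
    gene_id: str,
    upstream: int = 0,
    downstream: int = 0,
) -> str:
    """mRNA-sense sequence of a gene, optionally extended `upstream` nt before
    the start codon and `downstream` nt past the stop codon."""
    if upstream < 0 or downstream < 0:
        raise GenomeError("upstream/downstream extensions must be non-negative")
    f = genome.feature(gene_id)
    iv = transcript_window_to_genome(f, -upstream, len(f) + downstream)
    if genome.topology == "linear" and (iv.start < 0 or iv.end > len(genome)):
        raise GenomeError(
            f"extension of gene {gene_id} out of bounds on linear genome"
        )
    s = genome.slice(iv.start, iv.end)
    return revcomp(s) if f.strand == "-" else s


# ---------------------------------------------------------------------------
# I/O


def read_coordinate_table(path: str | Path) -> list[GeneFeature]:
    """TSV with columns gene_id, start (1-based), end (inclusive), strand."""
    feats = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene_id", "start", "end", "strand"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise GenomeError(
                f"coordinate table {path}: need columns {sorted(required)}"
            )
        for i, row in enumerate(reader, start=2):
            try:
                s0, e0 = to_internal(int(row["start"]), int(row["end"]))
            except (ValueError, GenomeError) as exc:
                raise GenomeError(f"coordinate table {path} line {i}: {exc}") from exc
            feats.append(
                GeneFeature(
                    gene_id=row["gene_id"],
                    start=s0,
                    end=e0,
                    strand=row["strand"],
                    kind=row.get("kind", "CDS") or "CDS",
                    partial=(row.get("partial", "") or "").lower() in ("1", "true", "yes"),
                )
            )
    return feats


def _features_from_record(record: SeqRecord) -> list[GeneFeature]:
    feats = []
    for sf in record.features:
        if sf.type not in ("CDS", "gene"):
            continue
        if sf.type == "gene" and any(
            f.type == "CDS"
            and int(f.location.start) == int(sf.location.start)
            and int(f.location.end) == int(sf.location.end)
            for f in record.features
        ):
            continue  # avoid duplicating gene/CDS pairs
        quals = sf.qualifiers
        name = (
            quals.get("gene", [None])[0]
            or quals.get("locus_tag", [None])[0]
            or quals.get("label", [None])[0]
            or f"{sf.type}_{int(sf.location.start) + 1}"
        )
        feats.append(
            GeneFeature(
                gene_id=name,
                start=int(sf.location.start),
                end=int(sf.location.end),
                strand="-" if sf.location.strand == -1 else "+",
                kind="CDS" if sf.type == "CDS" else "other",
                partial="<" in str(sf.location) or ">" in str(sf.location),
            )
        )
    return feats


def load_genome(
    path: str | Path,
    format: Optional[str] = None,
    table: Optional[str | Path] = None,
) -> AnnotatedGenome:
    """Load a GenBank or FASTA genome.

    FASTA carries no annotations, so CDS features come from an optional
    TSV coordinate table (1-based inclusive, converted on load).
    """
    path = Path(path)
    if format is None:
        format = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".genbank") else "fasta"
    if format not in ("genbank", "fasta"):
        raise GenomeError(f"unsupported format {format!r}")
    try:
        records = list(SeqIO.parse(str(path), format))
    except Exception as exc:  # Biopython raises assorted exceptions on bad input
        raise GenomeError(f"could not parse {path} as {format}: {exc}") from exc
    if not records:
        raise GenomeError(f"no records found in {path} (format {format})")
    record = records[0]
    features = _features_from_record(record) if format == "genbank" else []
    if table is not None:
        features = read_coordinate_table(table)
    topology = "linear"
    if (record.annotations or {}).get("topology") == "circular":
        topology = "circular"
    return AnnotatedGenome(
        id=record.id or path.stem,
        sequence=str(record.seq),
        topology=topology,
        features=features,
    )


def to_seqrecord(genome: AnnotatedGenome) -> SeqRecord:
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id[:16],
        description="",
        annotations={"molecule_type": "DNA", "topology": genome.topology},
    )
    for f in genome.features:
        record.features.append(
            SeqFeature(
                FeatureLocation(f.start, f.end, strand=-1 if f.strand == "-" else 1),
                type="CDS" if f.kind == "CDS" else "misc_feature",
                qualifiers={"gene": [f.gene_id]},
            )
        )
    return record


def write_genome(genome: AnnotatedGenome, path: str | Path, format: str = "genbank") -> None:
    SeqIO.write([to_seqrecord(genome)], str(path), format)


def write_coordinate_table(genome: AnnotatedGenome, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "start", "end", "strand", "kind", "partial"])
        for f in genome.features:
            s1, e1 = to_one_based(f.start, f.end)
            w.writerow([f.gene_id, s1, e1, f.strand, f.kind, int(f.partial)])


def write_bed(
    intervals: Iterable[tuple[str, GenomeInterval, str]], path: str | Path
) -> None:
    """BED6 (0-based half-open) of named intervals: (chrom, interval, name)."""
    with open(path, "w") as fh:
        for chrom, iv, name in intervals:
            fh.write(f"{chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
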