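"""Core genomic data types shared across the pipeline.

All internal coordinates are 0-based half-open. GTF is the only 1-based
inclusive surface, converted at the I/O boundary (:mod:`lncscout.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

DNA_ALPHABET = frozenset("ACGTN")
RNA_ALPHABET = frozenset("ACGUN")

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded interval on a scaffold, 0-based half-open."""

    scaffold: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.scaffold}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    """An exon-structured transcript; the unit classified, scored and quantified.

    Exons are sorted by start, non-overlapping, separated by >= 1 bp introns,
    and the transcript interval spans them exactly.
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval] = field(default_factory=list)
    biotype: str = "novel"  # one of {mRNA, lncRNA, novel}

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        scaf = self.exons[0].scaffold
        strand = self.exons[0].strand
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.scaffold != scaf or cur.strand != strand:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons span scaffolds/strands"
                )
            if cur.start < prev.end + 1:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap or touch "
                    f"({prev.start},{prev.end}) vs ({cur.start},{cur.end})"
                )

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.exons[0].scaffold,
            self.exons[0].start,
            self.exons[-1].end,
            self.exons[0].strand,
        )

    @property
    def scaffold(self) -> str:
        return self.exons[0].scaffold

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def spliced_length(self) -> int:
        """Sum of exon lengths (the length the candidate filter uses)."""
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.scaffold, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]


@dataclass
class SequenceRecord:
    """A named nucleotide sequence (DNA or RNA)."""

    identifier: str
    sequence: str
    alphabet: str = "DNA"  # "DNA" or "RNA"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"sequence {self.identifier} is empty")
        allowed = DNA_ALPHABET if self.alphabet == "DNA" else RNA_ALPHABET
        seq = self.sequence.upper()
        bad = set(seq) - allowed
        if bad:
            raise ValueError(
                f"sequence {self.identifier} contains invalid characters {sorted(bad)} "
                f"for alphabet {self.alphabet}"
            )
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def extract_spliced_sequence(tx: TranscriptModel, genome: dict[str, str]) -> str:
    """Spliced transcript sequence from genome scaffolds, strand-resolved.

    For '-' transcripts the exonic sequence is reverse-complemented so the
    returned string reads 5'->3' on the transcript. Unstranded ('.') is
    returned in genome orientation.
    """
    scaf = genome[tx.scaffold]
    parts = [scaf[e.start : e.end] for e in tx.exons]
    seq = "".join(parts).upper()
    if tx.strand == "-":
        seq = reverse_complement(seq)
    return seq


def gc_content(seq: str) -> float:
    """GC fraction with N excluded from numerator and denominator."""
    seq = seq.upper().replace("U", "T")
    denom = sum(seq.count(b) for b in "ACGT")
    if denom == 0:
        raise ValueError("sequence has no unambiguous bases")
    return (seq.count("G") + seq.count("C")) / denom
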