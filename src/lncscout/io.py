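"""Readers and writers for GTF, FASTA, BED and TSV tables.

One coordinate convention rules the package: 0-based half-open. GTF files
(1-based inclusive) are converted exactly once, here. BED is emitted
0-based half-open, i.e. identical to the internal convention.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .models import GenomicInterval, SequenceRecord, TranscriptModel


class ParseError(ValueError):
    pass


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon features from a GTF file into TranscriptModels.

    Only ``exon`` features are used; each must carry ``transcript_id`` and
    ``gene_id`` attributes. 1-based inclusive GTF coordinates become 0-based
    half-open. Exons are grouped per transcript and sorted by start.
    An optional ``transcript_biotype`` attribute is propagated.
    """
    path = Path(path)
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            scaffold, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end1 < start1:
                raise ParseError(f"{path}:{lineno}: end < start ({end1} < {start1})")
            attributes = _parse_gtf_attributes(attrs)
            if "transcript_id" not in attributes or "gene_id" not in attributes:
                raise ParseError(
                    f"{path}:{lineno}: exon lacks transcript_id/gene_id attributes"
                )
            tid = attributes["transcript_id"]
            # GTF 1-based inclusive -> 0-based half-open
            iv = GenomicInterval(scaffold, start1 - 1, end1, strand)
            if tid not in exons:
                exons[tid] = []
                order.append(tid)
                meta[tid] = (
                    attributes["gene_id"],
                    attributes.get("transcript_biotype", "novel"),
                )
            exons[tid].append(iv)
    return [
        TranscriptModel(tid, meta[tid][0], exons[tid], biotype=meta[tid][1])
        for tid in order
    ]


def write_gtf(transcripts: list[TranscriptModel], path: str | Path) -> None:
    """Write transcripts as GTF exon features (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            for i, exon in enumerate(tx.exons, start=1):
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                    f'transcript_biotype "{tx.biotype}"; exon_number "{i}";'
                )
                fh.write(
                    "\t".join(
                        [
                            exon.scaffold,
                            "lncscout",
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            exon.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_fasta(path: str | Path, alphabet: str = "DNA") -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    ident: str | None = None
    chunks: list[str] = []
    seen: set[str] = set()

    def _flush() -> None:
        if ident is not None:
            if ident in seen:
                raise ParseError(f"duplicate FASTA identifier {ident!r}")
            seen.add(ident)
            records.append(SequenceRecord(ident, "".join(chunks), alphabet))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                ident = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    _flush()
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.identifier}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV of non-negative integer counts."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"duplicate feature identifiers: {dups[:5]}")
    if df.columns.duplicated().any():
        raise ParseError("duplicate sample identifiers")
    if (df.to_numpy() < 0).any():
        raise ParseError("negative count in count matrix")
    return df.astype(int)


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet: sample_id, group in {virgin, mated}, biological_replicate,
    technical_run."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "biological_replicate", "technical_run"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"sample sheet missing columns: {sorted(missing)}")
    bad = set(df["group"]) - {"virgin", "mated"}
    if bad:
        raise ParseError(f"unknown groups: {sorted(bad)}")
    return df.set_index("sample_id")


def write_bed(intervals: list[GenomicInterval], path: str | Path,
              names: list[str] | None = None,
              scores: list[float] | None = None) -> None:
    """Write BED6 (0-based half-open, same as internal convention)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"feature_{i}"
            score = scores[i] if scores else 0
            strand = iv.strand if iv.strand != "." else "."
            fh.write(
                f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{strand}\n"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out
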