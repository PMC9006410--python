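"""RNA:DNA:DNA triplex prediction by Hoogsteen-motif matching.

A triplex-forming oligonucleotide (TFO) segment of an RNA binds the purine
strand of duplex DNA in the major groove. Matching follows the canonical
triplet rules per motif:

* pyrimidine motif (parallel to the purine strand):  U.A and C.G
* purine motif (antiparallel):                       A.A and G.G
* mixed motif (both orientations searched):          U.A and G.G

A reported match is a maximal ungapped TFO/TTS alignment satisfying every
constraint: length >= 15 nt, error rate strictly < 0.20, no more than 3
consecutive errors, and guanine fraction of the TTS purine strand >= 0.20.
Both DNA strands are considered as candidate purine strands; TTS
coordinates are always reported on the given (forward) DNA sequence with
the purine strand recorded as '+' or '-'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import GenomicInterval, TranscriptModel, reverse_complement

# motif -> set of valid (TFO RNA base, purine-strand DNA base) pairs
HOOGSTEEN_PAIRS: dict[str, frozenset[tuple[str, str]]] = {
    "pyrimidine": frozenset({("U", "A"), ("C", "G")}),
    "purine": frozenset({("A", "A"), ("G", "G")}),
    "mixed": frozenset({("U", "A"), ("G", "G")}),
}

MOTIF_ORIENTATIONS: dict[str, tuple[str, ...]] = {
    "pyrimidine": ("parallel",),
    "purine": ("antiparallel",),
    "mixed": ("parallel", "antiparallel"),
}


@dataclass(frozen=True)
class TriplexParams:
    min_length: int = 15
    max_error_rate: float = 0.20  # strict upper bound
    max_consecutive_errors: int = 3
    min_guanine_fraction: float = 0.20  # of the TTS purine strand, inclusive
    motifs: tuple[str, ...] = ("pyrimidine", "purine", "mixed")

    def __post_init__(self) -> None:
        if not (0.0 < self.max_error_rate < 1.0):
            raise ValueError("max_error_rate must lie in (0, 1)")
        if self.min_length < 5:
            raise ValueError("min_length must be >= 5")
        unknown = set(self.motifs) - set(HOOGSTEEN_PAIRS)
        if unknown:
            raise ValueError(f"unknown motifs: {sorted(unknown)}")


def hoogsteen_match(tfo_base: str, purine_strand_base: str, motif: str) -> bool:
    """Whether an RNA base can Hoogsteen-pair the purine-strand DNA base.

    T in RNA input is treated as U; N never matches.
    """
    if motif not in HOOGSTEEN_PAIRS:
        raise ValueError(f"unknown motif {motif!r}")
    t = tfo_base.upper().replace("T", "U")
    d = purine_strand_base.upper()
    return (t, d) in HOOGSTEEN_PAIRS[motif]


@dataclass(frozen=True)
class TriplexMatch:
    tfo_start: int  # on the RNA, 0-based half-open, original orientation
    tfo_end: int
    tts: GenomicInterval  # on the given DNA; strand = purine strand
    motif: str
    orientation: str  # parallel / antiparallel
    errors: int
    error_positions: tuple[int, ...]  # offsets along the TTS purine strand 5'->3'
    tts_guanine_fraction: float
    tts_ga_fraction: float
    feature: str = ""  # filled by locus scans (e.g. "intron_1")

    @property
    def length(self) -> int:
        return self.tfo_end - self.tfo_start

    @property
    def score(self) -> int:
        return self.length - self.errors

    def key(self) -> tuple:
        return (
            self.tfo_start,
            self.tfo_end,
            self.tts.scaffold,
            self.tts.start,
            self.tts.end,
            self.tts.strand,
            self.motif,
            self.orientation,
        )


def match_base_pairs(
    match: TriplexMatch, rna_seq: str, dna_seq: str
) -> list[tuple[str, str]]:
    """(TFO base, purine-strand base) per position, TTS 5'->3' on the purine
    strand — for re-verification of reported matches."""
    rna = rna_seq.upper().replace("U", "T")
    dna = dna_seq.upper()
    out = []
    for k in range(match.length):
        if match.tts.strand == "+":
            pur = dna[match.tts.start + k]
        else:
            pur = reverse_complement(dna[match.tts.end - 1 - k])
        if match.orientation == "parallel":
            tfo = rna[match.tfo_start + k]
        else:
            tfo = rna[match.tfo_end - 1 - k]
        out.append((tfo.replace("T", "U"), pur))
    return out


def _pair_ok_table(motif: str) -> np.ndarray:
    """256 x 256 boolean lookup: ok[ord(rna_base), ord(dna_base)]."""
    table = np.zeros((256, 256), dtype=bool)
    for t, d in HOOGSTEEN_PAIRS[motif]:
        table[ord(t), ord(d)] = True
    return table


def find_triplexes(
    rna_seq: str,
    dna_seq: str,
    params: TriplexParams = TriplexParams(),
    dna_id: str = "dna",
) -> list[TriplexMatch]:
    """All maximal TFO:TTS matches between an RNA and a duplex DNA sequence.

    Enumerates every ungapped alignment diagonal for each (motif,
    orientation, candidate purine strand); on a diagonal a window is valid
    when it meets all four constraints and is reported when neither one-base
    extension stays valid (maximality). Matches are deduplicated by
    (tfo, tts, motif, orientation).
    """
    rna = rna_seq.upper().replace("T", "U")
    dna = dna_seq.upper()
    n_rna = len(rna)
    n_dna = len(dna)
    if n_rna < params.min_length:
        return []

    results: dict[tuple, TriplexMatch] = {}
    for strand in ("+", "-"):
        pur = dna if strand == "+" else reverse_complement(dna)
        pur_u8 = np.frombuffer(pur.encode(), dtype=np.uint8)
        is_g = (pur_u8 == ord("G")).astype(np.int64)
        is_ga = ((pur_u8 == ord("G")) | (pur_u8 == ord("A"))).astype(np.int64)
        for motif in params.motifs:
            ok = _pair_ok_table(motif)
            for orientation in MOTIF_ORIENTATIONS[motif]:
                eff_rna = rna if orientation == "parallel" else rna[::-1]
                rna_u8 = np.frombuffer(eff_rna.encode(), dtype=np.uint8)
                _scan_diagonals(
                    rna_u8, pur_u8, is_g, is_ga, ok, params,
                    strand, motif, orientation, n_rna, n_dna, dna_id, results,
                )
    return sorted(results.values(), key=lambda m: m.key())


def _scan_diagonals(
    rna_u8: np.ndarray,
    pur_u8: np.ndarray,
    is_g: np.ndarray,
    is_ga: np.ndarray,
    ok: np.ndarray,
    params: TriplexParams,
    strand: str,
    motif: str,
    orientation: str,
    n_rna: int,
    n_dna: int,
    dna_id: str,
    results: dict,
) -> None:
    min_len = params.min_length
    max_rate = params.max_error_rate
    min_g = params.min_guanine_fraction
    run = params.max_consecutive_errors + 1  # this many consecutive errors is fatal

    for offset in range(-(n_rna - min_len), n_dna - min_len + 1):
        i0 = max(0, -offset)
        j0 = i0 + offset
        length = min(n_rna - i0, n_dna - j0)
        if length < min_len:
            continue
        err = (~ok[rna_u8[i0 : i0 + length], pur_u8[j0 : j0 + length]]).astype(np.int64)
        pe = np.concatenate(([0], np.cumsum(err)))
        pg = np.concatenate(([0], np.cumsum(is_g[j0 : j0 + length])))
        pga = np.concatenate(([0], np.cumsum(is_ga[j0 : j0 + length])))
        # nf[a] = first position >= a where a fatal error run begins
        nf = np.full(length + 1, length, dtype=np.int64)
        if length >= run:
            starts = np.nonzero(pe[run:] - pe[:-run] == run)[0]
            nf[starts] = starts
        nf = np.minimum.accumulate(nf[::-1])[::-1]

        # only starts whose error-run bound still allows a min-length window
        b_hi_all = np.minimum(length, nf[: length - min_len + 1] + run - 1)
        a_candidates = np.nonzero(
            b_hi_all >= np.arange(length - min_len + 1) + min_len
        )[0]
        if len(a_candidates) == 0:
            continue

        valid: set[tuple[int, int]] = set()
        for a in a_candidates:
            a = int(a)
            b_hi = int(b_hi_all[a])
            for b in range(a + min_len, b_hi + 1):
                w = b - a
                if (pe[b] - pe[a]) / w >= max_rate:
                    continue
                if (pg[b] - pg[a]) / w < min_g:
                    continue
                valid.add((a, b))

        for a, b in valid:
            if (a - 1, b) in valid or (a, b + 1) in valid:
                continue
            _emit(
                a, b, i0, j0, pe, pg, pga, err, strand, motif, orientation,
                n_rna, n_dna, dna_id, results,
            )


def _emit(
    a: int,
    b: int,
    i0: int,
    j0: int,
    pe: np.ndarray,
    pg: np.ndarray,
    pga: np.ndarray,
    err: np.ndarray,
    strand: str,
    motif: str,
    orientation: str,
    n_rna: int,
    n_dna: int,
    dna_id: str,
    results: dict,
) -> None:
    w = b - a
    # effective-RNA window -> original RNA coordinates
    ei, ej = i0 + a, i0 + b
    if orientation == "parallel":
        tfo_start, tfo_end = ei, ej
    else:
        tfo_start, tfo_end = n_rna - ej, n_rna - ei
    # purine-strand window -> given-strand coordinates
    ps, pend = j0 + a, j0 + b
    if strand == "+":
        tts = GenomicInterval(dna_id, ps, pend, "+")
    else:
        tts = GenomicInterval(dna_id, n_dna - pend, n_dna - ps, "-")
    match = TriplexMatch(
        tfo_start=int(tfo_start),
        tfo_end=int(tfo_end),
        tts=tts,
        motif=motif,
        orientation=orientation,
        errors=int(pe[b] - pe[a]),
        error_positions=tuple(int(k - a) for k in range(a, b) if err[k]),
        tts_guanine_fraction=float(pg[b] - pg[a]) / w,
        tts_ga_fraction=float(pga[b] - pga[a]) / w,
    )
    results.setdefault(match.key(), match)


# ---------------------------------------------------------------------------
# Locus scan with genomic coordinates and feature annotation


def annotate_feature(
    iv: GenomicInterval, transcripts: list[TranscriptModel]
) -> str:
    """Label an interval as exon_k / intron_k / flank relative to the
    transcripts of a locus (intron 1 = between first two exons in transcript
    orientation). Exon labels take precedence over intron labels."""
    best = "flank"
    for tx in transcripts:
        if tx.scaffold != iv.scaffold:
            continue
        exons = tx.exons if tx.strand != "-" else list(reversed(tx.exons))
        for k, exon in enumerate(exons, start=1):
            if exon.start < iv.end and iv.start < exon.end:
                return f"exon_{k}"
        introns = tx.introns()
        introns = introns if tx.strand != "-" else list(reversed(introns))
        for k, intron in enumerate(introns, start=1):
            if intron.start < iv.end and iv.start < intron.end:
                best = f"intron_{k}"
    return best


def scan_lncrna_vs_locus(
    lncrna_seq: str,
    locus: GenomicInterval,
    genome: dict[str, str],
    transcripts: list[TranscriptModel],
    params: TriplexParams = TriplexParams(),
) -> list[TriplexMatch]:
    """find_triplexes against a genomic locus; TTS lifted to genome space and
    annotated with the containing gene feature."""
    scaf = genome.get(locus.scaffold)
    if scaf is None or locus.end > len(scaf):
        raise ValueError(f"locus {locus} outside the genome")
    dna = scaf[locus.start : locus.end]
    matches = find_triplexes(lncrna_seq, dna, params, dna_id=locus.scaffold)
    lifted = []
    for m in matches:
        tts = GenomicInterval(
            locus.scaffold, m.tts.start + locus.start, m.tts.end + locus.start,
            m.tts.strand,
        )
        lifted.append(
            TriplexMatch(
                tfo_start=m.tfo_start,
                tfo_end=m.tfo_end,
                tts=tts,
                motif=m.motif,
                orientation=m.orientation,
                errors=m.errors,
                error_positions=m.error_positions,
                tts_guanine_fraction=m.tts_guanine_fraction,
                tts_ga_fraction=m.tts_ga_fraction,
                feature=annotate_feature(tts, transcripts),
            )
        )
    return lifted


# ---------------------------------------------------------------------------
# TTS clustering


@dataclass
class TtsCluster:
    interval: GenomicInterval
    n_members: int
    ga_fraction: float
    high_frequency: bool
    members: list[TriplexMatch] = field(repr=False, default_factory=list)


def cluster_tts(
    matches: list[TriplexMatch],
    genome: dict[str, str] | None = None,
    gap: int = 0,
    high_frequency_k: int = 10,
) -> list[TtsCluster]:
    """Merge TTS intervals that overlap or lie within ``gap`` bp.

    Clustering is per scaffold (both purine strands pooled, since a TTS
    names a duplex region). ga_fraction is computed on the merged interval's
    forward sequence when a genome is supplied (G+A and C+T fractions are
    strand-mirror images; the larger is reported), else on member averages.
    """
    if not matches:
        return []
    by_scaffold: dict[str, list[TriplexMatch]] = {}
    for m in matches:
        by_scaffold.setdefault(m.tts.scaffold, []).append(m)

    clusters: list[TtsCluster] = []
    for scaf, ms in sorted(by_scaffold.items()):
        ms = sorted(ms, key=lambda m: (m.tts.start, m.tts.end))
        cur = [ms[0]]
        cur_end = ms[0].tts.end
        groups = []
        for m in ms[1:]:
            if m.tts.start <= cur_end + gap:
                cur.append(m)
                cur_end = max(cur_end, m.tts.end)
            else:
                groups.append(cur)
                cur = [m]
                cur_end = m.tts.end
        groups.append(cur)
        for grp in groups:
            start = min(m.tts.start for m in grp)
            end = max(m.tts.end for m in grp)
            if genome is not None and scaf in genome:
                seq = genome[scaf][start:end].upper()
                n = max(len(seq), 1)
                ga = (seq.count("G") + seq.count("A")) / n
                ga = max(ga, (seq.count("C") + seq.count("T")) / n)
            else:
                ga = float(np.mean([m.tts_ga_fraction for m in grp]))
            clusters.append(
                TtsCluster(
                    interval=GenomicInterval(scaf, start, end, "."),
                    n_members=len(grp),
                    ga_fraction=ga,
                    high_frequency=len(grp) >= high_frequency_k,
                    members=grp,
                )
            )
    return clusters


def matches_to_frame(matches: list[TriplexMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tfo_start": m.tfo_start,
                "tfo_end": m.tfo_end,
                "tts_scaffold": m.tts.scaffold,
                "tts_start": m.tts.start,
                "tts_end": m.tts.end,
                "tts_strand": m.tts.strand,
                "motif": m.motif,
                "orientation": m.orientation,
                "length": m.length,
                "errors": m.errors,
                "score": m.score,
                "tts_guanine_fraction": m.tts_guanine_fraction,
                "tts_ga_fraction": m.tts_ga_fraction,
                "feature": m.feature,
            }
            for m in matches
        ],
        columns=[
            "tfo_start", "tfo_end", "tts_scaffold", "tts_start", "tts_end",
            "tts_strand", "motif", "orientation", "length", "errors", "score",
            "tts_guanine_fraction", "tts_ga_fraction", "feature",
        ],
    )
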