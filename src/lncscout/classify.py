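"""Class-code assignment against a reference annotation and candidate filtering.

Assembled transcripts are compared with the reference the way gffcompare
does, restricted to the codes this pipeline acts on:

=  exon chain identical to a reference transcript
o  any query exon overlaps any reference exon (disqualifies the candidate)
i  query entirely within a single reference intron
y  a full reference transcript lies within a query intron
p  possible run-on fragment: no overlap, query starts within a window
   downstream of a reference 3' end (strand-aware on the reference)
u  intergenic / unknown

Precedence is =, o, i, y, p, u: exonic overlap always disqualifies, so only
transcripts from non-coding loci survive. Candidates are then length-filtered
(spliced length >= 200 nt, inclusive) before coding-potential assessment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import TranscriptModel, gc_content

KEPT_CODES = frozenset({"i", "y", "p", "u"})
DEFAULT_MIN_LENGTH = 200
DEFAULT_RUNON_WINDOW = 2000


def _same_strand(a: str, b: str) -> bool:
    return a == b or a == "." or b == "."


def _exon_chain_equal(q: TranscriptModel, r: TranscriptModel) -> bool:
    if q.scaffold != r.scaffold or not _same_strand(q.strand, r.strand):
        return False
    if q.n_exons != r.n_exons:
        return False
    return all(
        qe.start == re_.start and qe.end == re_.end
        for qe, re_ in zip(q.exons, r.exons)
    )


def assign_class_code(
    query: TranscriptModel,
    reference: list[TranscriptModel],
    runon_window: int = DEFAULT_RUNON_WINDOW,
    stranded_containment: bool = False,
) -> str:
    """Assign the class code of ``query`` relative to the reference set.

    ``stranded_containment`` restricts codes i and y to same-strand
    reference transcripts; exonic overlap (o) always counts on either strand.
    Unstranded queries ('.') match either strand throughout.
    """
    if not query.exons:
        raise ValueError("query transcript has no exons")
    refs = [r for r in reference if r.scaffold == query.scaffold]

    for r in refs:
        if _exon_chain_equal(query, r):
            return "="

    for r in refs:
        for qe in query.exons:
            for re_ in r.exons:
                if qe.start < re_.end and re_.start < qe.end:
                    return "o"

    span = query.interval
    for r in refs:
        if stranded_containment and not _same_strand(query.strand, r.strand):
            continue
        for intron in r.introns():
            if intron.start <= span.start and span.end <= intron.end:
                return "i"

    for intron in query.introns():
        for r in refs:
            if stranded_containment and not _same_strand(query.strand, r.strand):
                continue
            rspan = r.interval
            if intron.start <= rspan.start and rspan.end <= intron.end:
                return "y"

    for r in refs:
        rspan = r.interval
        if r.strand == "-":
            # downstream of a '-' reference = lower coordinates
            gap = rspan.start - span.end
        else:
            gap = span.start - rspan.end
        if 0 <= gap <= runon_window:
            return "p"

    return "u"


@dataclass
class CandidateVerdict:
    transcript_id: str
    class_code: str
    spliced_length: int
    kept: bool
    reason: str  # "ok", "class_code", or "length"


def filter_candidates(
    novel: list[TranscriptModel],
    reference: list[TranscriptModel],
    min_length: int = DEFAULT_MIN_LENGTH,
    kept_codes: frozenset[str] = KEPT_CODES,
    runon_window: int = DEFAULT_RUNON_WINDOW,
) -> pd.DataFrame:
    """Class-code + length filter over novel transcripts.

    Returns a table with one row per transcript: transcript_id, class_code,
    spliced_length, kept, reason. Kept candidates have code in ``kept_codes``
    and spliced length >= ``min_length`` (inclusive bound).
    """
    rows = []
    for tx in novel:
        code = assign_class_code(tx, reference, runon_window=runon_window)
        length = tx.spliced_length
        if code not in kept_codes:
            kept, reason = False, "class_code"
        elif length < min_length:
            kept, reason = False, "length"
        else:
            kept, reason = True, "ok"
        rows.append(
            {
                "transcript_id": tx.transcript_id,
                "class_code": code,
                "spliced_length": length,
                "kept": kept,
                "reason": reason,
            }
        )
    return pd.DataFrame(
        rows, columns=["transcript_id", "class_code", "spliced_length", "kept", "reason"]
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U and group characterization


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration (tie-aware) when both samples have n <= 8; otherwise
    the normal approximation with tie correction and continuity correction.
    Returns (U of sample x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("empty group in Mann-Whitney test")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_x = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0

    if n1 <= 8 and n2 <= 8:
        # exact: enumerate all C(n1+n2, n1) assignments of the pooled ranks
        mean_u = n1 * n2 / 2.0
        obs_dev = abs(u_x - mean_u)
        count = 0
        total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u - mean_u) >= obs_dev - 1e-12:
                count += 1
        return float(u_x), count / total

    mean_u = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return float(u_x), 1.0
    z = (abs(u_x - mean_u) - 0.5) / math.sqrt(var_u)
    z = max(z, 0.0)
    p = 2.0 * stats.norm.sf(z)
    return float(u_x), min(p, 1.0)


def characterize_transcripts(
    groups: dict[str, list[TranscriptModel]],
    sequences: dict[str, str],
    tpm: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group sequence/expression features and pairwise Mann-Whitney tests.

    ``groups`` maps a group name (e.g. "mRNA", "reference lncRNA",
    "novel lncRNA") to its transcripts. Expression enters on the
    log10(TPM + 1) scale, averaged over samples per transcript.

    Returns ``(features, comparisons)``: a per-transcript feature table and a
    per-feature pairwise p-value table.
    """
    if any(len(txs) == 0 for txs in groups.values()):
        empty = [g for g, txs in groups.items() if not txs]
        raise ValueError(f"empty transcript group(s): {empty}")

    rows = []
    for gname, txs in groups.items():
        for tx in txs:
            seq = sequences[tx.transcript_id]
            row = {
                "group": gname,
                "transcript_id": tx.transcript_id,
                "length": tx.spliced_length,
                "n_exons": tx.n_exons,
                "gc_content": gc_content(seq),
            }
            if tpm is not None and tx.transcript_id in tpm.index:
                row["log10_tpm1"] = float(
                    np.log10(tpm.loc[tx.transcript_id].mean() + 1.0)
                )
            rows.append(row)
    feats = pd.DataFrame(rows)

    metrics = [c for c in ("length", "n_exons", "gc_content", "log10_tpm1")
               if c in feats.columns]
    comps = []
    names = list(groups)
    for a, b in itertools.combinations(names, 2):
        for metric in metrics:
            xa = feats.loc[feats["group"] == a, metric].dropna().to_numpy()
            xb = feats.loc[feats["group"] == b, metric].dropna().to_numpy()
            if len(xa) == 0 or len(xb) == 0:
                continue
            u, p = mann_whitney_u(xa, xb)
            comps.append(
                {"group_a": a, "group_b": b, "metric": metric, "U": u, "p_value": p}
            )
    return feats, pd.DataFrame(comps)
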