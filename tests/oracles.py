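"""Independent brute-force oracles used by the test suite.

Each oracle re-derives the quantity from first principles with a different
algorithm (and usually different data structures) from the package
implementation, so agreement is evidence of correctness rather than
repetition.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# Class codes: all-pairs interval checks


def classify_oracle(query, reference, runon_window=2000):
    """Brute-force class code via exhaustive pairwise checks."""
    refs = [r for r in reference if r.scaffold == query.scaffold]

    def strands_ok(a, b):
        return a == b or "." in (a, b)

    # "=": identical exon chain
    for r in refs:
        if strands_ok(query.strand, r.strand) and [
            (e.start, e.end) for e in query.exons
        ] == [(e.start, e.end) for e in r.exons]:
            return "="
    # "o": any exonic overlap, any strand
    for r in refs:
        for qe in query.exons:
            for re_ in r.exons:
                if max(qe.start, re_.start) < min(qe.end, re_.end):
                    return "o"
    # "i": query span inside one reference intron
    qs, qe_ = query.exons[0].start, query.exons[-1].end
    for r in refs:
        for a, b in zip(r.exons, r.exons[1:]):
            if a.end <= qs and qe_ <= b.start:
                return "i"
    # "y": a full reference inside a query intron
    for a, b in zip(query.exons, query.exons[1:]):
        for r in refs:
            if a.end <= r.exons[0].start and r.exons[-1].end <= b.start:
                return "y"
    # "p": strand-aware downstream window of a reference end
    for r in refs:
        if r.strand == "-":
            d = r.exons[0].start - qe_
        else:
            d = qs - r.exons[-1].end
        if 0 <= d <= runon_window:
            return "p"
    return "u"


# ---------------------------------------------------------------------------
# ORF scan: naive triple loop

_STOPS = {"TAA", "TAG", "TGA"}


def orf_oracle(seq):
    """Every ATG-initiated ORF, found by scanning forward from each ATG."""
    seq = seq.upper().replace("U", "T")
    n = len(seq)
    out = []
    for start in range(n - 2):
        if seq[start : start + 3] != "ATG":
            continue
        end = None
        has_stop = False
        j = start
        while j + 3 <= n:
            if seq[j : j + 3] in _STOPS and j > start:
                end = j + 3
                has_stop = True
                break
            j += 3
        if end is None:
            end = start + ((n - start) // 3) * 3
        out.append((start, end, start % 3, has_stop))
    return sorted(out)


# ---------------------------------------------------------------------------
# Fickett TESTCODE: independent transcription of the published tables

_FICKETT_POS = {
    "A": ((1.9, 0.94), (1.8, 0.68), (1.7, 0.84), (1.6, 0.93), (1.5, 0.58),
          (1.4, 0.68), (1.3, 0.45), (1.2, 0.34), (1.1, 0.20), (0.0, 0.22)),
    "C": ((1.9, 0.80), (1.8, 0.70), (1.7, 0.70), (1.6, 0.81), (1.5, 0.66),
          (1.4, 0.48), (1.3, 0.51), (1.2, 0.33), (1.1, 0.30), (0.0, 0.23)),
    "G": ((1.9, 0.90), (1.8, 0.88), (1.7, 0.74), (1.6, 0.64), (1.5, 0.53),
          (1.4, 0.48), (1.3, 0.27), (1.2, 0.16), (1.1, 0.08), (0.0, 0.08)),
    "T": ((1.9, 0.97), (1.8, 0.97), (1.7, 0.91), (1.6, 0.68), (1.5, 0.69),
          (1.4, 0.44), (1.3, 0.54), (1.2, 0.20), (1.1, 0.09), (0.0, 0.09)),
}
_FICKETT_CONT = {
    "A": ((0.33, 0.28), (0.31, 0.49), (0.29, 0.44), (0.27, 0.55), (0.25, 0.62),
          (0.23, 0.49), (0.21, 0.67), (0.19, 0.65), (0.17, 0.81), (0.0, 0.21)),
    "C": ((0.33, 0.82), (0.31, 0.64), (0.29, 0.51), (0.27, 0.64), (0.25, 0.59),
          (0.23, 0.59), (0.21, 0.43), (0.19, 0.44), (0.17, 0.39), (0.0, 0.31)),
    "G": ((0.33, 0.40), (0.31, 0.54), (0.29, 0.47), (0.27, 0.64), (0.25, 0.64),
          (0.23, 0.73), (0.21, 0.41), (0.19, 0.41), (0.17, 0.33), (0.0, 0.29)),
    "T": ((0.33, 0.28), (0.31, 0.24), (0.29, 0.39), (0.27, 0.40), (0.25, 0.55),
          (0.23, 0.75), (0.21, 0.56), (0.19, 0.69), (0.17, 0.51), (0.0, 0.58)),
}
_POS_W = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_CONT_W = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}


def fickett_oracle(seq):
    seq = seq.upper().replace("U", "T")
    score = 0.0
    unambig = [b for b in seq if b in "ACGT"]
    for base in "ACGT":
        phase = [0, 0, 0]
        for i, b in enumerate(seq):
            if b == base:
                phase[i % 3] += 1
        pos_val = max(phase) / (min(phase) + 1.0)
        for thr, prob in _FICKETT_POS[base]:
            if pos_val >= thr:
                score += prob * _POS_W[base]
                break
        frac = unambig.count(base) / len(unambig) if unambig else 0.0
        for thr, prob in _FICKETT_CONT[base]:
            if frac >= thr:
                score += prob * _CONT_W[base]
                break
    return score


# ---------------------------------------------------------------------------
# Hexamer score: naive loop


def hexamer_oracle(orf_seq, table):
    seq = orf_seq.upper().replace("U", "T")
    vals = []
    i = 0
    while i + 6 <= len(seq):
        h = seq[i : i + 6]
        if h in table:
            vals.append(table[h])
        i += 3
    return sum(vals) / len(vals) if vals else 0.0


# ---------------------------------------------------------------------------
# Spearman: manual average ranks + explicit Pearson


def rank_oracle(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    rx = rank_oracle(list(x))
    ry = rank_oracle(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = sum((a - mx) ** 2 for a in rx) ** 0.5
    dy = sum((b - my) ** 2 for b in ry) ** 0.5
    if dx == 0 or dy == 0:
        return float("nan")
    return num / (dx * dy)


# ---------------------------------------------------------------------------
# Triplex: exhaustive window enumeration + maximality


_ORACLE_PAIRS = {
    "pyrimidine": {("U", "A"), ("C", "G")},
    "purine": {("A", "A"), ("G", "G")},
    "mixed": {("U", "A"), ("G", "G")},
}
_ORACLE_ORIENT = {
    "pyrimidine": ("parallel",),
    "purine": ("antiparallel",),
    "mixed": ("parallel", "antiparallel"),
}
_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(s):
    return "".join(_RC[b] for b in reversed(s))


def triplex_oracle(rna_seq, dna_seq, min_length=15, max_error_rate=0.2,
                   max_consecutive_errors=3, min_guanine_fraction=0.2,
                   motifs=("pyrimidine", "purine", "mixed")):
    """Enumerate every window on every alignment diagonal, check all four
    constraints, and keep maximal windows.

    Returns a set of keys (tfo_start, tfo_end, tts_start, tts_end, strand,
    motif, orientation) comparable with TriplexMatch.key() minus scaffold.

    A whole diagonal is skipped when no 15-nt window on it holds >= 11
    matches: any window with error rate < 0.2 contains a 15-nt subwindow
    with <= 4 errors (for width >= 35 by a disjoint-subwindow count; for
    width <= 34 because the two end subwindows would need more errors than
    the rate bound allows), so such diagonals provably hold no valid
    window. The skip only applies at the default parameters.
    """
    rna = rna_seq.upper().replace("T", "U")
    dna = dna_seq.upper()
    n_rna, n_dna = len(rna), len(dna)
    run = max_consecutive_errors + 1
    can_skip = (min_length == 15 and max_error_rate == 0.2
                and max_consecutive_errors == 3)
    out = set()

    for strand in ("+", "-"):
        pur = dna if strand == "+" else _revcomp(dna)
        for motif in motifs:
            pairs = _ORACLE_PAIRS[motif]
            for orientation in _ORACLE_ORIENT[motif]:
                eff = rna if orientation == "parallel" else rna[::-1]
                for off in range(-(n_rna - 1), n_dna):
                    i0 = max(0, -off)
                    j0 = i0 + off
                    ln = min(n_rna - i0, n_dna - j0)
                    if ln < min_length:
                        continue
                    err = [
                        0 if (eff[i0 + k], pur[j0 + k]) in pairs else 1
                        for k in range(ln)
                    ]
                    if can_skip and ln >= 15:
                        best = max(
                            15 - sum(err[s : s + 15]) for s in range(ln - 14)
                        )
                        if best <= 10:
                            continue
                    gs = [1 if pur[j0 + k] == "G" else 0 for k in range(ln)]
                    valid = set()
                    for a in range(ln - min_length + 1):
                        for b in range(a + min_length, ln + 1):
                            w = b - a
                            e = sum(err[a:b])
                            if e / w >= max_error_rate:
                                continue
                            if sum(gs[a:b]) / w < min_guanine_fraction:
                                continue
                            runlen = best_run = 0
                            for k in range(a, b):
                                runlen = runlen + 1 if err[k] else 0
                                best_run = max(best_run, runlen)
                            if best_run > max_consecutive_errors:
                                continue
                            valid.add((a, b))
                    for a, b in valid:
                        if (a - 1, b) in valid or (a, b + 1) in valid:
                            continue
                        ei, ej = i0 + a, i0 + b
                        if orientation == "parallel":
                            tfo = (ei, ej)
                        else:
                            tfo = (n_rna - ej, n_rna - ei)
                        ps, pe = j0 + a, j0 + b
                        if strand == "+":
                            tts = (ps, pe)
                        else:
                            tts = (n_dna - pe, n_dna - ps)
                        out.add((tfo[0], tfo[1], tts[0], tts[1], strand,
                                 motif, orientation))
    return out


# ---------------------------------------------------------------------------
# Logistic regression oracle (statsmodels, used where installed)


def logistic_oracle(x, y, tol=1e-10):
    """Plain Newton-Raphson logistic fit on raw features + intercept."""
    x = np.column_stack([np.ones(len(y)), np.asarray(x, dtype=float)])
    y = np.asarray(y, dtype=float)
    beta = np.zeros(x.shape[1])
    for _ in range(200):
        eta = np.clip(x @ beta, -30, 30)
        mu = 1 / (1 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-10)
        grad = x.T @ (y - mu)
        hess = (x.T * w) @ x
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta
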