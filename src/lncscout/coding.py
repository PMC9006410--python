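"""CPAT-style coding-potential assessment.

Four sequence features drive a logistic regression trained on known coding
vs noncoding transcripts:

* longest ORF length (nt)
* ORF coverage (ORF length / transcript length)
* Fickett TESTCODE statistic (positional periodicity + base composition)
* hexamer usage bias (mean log-ratio of in-frame 6-mer frequencies between
  coding and noncoding training sets)

The fitted model yields a coding probability per transcript; a cutoff is
calibrated on a labelled benchmark by maximizing accuracy over all observed
scores, with the ROC/AUC reported alongside. Transcripts below the cutoff
are further discarded when they carry a long complete ORF (>= 100 codons by
default, TransDecoder's minimum) or appear in a precomputed homology-hit
table; the remainder are the novel lncRNA set.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

_FICKETT_SHA256 = "01db0728f277c717f1886c2eaa919bcd3b0bcc62f882ef377a1791b0383a8926"


def _norm_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


# ---------------------------------------------------------------------------
# ORF scanning


@dataclass(frozen=True)
class OrfHit:
    start: int  # 0-based on the transcript
    end: int  # exclusive; includes the stop codon when present
    frame: int  # 0, 1, 2
    has_start: bool
    has_stop: bool

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def n_codons(self) -> int:
        return self.length_nt // 3


def find_orfs(seq: str) -> list[OrfHit]:
    """All ATG-initiated ORFs on the sense strand, three frames.

    Each ATG opens an ORF running to the first in-frame stop codon
    (stop included, ``has_stop=True``) or to the end of the frame
    (``has_stop=False``). Nested ATGs each yield their own hit.
    """
    seq = _norm_dna(seq)
    n = len(seq)
    hits: list[OrfHit] = []
    for frame in range(3):
        open_starts: list[int] = []
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if codon == START_CODON:
                open_starts.append(i)
            if codon in STOP_CODONS and open_starts:
                for s in open_starts:
                    hits.append(OrfHit(s, i + 3, frame, True, True))
                open_starts = []
            i += 3
        frame_end = frame + ((n - frame) // 3) * 3
        for s in open_starts:
            hits.append(OrfHit(s, frame_end, frame, True, False))
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def longest_orf(seq: str) -> OrfHit | None:
    """Longest ORF by length in nt; ties broken by smallest start."""
    hits = find_orfs(seq)
    if not hits:
        return None
    return max(hits, key=lambda h: (h.length_nt, -h.start))


# ---------------------------------------------------------------------------
# Fickett TESTCODE


def load_fickett_tables() -> dict:
    data = resources.files("lncscout.data").joinpath("fickett_tables.json").read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FICKETT_SHA256:
        raise RuntimeError(
            "fickett_tables.json checksum mismatch: expected "
            f"{_FICKETT_SHA256}, got {digest}"
        )
    return json.loads(data)


_FICKETT = load_fickett_tables()


def _lookup(value: float, thresholds: list[float], probs: list[float]) -> float:
    for t, p in zip(thresholds, probs):
        if value >= t:
            return p
    return probs[-1]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE statistic of a transcript sequence.

    For each base: the position value is max/(min+1) over counts at the three
    codon-phase positions, the content value is the base's overall fraction;
    both are converted to probabilities via the published lookup tables and
    combined with the published weights. T and U are equivalent.
    """
    seq = _norm_dna(seq)
    if len(seq) < 2:
        raise ValueError("sequence shorter than 2 nt")
    total = 0.0
    n_unambig = sum(seq.count(b) for b in "ACGT")
    for base in "ACGT":
        counts = [seq[phase::3].count(base) for phase in range(3)]
        pos_value = max(counts) / (min(counts) + 1.0)
        pos_prob = _lookup(
            pos_value, _FICKETT["position_thresholds"], _FICKETT["position_prob"][base]
        )
        total += pos_prob * _FICKETT["position_weight"][base]
        content = seq.count(base) / n_unambig if n_unambig else 0.0
        cont_prob = _lookup(
            content, _FICKETT["content_thresholds"], _FICKETT["content_prob"][base]
        )
        total += cont_prob * _FICKETT["content_weight"][base]
    return total


# ---------------------------------------------------------------------------
# Hexamer usage bias

_ALL_HEXAMERS = ["".join(p) for p in itertools.product("ACGT", repeat=6)]


def _hexamer_counts(seqs: list[str], step: int) -> dict[str, int]:
    counts = dict.fromkeys(_ALL_HEXAMERS, 0)
    for seq in seqs:
        seq = _norm_dna(seq)
        for i in range(0, len(seq) - 5, step):
            h = seq[i : i + 6]
            if h in counts:
                counts[h] += 1
    return counts


def build_hexamer_table(
    coding_seqs: list[str], noncoding_seqs: list[str], pseudocount: float = 1.0
) -> dict[str, float]:
    """log(f_coding / f_noncoding) per hexamer with additive smoothing.

    Coding frequencies come from in-frame (step 3) hexamers of the training
    ORFs; noncoding from step-1 hexamers of noncoding sequences.
    """
    if not coding_seqs or not noncoding_seqs:
        raise ValueError("empty training set for hexamer table")
    cod = _hexamer_counts(coding_seqs, step=3)
    non = _hexamer_counts(noncoding_seqs, step=1)
    tot_c = sum(cod.values()) + pseudocount * 4096
    tot_n = sum(non.values()) + pseudocount * 4096
    return {
        h: math.log(((cod[h] + pseudocount) / tot_c) / ((non[h] + pseudocount) / tot_n))
        for h in _ALL_HEXAMERS
    }


def hexamer_score(orf_seq: str, table: dict[str, float]) -> float:
    """Mean log-ratio over the ORF's in-frame hexamers; < 6 nt scores 0."""
    seq = _norm_dna(orf_seq)
    if len(seq) < 6:
        return 0.0
    vals = [table[seq[i : i + 6]] for i in range(0, len(seq) - 5, 3)
            if seq[i : i + 6] in table]
    if not vals:
        return 0.0
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Feature extraction


def coding_features(seq: str, hexamer_table: dict[str, float]) -> dict[str, float]:
    """The four CPAT features for one transcript sequence."""
    seq = _norm_dna(seq)
    orf = longest_orf(seq)
    orf_len = orf.length_nt if orf else 0
    orf_seq = seq[orf.start : orf.end] if orf else ""
    return {
        "orf_length_nt": float(orf_len),
        "orf_coverage": orf_len / len(seq) if seq else 0.0,
        "fickett_score": fickett_score(seq),
        "hexamer_score": hexamer_score(orf_seq, hexamer_table) if orf else 0.0,
    }


FEATURE_NAMES = ["orf_length_nt", "orf_coverage", "fickett_score", "hexamer_score"]


# ---------------------------------------------------------------------------
# Logistic regression by IRLS


@dataclass
class CodingModel:
    coefficients: np.ndarray  # intercept + 4 features, original scale
    feature_names: list[str]
    converged: bool
    n_iterations: int
    ridge_fallback: bool
    cutoff: float | None = None
    accuracy_at_cutoff: float | None = None
    roc_points: np.ndarray | None = None  # columns: threshold, fpr, tpr
    auc: float | None = None
    metadata: dict = field(default_factory=dict)

    def predict_proba(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            x = features[self.feature_names].to_numpy(dtype=float)
        else:
            x = np.asarray(features, dtype=float)
        eta = self.coefficients[0] + x @ self.coefficients[1:]
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))

    def to_json(self) -> str:
        obj = {
            "coefficients": self.coefficients.tolist(),
            "feature_names": self.feature_names,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "ridge_fallback": self.ridge_fallback,
            "cutoff": self.cutoff,
            "accuracy_at_cutoff": self.accuracy_at_cutoff,
            "auc": self.auc,
            "roc_points": None if self.roc_points is None else self.roc_points.tolist(),
            "metadata": self.metadata,
            "fickett_sha256": _FICKETT_SHA256,
        }
        return json.dumps(obj, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CodingModel":
        obj = json.loads(text)
        return cls(
            coefficients=np.asarray(obj["coefficients"], dtype=float),
            feature_names=obj["feature_names"],
            converged=obj["converged"],
            n_iterations=obj["n_iterations"],
            ridge_fallback=obj["ridge_fallback"],
            cutoff=obj["cutoff"],
            accuracy_at_cutoff=obj["accuracy_at_cutoff"],
            roc_points=None if obj["roc_points"] is None
            else np.asarray(obj["roc_points"], dtype=float),
            auc=obj["auc"],
            metadata=obj.get("metadata", {}),
        )


def _irls_logistic(
    x: np.ndarray, y: np.ndarray, ridge: float = 0.0,
    tol: float = 1e-8, max_iter: int = 100
) -> tuple[np.ndarray, bool, int]:
    """Newton/IRLS for logistic regression; x includes the intercept column.

    ``ridge`` penalizes all coefficients except the intercept.
    """
    n, p = x.shape
    beta = np.zeros(p)
    pen = np.full(p, ridge)
    pen[0] = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(x @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        z = eta + (y - mu) / w
        xtw = x.T * w
        a = xtw @ x + np.diag(pen)
        b = xtw @ z
        new_beta = np.linalg.solve(a, b)
        if np.max(np.abs(new_beta - beta)) < tol:
            beta = new_beta
            converged = True
            break
        beta = new_beta
    return beta, converged, it


def train_model(features: pd.DataFrame, labels: np.ndarray) -> CodingModel:
    """Fit the logistic coding model (label 1 = coding).

    Features are standardized internally; coefficients are reported on the
    original scale. Perfect separation (non-convergence or exploding
    coefficients) triggers a ridge (1e-4) refit flagged in the metadata.
    """
    x_raw = features[FEATURE_NAMES].to_numpy(dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(y) < 20:
        raise ValueError("need at least 20 training transcripts")
    if len(np.unique(y)) < 2:
        raise ValueError("both labels must be present")
    mean = x_raw.mean(axis=0)
    sd = x_raw.std(axis=0)
    sd[sd == 0] = 1.0
    x = np.column_stack([np.ones(len(y)), (x_raw - mean) / sd])

    beta, converged, it = _irls_logistic(x, y)
    ridge_fallback = False
    if not converged or np.max(np.abs(beta)) > 1e4:
        beta, converged, it = _irls_logistic(x, y, ridge=1e-4)
        ridge_fallback = True

    # back-transform to original scale
    coef = np.empty(len(beta))
    coef[1:] = beta[1:] / sd
    coef[0] = beta[0] - float(np.sum(beta[1:] * mean / sd))
    return CodingModel(
        coefficients=coef,
        feature_names=list(FEATURE_NAMES),
        converged=converged,
        n_iterations=it,
        ridge_fallback=ridge_fallback,
        metadata={"n_train": int(len(y)), "n_coding": int(y.sum())},
    )


# ---------------------------------------------------------------------------
# Cutoff calibration


def calibrate_cutoff(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, float, np.ndarray, float]:
    """Accuracy-maximizing coding-probability cutoff on a labelled benchmark.

    Every observed score is evaluated as a threshold with the rule
    "coding iff probability >= t"; ties go to the smallest threshold.
    Returns (cutoff, accuracy, roc_points, auc) with roc_points columns
    (threshold, fpr, tpr) and trapezoid AUC.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("cutoff calibration needs both classes")
    thresholds = np.unique(scores)
    best_t, best_acc = thresholds[0], -1.0
    roc = []
    for t in thresholds:
        pred = scores >= t
        acc = float((pred == (y == 1)).mean())
        tpr = float(pred[y == 1].mean())
        fpr = float(pred[y == 0].mean())
        roc.append((t, fpr, tpr))
        if acc > best_acc + 1e-12:
            best_acc, best_t = acc, float(t)
    roc_arr = np.asarray(roc, dtype=float)
    # ROC sorted by increasing fpr for the trapezoid; add the (0,0)/(1,1) anchors
    pts = np.vstack([[np.nan, 0.0, 0.0], roc_arr[::-1][:, :3], [np.nan, 1.0, 1.0]])
    order = np.lexsort((pts[:, 2], pts[:, 1]))
    pts = pts[order]
    auc = float(np.trapezoid(pts[:, 2], pts[:, 1]))
    return float(best_t), best_acc, roc_arr, auc


# ---------------------------------------------------------------------------
# ORF / homology discard


def orf_homology_filter(
    candidates: list[str],
    sequences: dict[str, str],
    max_orf_aa: int = 100,
    hits: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Discard low-coding-probability candidates that still look protein-like.

    A candidate is discarded when its longest *complete* ORF (start and stop
    present) spans >= ``max_orf_aa`` codons (inclusive; the stop codon counts),
    or when its id appears in the precomputed homology table (columns
    transcript_id, hit_id, evalue). Returns a verdict table.
    """
    hit_ids: set[str] = set()
    if hits is not None and len(hits):
        hit_ids = set(hits["transcript_id"].astype(str))
    rows = []
    for tid in candidates:
        seq = sequences[tid]
        complete = [h for h in find_orfs(seq) if h.has_start and h.has_stop]
        max_codons = max((h.n_codons for h in complete), default=0)
        if tid in hit_ids:
            kept, reason = False, "homology_hit"
        elif max_codons >= max_orf_aa:
            kept, reason = False, "long_orf"
        else:
            kept, reason = True, "ok"
        rows.append(
            {
                "transcript_id": tid,
                "longest_complete_orf_codons": max_codons,
                "kept": kept,
                "reason": reason,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "longest_complete_orf_codons", "kept", "reason"],
    )
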