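"""Per-group Spearman co-expression networks between DE lncRNAs and DE mRNAs.

Every DEL x DEG pair is tested within each condition's samples separately;
an edge is retained when |rho| > 0.8 (strict) and p < 0.01 (strict).
Edge p-values are raw by default — a deliberate, liberal choice — with an
optional BH correction per group.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

DEFAULT_RHO_MIN = 0.8
DEFAULT_P_MAX = 0.01


def spearman(x, y, method: str = "t") -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties get average ranks; rho is the Pearson correlation of the ranks.
    With ``method="t"`` (default) p comes from the t approximation with
    n-2 df (|rho| = 1 gives p = 0); ``method="exact"`` enumerates the
    permutation distribution (n <= 8 only). Zero-variance input yields
    (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("length mismatch")
    if n < 4:
        raise ValueError("need n >= 4 for a correlation test")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return float("nan"), float("nan")
    if np.array_equal(rx, ry):
        rho = 1.0
    elif np.array_equal(rx, len(rx) + 1.0 - ry):
        rho = -1.0
    else:
        rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
        rho = max(-1.0, min(1.0, rho))

    if method == "exact":
        if n > 8:
            raise ValueError("exact permutation p only supported for n <= 8")
        obs = abs(rho)
        count = total = 0
        centred_y = ry - ry.mean()
        centred_x = rx - rx.mean()
        denom = sx * sy * n
        for perm in itertools.permutations(range(n)):
            r = float(np.dot(centred_x, centred_y[list(perm)]) / denom)
            total += 1
            if abs(r) >= obs - 1e-12:
                count += 1
        return rho, count / total

    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, min(p, 1.0)


@dataclass(frozen=True)
class CorrelationEdge:
    lncrna_id: str
    mrna_id: str
    group: str  # "virgin" or "mated"
    rho: float
    p: float

    @property
    def sign(self) -> str:
        return "positive" if self.rho > 0 else "negative"


def build_network(
    tpm: pd.DataFrame,
    dels: list[str],
    degs: list[str],
    samples: pd.DataFrame,
    rho_min: float = DEFAULT_RHO_MIN,
    p_max: float = DEFAULT_P_MAX,
    adjust: bool = False,
    average_replicates: bool = False,
) -> list[CorrelationEdge]:
    """Retain DEL:DEG pairs with |rho| > rho_min and p < p_max per group.

    ``adjust`` applies BH to the edge p-values within each group before
    thresholding. ``average_replicates`` collapses technical runs to
    biological replicates first (default: all libraries are samples).
    """
    overlap = set(dels) & set(degs)
    if overlap:
        raise ValueError(f"DEL and DEG id sets overlap: {sorted(overlap)[:5]}")
    missing = (set(dels) | set(degs)) - set(tpm.index)
    if missing:
        raise ValueError(f"ids absent from TPM matrix: {sorted(missing)[:5]}")

    if average_replicates:
        from .de import average_technical_runs

        tpm, group_of = average_technical_runs(tpm, samples)
    else:
        group_of = samples["group"].reindex(tpm.columns)

    edges: list[CorrelationEdge] = []
    for group in ("virgin", "mated"):
        cols = group_of.index[group_of == group]
        if len(cols) < 4:
            raise ValueError(f"group {group!r} has < 4 samples")
        sub = tpm[cols]
        results = []
        for lnc in dels:
            xv = sub.loc[lnc].to_numpy()
            for mr in degs:
                rho, p = spearman(xv, sub.loc[mr].to_numpy())
                results.append((lnc, mr, rho, p))
        pvals = np.array([r[3] for r in results], dtype=float)
        effective_p = bh_adjust(pvals) if adjust else pvals
        for (lnc, mr, rho, _), p in zip(results, effective_p):
            if np.isnan(rho) or np.isnan(p):
                continue
            if abs(rho) > rho_min and p < p_max:
                edges.append(CorrelationEdge(lnc, mr, group, rho, float(p)))
    return edges


def edges_to_frame(edges: list[CorrelationEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lncrna_id": e.lncrna_id,
                "mrna_id": e.mrna_id,
                "group": e.group,
                "rho": e.rho,
                "p": e.p,
                "sign": e.sign,
            }
            for e in edges
        ],
        columns=["lncrna_id", "mrna_id", "group", "rho", "p", "sign"],
    )


def pair_categories(
    edges: list[CorrelationEdge], de_flags: pd.Series
) -> pd.DataFrame:
    """Cross-tabulate DEL direction x DEG direction among retained edges,
    with per-group proportions."""
    rows = []
    for e in edges:
        if e.lncrna_id not in de_flags.index or e.mrna_id not in de_flags.index:
            raise ValueError(f"edge endpoint lacks a DE flag: {e.lncrna_id}:{e.mrna_id}")
        rows.append(
            {
                "group": e.group,
                "del_direction": de_flags[e.lncrna_id],
                "deg_direction": de_flags[e.mrna_id],
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["group", "del_direction", "deg_direction", "count", "proportion"]
        )
    df = pd.DataFrame(rows)
    tab = (
        df.groupby(["group", "del_direction", "deg_direction"])
        .size()
        .rename("count")
        .reset_index()
    )
    tab["proportion"] = tab.groupby("group")["count"].transform(lambda c: c / c.sum())
    return tab


def ego_network(
    edges: list[CorrelationEdge], focal_id: str, known_ids: set[str] | None = None
) -> list[CorrelationEdge]:
    """Edges incident to one focal node (a lncRNA or an mRNA).

    An id absent from the edge list but present in ``known_ids`` returns an
    empty set; a completely unknown id is an error.
    """
    sub = [e for e in edges if focal_id in (e.lncrna_id, e.mrna_id)]
    if not sub:
        seen = {e.lncrna_id for e in edges} | {e.mrna_id for e in edges}
        if focal_id not in seen and (known_ids is None or focal_id not in known_ids):
            raise KeyError(f"unknown focal id {focal_id!r}")
    return sub
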