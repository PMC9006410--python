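"""Negative-binomial differential expression between two conditions.

The test pipeline mirrors the shape of the standard bulk RNA-seq workflow:
median-of-ratios size factors, a per-gene NB2 dispersion estimated by the
method of moments and shrunk toward a mean-dispersion trend, and a Wald test
on the group coefficient of a log-link NB GLM fit by IRLS (vectorised over
genes: the two-group design admits a per-group Newton update). Genes are
called differentially expressed when |log2FC| >= 1 (inclusive) and
BH-FDR < 0.01 (strict).

Condition labels are "virgin" (reference) and "mated"; log2FC > 0 means
higher expression in mated samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

REFERENCE_GROUP = "virgin"
TREATMENT_GROUP = "mated"
DISPERSION_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# TPM


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from counts and effective lengths (nt).

    Each sample column sums to 1e6 unless it is all-zero, in which case it
    stays all-zero.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"missing lengths for features: {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    rate = counts.div(lengths, axis=0)
    colsum = rate.sum(axis=0)
    scale = np.where(colsum > 0, 1e6 / colsum.replace(0, np.nan), 0.0)
    return rate.mul(scale, axis=1).fillna(0.0)


# ---------------------------------------------------------------------------
# Prefilter


def prefilter_genes(
    counts: pd.DataFrame, groups: pd.Series, min_nonzero: int = 3
) -> pd.Index:
    """Keep genes with nonzero counts in >= min_nonzero samples of at least
    one group."""
    group_names = groups.unique()
    if len(group_names) != 2:
        raise ValueError("prefilter expects exactly two groups")
    nz = counts > 0
    keep = pd.Series(False, index=counts.index)
    for g in group_names:
        cols = groups.index[groups == g]
        keep |= nz[cols].sum(axis=1) >= min_nonzero
    return counts.index[keep]


# ---------------------------------------------------------------------------
# Size factors (median of ratios)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors.

    For genes with nonzero counts in every sample, factor_j = median over
    genes of count_gj / geometric-mean_g.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; prefilter the matrix first"
        )
    sub = mat[all_nonzero]
    log_geo = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_geo[:, None]
    return pd.Series(np.exp(np.median(ratios, axis=0)), index=counts.columns)


# ---------------------------------------------------------------------------
# Dispersion


def estimate_dispersion(
    counts: pd.DataFrame, factors: pd.Series, groups: pd.Series
) -> pd.Series:
    """Per-gene NB2 dispersion: method of moments within groups, then
    50/50 log-scale shrinkage toward a least-squares mean-dispersion trend.
    """
    norm = counts.div(factors, axis=1)
    group_names = list(groups.unique())
    num = np.zeros(len(counts))
    den = np.zeros(len(counts))
    for g in group_names:
        cols = groups.index[groups == g]
        if len(cols) < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples")
        sub = norm[cols].to_numpy()
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        df = len(cols) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (var - mu) / mu**2
        a = np.where(np.isfinite(a), a, 0.0)
        num += df * a
        den += df
    alpha = np.maximum(num / den, DISPERSION_FLOOR)

    mu_all = norm.to_numpy().mean(axis=1)
    ok = mu_all > 0
    log_mu = np.log(mu_all[ok])
    log_a = np.log(alpha[ok])
    if ok.sum() >= 2 and np.ptp(log_mu) > 0:
        slope, intercept = np.polyfit(log_mu, log_a, 1)
    else:
        slope, intercept = 0.0, float(np.mean(log_a)) if ok.any() else 0.0
    trend = np.full(len(alpha), np.exp(intercept))
    trend[ok] = np.exp(intercept + slope * log_mu)
    shrunk = np.exp(0.5 * np.log(alpha) + 0.5 * np.log(np.maximum(trend, DISPERSION_FLOOR)))
    return pd.Series(np.maximum(shrunk, DISPERSION_FLOOR), index=counts.index)


# ---------------------------------------------------------------------------
# NB Wald test


def nb_wald_test(
    counts: pd.DataFrame,
    factors: pd.Series,
    dispersions: pd.Series,
    groups: pd.Series,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> pd.DataFrame:
    """Wald test on the group coefficient of a log-link NB GLM.

    The two-group design with size-factor offsets factorizes per group, so
    IRLS reduces to a scalar Newton update on each group's log-mean,
    vectorised over all genes. log2FC is mated-vs-virgin. Genes whose fit
    does not converge get NA p-values and converged=False.

    Returns a table with baseMean, log2FoldChange, lfcSE, pvalue, converged.
    """
    y = counts.to_numpy(dtype=float)
    s = factors.reindex(counts.columns).to_numpy(dtype=float)
    alpha = dispersions.reindex(counts.index).to_numpy(dtype=float)[:, None]
    gvec = groups.reindex(counts.columns)
    masks = {
        REFERENCE_GROUP: (gvec == REFERENCE_GROUP).to_numpy(),
        TREATMENT_GROUP: (gvec == TREATMENT_GROUP).to_numpy(),
    }
    if not masks[REFERENCE_GROUP].any() or not masks[TREATMENT_GROUP].any():
        raise ValueError("both 'virgin' and 'mated' samples are required")

    n_genes = y.shape[0]
    beta = {}
    info = {}
    converged = np.ones(n_genes, dtype=bool)
    for gname, mask in masks.items():
        yg = y[:, mask]
        sg = s[mask]
        # moment start: log(weighted mean of normalized counts), floored
        init = np.log(np.maximum(yg.sum(axis=1) / sg.sum(), 1e-8))
        b = init.copy()
        done = np.zeros(n_genes, dtype=bool)
        for _ in range(max_iter):
            mu = sg[None, :] * np.exp(b)[:, None]
            w = mu / (1.0 + alpha * mu)  # IRLS working weights
            score = ((yg - mu) / (1.0 + alpha * mu)).sum(axis=1)
            wsum = w.sum(axis=1)
            step = score / np.maximum(wsum, 1e-12)
            step = np.clip(step, -5, 5)
            b_new = np.where(done, b, b + step)
            done |= np.abs(b_new - b) < tol
            b = b_new
            if done.all():
                break
        converged &= done
        mu = sg[None, :] * np.exp(b)[:, None]
        w = mu / (1.0 + alpha * mu)
        beta[gname] = b
        info[gname] = w.sum(axis=1)

    log2fc = (beta[TREATMENT_GROUP] - beta[REFERENCE_GROUP]) / np.log(2.0)
    var = 1.0 / info[TREATMENT_GROUP] + 1.0 / info[REFERENCE_GROUP]
    se_ln = np.sqrt(var)
    wald = (beta[TREATMENT_GROUP] - beta[REFERENCE_GROUP]) / se_ln
    pvals = 2.0 * stats.norm.sf(np.abs(wald))
    pvals = np.where(converged, pvals, np.nan)

    base_mean = (y / s[None, :]).mean(axis=1)
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": log2fc,
            "lfcSE": se_ln / np.log(2.0),
            "pvalue": pvals,
            "converged": converged,
        },
        index=counts.index,
    )


# ---------------------------------------------------------------------------
# BH adjustment and DE calls


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NA propagates."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pv)
    if m:
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = np.minimum(ranked, 1.0)
        out[ok] = adj
    return out


def call_de(
    results: pd.DataFrame, lfc_min: float = 1.0, fdr_max: float = 0.01
) -> pd.Series:
    """DE flags: |log2FC| >= lfc_min (inclusive) and FDR < fdr_max (strict)."""
    lfc = results["log2FoldChange"]
    fdr = results["padj"]
    flags = pd.Series("ns", index=results.index)
    sig = fdr < fdr_max  # NaN compares False
    flags[sig & (lfc >= lfc_min)] = "up_in_mated"
    flags[sig & (lfc <= -lfc_min)] = "up_in_virgin"
    return flags


def run_de(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    lengths: pd.Series,
    min_nonzero: int = 3,
    lfc_min: float = 1.0,
    fdr_max: float = 0.01,
) -> pd.DataFrame:
    """Full DE pipeline: prefilter -> size factors -> dispersion -> Wald ->
    BH -> flags. Technical runs are treated as samples for testing."""
    groups = samples["group"]
    kept = prefilter_genes(counts, groups, min_nonzero=min_nonzero)
    sub = counts.loc[kept]
    sf = size_factors(sub)
    disp = estimate_dispersion(sub, sf, groups)
    res = nb_wald_test(sub, sf, disp, groups)
    res["padj"] = bh_adjust(res["pvalue"].to_numpy())
    res["dispersion"] = disp
    res["de_flag"] = call_de(res, lfc_min=lfc_min, fdr_max=fdr_max)
    res["length"] = lengths.reindex(res.index)
    return res


# ---------------------------------------------------------------------------
# Clustering of DE genes


def average_technical_runs(
    tpm: pd.DataFrame, samples: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Average TPM over technical runs per biological replicate.

    Returns the averaged matrix (columns = "group.biorep") and the group of
    each averaged column.
    """
    key = samples["group"].astype(str) + "." + samples["biological_replicate"].astype(str)
    averaged = tpm.T.groupby(key.reindex(tpm.columns)).mean().T
    grp = pd.Series(
        [c.split(".", 1)[0] for c in averaged.columns], index=averaged.columns
    )
    return averaged, grp


def cluster_de_genes(
    tpm: pd.DataFrame, de_genes: list[str], samples: pd.DataFrame
) -> dict:
    """Z-scored hierarchical clustering (average linkage, Euclidean) of DE
    genes over biological replicates.

    Technical runs are averaged per replicate, each gene row is z-scored
    (population sd; zero-variance rows become zero vectors and are flagged),
    and both axes are clustered. Returns gene/sample leaf orders, linkage
    matrices, the z matrix and the flagged genes.
    """
    if len(de_genes) < 2:
        raise ValueError("need >= 2 DE genes to cluster")
    averaged, grp = average_technical_runs(tpm.loc[de_genes], samples)
    mat = averaged.to_numpy(dtype=float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    flat = (sd[:, 0] == 0)
    sd[sd == 0] = 1.0
    z = (mat - mean) / sd
    z[flat, :] = 0.0

    gene_linkage = hierarchy.linkage(z, method="average", metric="euclidean")
    sample_linkage = hierarchy.linkage(z.T, method="average", metric="euclidean")
    gene_order = hierarchy.leaves_list(gene_linkage)
    sample_order = hierarchy.leaves_list(sample_linkage)
    return {
        "z": pd.DataFrame(z, index=averaged.index, columns=averaged.columns),
        "gene_order": [averaged.index[i] for i in gene_order],
        "sample_order": [averaged.columns[i] for i in sample_order],
        "gene_linkage": gene_linkage,
        "sample_linkage": sample_linkage,
        "sample_groups": grp,
        "zero_variance_genes": [g for g, f in zip(averaged.index, flat) if f],
    }


def top_split_partition(linkage: np.ndarray, labels: list[str]) -> list[set[str]]:
    """The two-cluster partition at the dendrogram's top split."""
    assign = hierarchy.fcluster(linkage, t=2, criterion="maxclust")
    out: dict[int, set[str]] = {}
    for lab, a in zip(labels, assign):
        out.setdefault(int(a), set()).add(lab)
    return list(out.values())
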