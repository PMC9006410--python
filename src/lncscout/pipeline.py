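"""End-to-end orchestration: classify -> coding potential -> DE -> correlation
-> triplex, with a machine-readable run report and a truth-evaluation harness
for synthetic runs.

Stage outputs are plain TSV/BED/JSON files written before the next stage
starts; re-running with an identical config and seed reproduces them
byte-identically.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import filter_candidates
from .coding import (
    build_hexamer_table,
    calibrate_cutoff,
    coding_features,
    longest_orf,
    orf_homology_filter,
    train_model,
)
from .de import compute_tpm, cluster_de_genes, run_de, top_split_partition
from .io import write_bed
from .models import GenomicInterval
from .network import build_network, edges_to_frame, pair_categories
from .simulate import SyntheticDataset
from .triplex import TriplexParams, cluster_tts, matches_to_frame, scan_lncrna_vs_locus


@dataclass
class PipelineParams:
    min_length: int = 200
    runon_window: int = 2000
    coding_cutoff: float | None = None  # None = calibrate on the reference benchmark
    max_orf_aa: int = 100
    homology_hits: pd.DataFrame | None = None
    min_nonzero: int = 3
    lfc_min: float = 1.0
    fdr_max: float = 0.01
    rho_min: float = 0.8
    p_max: float = 0.01
    triplex: TriplexParams = field(default_factory=TriplexParams)
    locus_flank: int = 1000
    tts_cluster_gap: int = 10
    tts_high_frequency_k: int = 10


class StageError(RuntimeError):
    def __init__(self, stage: str, reason: str) -> None:
        super().__init__(f"stage {stage!r} failed: {reason}")
        self.stage = stage


def run_pipeline(
    dataset: SyntheticDataset,
    outdir: str | Path,
    params: PipelineParams | None = None,
) -> dict:
    """Run all stages on a dataset, writing stage outputs under ``outdir``.

    Returns the run report (also written as run_report.json).
    """
    params = params or PipelineParams()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": dataset.config.seed,
        "parameters": {
            "min_length": params.min_length,
            "runon_window": params.runon_window,
            "coding_cutoff": params.coding_cutoff,
            "max_orf_aa": params.max_orf_aa,
            "lfc_min": params.lfc_min,
            "fdr_max": params.fdr_max,
            "rho_min": params.rho_min,
            "p_max": params.p_max,
            "triplex_min_length": params.triplex.min_length,
        },
        "stages": {},
    }
    sequences = dataset.sequences()

    # ---- stage 1: classify ------------------------------------------------
    t0 = time.perf_counter()
    try:
        candidates = filter_candidates(
            dataset.novels,
            dataset.reference,
            min_length=params.min_length,
            runon_window=params.runon_window,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("classify", str(exc)) from exc
    candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
    kept_ids = candidates.loc[candidates["kept"], "transcript_id"].tolist()
    report["stages"]["classify"] = {
        "n_input": len(candidates),
        "n_kept": len(kept_ids),
        "n_rejected": int((~candidates["kept"]).sum()),
        "rejected_by_reason": candidates.loc[~candidates["kept"], "reason"]
        .value_counts()
        .to_dict(),
        "seconds": round(time.perf_counter() - t0, 3),
    }

    # ---- stage 2: coding potential ---------------------------------------
    t0 = time.perf_counter()
    try:
        ref_mrna = [t.transcript_id for t in dataset.reference if t.biotype == "mRNA"]
        ref_lnc = [t.transcript_id for t in dataset.reference if t.biotype == "lncRNA"]
        if not ref_mrna or not ref_lnc:
            raise ValueError("need reference mRNAs and lncRNAs to train the model")
        coding_orfs = []
        for tid in ref_mrna:
            orf = longest_orf(sequences[tid])
            if orf:
                coding_orfs.append(sequences[tid][orf.start : orf.end])
        hex_table = build_hexamer_table(
            coding_orfs, [sequences[t] for t in ref_lnc]
        )
        train_ids = ref_mrna + ref_lnc
        feats = pd.DataFrame(
            [coding_features(sequences[t], hex_table) for t in train_ids],
            index=train_ids,
        )
        labels = np.array([1] * len(ref_mrna) + [0] * len(ref_lnc))
        model = train_model(feats, labels)
        bench_scores = model.predict_proba(feats)
        cutoff, acc, roc, auc = calibrate_cutoff(bench_scores, labels)
        model.cutoff = params.coding_cutoff if params.coding_cutoff is not None else cutoff
        model.accuracy_at_cutoff = acc
        model.roc_points = roc
        model.auc = auc
        (out / "model.json").write_text(model.to_json())

        cand_feats = pd.DataFrame(
            [coding_features(sequences[t], hex_table) for t in kept_ids],
            index=kept_ids,
        )
        scores = (
            model.predict_proba(cand_feats) if kept_ids else np.array([])
        )
        scored = pd.DataFrame(
            {"transcript_id": kept_ids, "coding_probability": scores}
        )
        scored["below_cutoff"] = scored["coding_probability"] < model.cutoff
        noncoding_ids = scored.loc[scored["below_cutoff"], "transcript_id"].tolist()
        orf_verdicts = orf_homology_filter(
            noncoding_ids, sequences,
            max_orf_aa=params.max_orf_aa, hits=params.homology_hits,
        )
        scored = scored.merge(
            orf_verdicts[["transcript_id", "kept", "reason"]],
            on="transcript_id", how="left",
        )
        scored["kept"] = scored["kept"].astype(object).where(
            scored["kept"].notna(), False
        )
        scored.loc[~scored["below_cutoff"], "reason"] = "coding_probability"
        scored.to_csv(out / "scored.tsv", sep="\t", index=False)
        novel_lncrna_ids = orf_verdicts.loc[
            orf_verdicts["kept"], "transcript_id"
        ].tolist()
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("codepot", str(exc)) from exc
    report["stages"]["codepot"] = {
        "n_input": len(kept_ids),
        "n_below_cutoff": len(noncoding_ids),
        "n_kept": len(novel_lncrna_ids),
        "n_rejected": len(kept_ids) - len(novel_lncrna_ids),
        "cutoff": model.cutoff,
        "benchmark_accuracy": acc,
        "benchmark_auc": auc,
        "seconds": round(time.perf_counter() - t0, 3),
    }

    # ---- stage 3: differential expression --------------------------------
    t0 = time.perf_counter()
    try:
        de_res = run_de(
            dataset.counts,
            dataset.samples,
            dataset.lengths,
            min_nonzero=params.min_nonzero,
            lfc_min=params.lfc_min,
            fdr_max=params.fdr_max,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("de", str(exc)) from exc
    de_res.to_csv(out / "de_results.tsv", sep="\t", index_label="transcript_id")
    tpm = compute_tpm(dataset.counts, dataset.lengths)
    tpm.to_csv(out / "tpm.tsv", sep="\t", index_label="transcript_id")

    biotype = {t.transcript_id: t.biotype for t in dataset.all_transcripts}
    lncrna_universe = set(novel_lncrna_ids) | {
        t for t, b in biotype.items() if b == "lncRNA"
    }
    de_called = de_res.index[de_res["de_flag"] != "ns"]
    degs = [g for g in de_called if biotype.get(g) == "mRNA"]
    dels = [g for g in de_called if g in lncrna_universe]
    flags = de_res["de_flag"]
    report["stages"]["de"] = {
        "n_tested": int(len(de_res)),
        "n_deg": len(degs),
        "n_del": len(dels),
        "deg_up_in_mated": int(sum(flags[g] == "up_in_mated" for g in degs)),
        "deg_up_in_virgin": int(sum(flags[g] == "up_in_virgin" for g in degs)),
        "del_up_in_mated": int(sum(flags[g] == "up_in_mated" for g in dels)),
        "del_up_in_virgin": int(sum(flags[g] == "up_in_virgin" for g in dels)),
        "seconds": round(time.perf_counter() - t0, 3),
    }

    # clustering of DE genes (technical runs averaged)
    de_genes = list(degs) + list(dels)
    if len(de_genes) >= 2:
        clust = cluster_de_genes(tpm, de_genes, dataset.samples)
        pd.Series(clust["gene_order"], name="transcript_id").to_csv(
            out / "cluster_gene_order.tsv", sep="\t", index=False
        )
        pd.Series(clust["sample_order"], name="sample").to_csv(
            out / "cluster_sample_order.tsv", sep="\t", index=False
        )
        partition = top_split_partition(
            clust["sample_linkage"], list(clust["z"].columns)
        )
        report["stages"]["de"]["sample_top_split"] = sorted(
            sorted(p) for p in partition
        )

    # ---- stage 4: correlation network ------------------------------------
    t0 = time.perf_counter()
    try:
        if dels and degs:
            edges = build_network(
                tpm, dels, degs, dataset.samples,
                rho_min=params.rho_min, p_max=params.p_max,
            )
        else:
            edges = []
    except Exception as exc:  # noqa: BLE001
        raise StageError("corr", str(exc)) from exc
    edge_df = edges_to_frame(edges)
    edge_df.to_csv(out / "edges.tsv", sep="\t", index=False)
    cats = pair_categories(edges, flags)
    cats.to_csv(out / "pair_categories.tsv", sep="\t", index=False)
    report["stages"]["corr"] = {
        "n_pairs_tested": 2 * len(dels) * len(degs),
        "n_edges": len(edges),
        "edges_virgin": int((edge_df["group"] == "virgin").sum()),
        "edges_mated": int((edge_df["group"] == "mated").sum()),
        "seconds": round(time.perf_counter() - t0, 3),
    }

    # ---- stage 5: triplex -------------------------------------------------
    t0 = time.perf_counter()
    try:
        matches = []
        focal = None
        if edges:
            # every correlated DEL is scanned against the loci of its
            # correlated DEGs; the strongest-fold-change DEL is the report's
            # focal lncRNA
            edge_dels = sorted(
                {e.lncrna_id for e in edges},
                key=lambda g: (-abs(de_res.loc[g, "log2FoldChange"]), g),
            )
            focal = edge_dels[0]
            tx_by_id = {t.transcript_id: t for t in dataset.all_transcripts}
            scan_pairs = sorted({(e.lncrna_id, e.mrna_id) for e in edges})
            for lnc_id, mrna_id in scan_pairs:
                tx = tx_by_id[mrna_id]
                span = tx.interval
                locus = GenomicInterval(
                    span.scaffold,
                    max(0, span.start - params.locus_flank),
                    min(len(dataset.genome[span.scaffold]),
                        span.end + params.locus_flank),
                    ".",
                )
                matches.extend(
                    scan_lncrna_vs_locus(
                        sequences[lnc_id], locus, dataset.genome,
                        [tx], params.triplex,
                    )
                )
        clusters = cluster_tts(
            matches, dataset.genome,
            gap=params.tts_cluster_gap,
            high_frequency_k=params.tts_high_frequency_k,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("triplex", str(exc)) from exc
    match_df = matches_to_frame(matches)
    match_df.to_csv(out / "triplex_matches.tsv", sep="\t", index=False)
    write_bed(
        [m.tts for m in matches], out / "tts.bed",
        names=[f"tts_{i}" for i in range(len(matches))],
        scores=[m.score for m in matches],
    )
    pd.DataFrame(
        [
            {
                "scaffold": c.interval.scaffold,
                "start": c.interval.start,
                "end": c.interval.end,
                "n_members": c.n_members,
                "ga_fraction": c.ga_fraction,
                "high_frequency": c.high_frequency,
            }
            for c in clusters
        ],
        columns=["scaffold", "start", "end", "n_members", "ga_fraction",
                 "high_frequency"],
    ).to_csv(out / "tts_clusters.tsv", sep="\t", index=False)
    report["stages"]["triplex"] = {
        "focal_lncrna": focal,
        "n_matches": len(matches),
        "n_clusters": len(clusters),
        "n_high_frequency_clusters": int(sum(c.high_frequency for c in clusters)),
        "seconds": round(time.perf_counter() - t0, 3),
    }

    report["novel_lncrna_ids"] = novel_lncrna_ids
    report["deg_ids"] = degs
    report["del_ids"] = dels
    (out / "run_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


# ---------------------------------------------------------------------------
# Truth evaluation


def _rate(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def evaluate_against_truth(
    outdir: str | Path, report: dict, dataset: SyntheticDataset
) -> pd.DataFrame:
    """Sensitivity/precision per stage against the planted truth.

    lncRNA identification truth = planted novels of class i/y/p/u with
    spliced length >= 200; DE truth = planted nonzero fold-changes;
    edge truth = planted copula pairs (right pair, right group); triplex
    truth = a reported match overlapping the planted tract. Undefined
    rates (zero denominator) are NA.
    """
    out = Path(outdir)
    truth = dataset.truth
    lengths = {t.transcript_id: t.spliced_length for t in dataset.novels}

    expected_lnc = {
        row["transcript_id"]
        for _, row in truth.transcripts.iterrows()
        if row["true_class_code"] in {"i", "y", "p", "u"}
        and lengths.get(row["transcript_id"], 0) >= 200
    }
    missing = expected_lnc - set(lengths)
    if missing:
        raise ValueError(f"truth/output id mismatch: {sorted(missing)[:5]}")
    found_lnc = set(report["novel_lncrna_ids"])
    rows = [
        {
            "stage": "lncrna_identification",
            "sensitivity": _rate(len(found_lnc & expected_lnc), len(expected_lnc)),
            "precision": _rate(len(found_lnc & expected_lnc), len(found_lnc)),
        }
    ]

    de_truth = truth.de.set_index("transcript_id")
    called = set(report["deg_ids"]) | set(report["del_ids"])
    planted = set(de_truth.index[de_truth["is_de"]])
    rows.append(
        {
            "stage": "de",
            "sensitivity": _rate(len(called & planted), len(planted)),
            "precision": _rate(len(called & planted), len(called)),
        }
    )

    edge_df = pd.read_csv(out / "edges.tsv", sep="\t")
    edge_set = {
        (r["lncrna_id"], r["mrna_id"], r["group"]) for _, r in edge_df.iterrows()
    }
    n_recovered = sum(
        (pr["lncrna_id"], pr["mrna_id"], pr["group"]) in edge_set
        for _, pr in truth.pairs.iterrows()
    )
    truth_edge_set = {
        (pr["lncrna_id"], pr["mrna_id"], pr["group"])
        for _, pr in truth.pairs.iterrows()
    }
    rows.append(
        {
            "stage": "edges",
            "sensitivity": _rate(n_recovered, len(truth.pairs)),
            "precision": _rate(
                sum(e in truth_edge_set for e in edge_set), len(edge_set)
            ),
        }
    )

    match_df = pd.read_csv(out / "triplex_matches.tsv", sep="\t")
    n_plant_hit = 0
    for _, pr in truth.triplex.iterrows():
        hit = (
            (match_df["tts_scaffold"] == pr["scaffold"])
            & (match_df["tts_start"] < pr["tts_end"])
            & (match_df["tts_end"] > pr["tts_start"])
        )
        n_plant_hit += int(hit.any())
    rows.append(
        {
            "stage": "triplex",
            "sensitivity": _rate(n_plant_hit, len(truth.triplex)),
            "precision": None,
        }
    )
    return pd.DataFrame(rows, columns=["stage", "sensitivity", "precision"])
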