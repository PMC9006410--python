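"""Synthetic-data generator: determinism, planted structure, NB calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncscout.classify import assign_class_code
from lncscout.coding import longest_orf
from lncscout.models import extract_spliced_sequence
from lncscout.simulate import (
    ConfigError,
    SimulationConfig,
    TruthTable,
    make_design,
    plant_triplex,
    simulate_all,
    simulate_counts,
    simulate_genome_and_annotation,
    simulate_novel_transcripts,
    write_dataset,
)

SMALL = dict(
    n_scaffolds=2, scaffold_length=200_000, n_ref_mrna=20, n_ref_lncrna=10
)


def _de_truth(genes, lfcs):
    truth = TruthTable()
    truth.de = pd.DataFrame(
        {
            "transcript_id": genes,
            "log2fc": lfcs,
            "is_de": [f != 0 for f in lfcs],
            "biotype": ["mRNA"] * len(genes),
        }
    )
    return truth


class TestGenomeAndAnnotation:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(seed=5, **SMALL)
        a = tmp_path / "a"
        b = tmp_path / "b"
        write_dataset(simulate_all(cfg), a)
        write_dataset(simulate_all(cfg), b)
        for name in ("genome.fasta", "reference.gtf", "novel.gtf", "counts.tsv"):
            assert (a / name).read_bytes() == (b / name).read_bytes(), name

    def test_no_lncrna_config(self):
        cfg = SimulationConfig(seed=0, n_ref_lncrna=0, **{
            k: v for k, v in SMALL.items() if k != "n_ref_lncrna"})
        _, refs, _ = simulate_genome_and_annotation(cfg)
        assert all(t.biotype != "lncRNA" for t in refs)

    def test_mrnas_carry_long_orfs(self):
        cfg = SimulationConfig(seed=1, **SMALL)
        genome, refs, _ = simulate_genome_and_annotation(cfg)
        for tx in refs:
            if tx.biotype == "mRNA":
                seq = extract_spliced_sequence(tx, genome)
                orf = longest_orf(seq)
                assert orf is not None and orf.length_nt >= 300, tx.transcript_id

    def test_reference_lncrnas_are_spliced(self):
        cfg = SimulationConfig(seed=2, **SMALL)
        _, refs, _ = simulate_genome_and_annotation(cfg)
        assert all(
            t.n_exons >= 2 for t in refs if t.biotype == "lncRNA"
        )

    def test_too_many_genes_raises(self):
        with pytest.raises(ConfigError, match="too short"):
            cfg = SimulationConfig(seed=0, n_scaffolds=1, scaffold_length=50_000,
                                   n_ref_mrna=30, n_ref_lncrna=10)
            simulate_genome_and_annotation(cfg)


class TestNovelPlants:
    def test_planted_class_codes_recovered(self, dataset):
        truth = dataset.truth.transcripts.set_index("transcript_id")
        for tx in dataset.novels:
            expected = truth.loc[tx.transcript_id, "true_class_code"]
            assert assign_class_code(tx, dataset.reference) == expected

    def test_decoys_overlap_reference_exons(self, dataset):
        truth = dataset.truth.transcripts
        decoys = truth.loc[truth["cohort"] == "decoy", "transcript_id"]
        by_id = {t.transcript_id: t for t in dataset.novels}
        for tid in decoys:
            assert assign_class_code(by_id[tid], dataset.reference) not in "iypu"

    def test_zero_novels_gives_empty(self):
        cfg = SimulationConfig(seed=0, n_novel_i=0, n_novel_y=0, n_novel_p=0,
                               n_novel_u=0, n_decoy_coding_overlap=0, **SMALL)
        genome, refs, _ = simulate_genome_and_annotation(cfg)
        novels, rows = simulate_novel_transcripts(refs, genome, cfg)
        assert novels == [] and rows.empty

    def test_empty_annotation_raises(self):
        cfg = SimulationConfig(seed=0, **SMALL)
        with pytest.raises(ConfigError):
            simulate_novel_transcripts([], {"s": "ACGT" * 100}, cfg)


class TestCounts:
    def test_same_seed_identical_matrix(self):
        cfg = SimulationConfig(seed=3)
        design = make_design(cfg)
        truth = _de_truth(["a", "b", "c"], [0.0, 1.0, -2.0])
        c1, _ = simulate_counts(design, truth, cfg,
                                rng=np.random.default_rng(7))
        c2, _ = simulate_counts(design, truth, cfg,
                                rng=np.random.default_rng(7))
        assert c1.equals(c2)

    def test_design_shape_32_libraries(self):
        design = make_design(SimulationConfig(seed=0))
        assert len(design) == 32
        assert design.groupby("group").size().tolist() == [16, 16]

    def test_null_genes_group_means_within_sampling_error(self):
        # planted log2FC = 0: |mean difference| < 3 SE for >= 95% of genes
        cfg = SimulationConfig(seed=0)
        design = make_design(cfg)
        ok = total = 0
        for seed in range(20):
            truth = _de_truth([f"g{i}" for i in range(30)], [0.0] * 30)
            counts, _ = simulate_counts(design, truth, cfg,
                                        rng=np.random.default_rng(seed))
            # technical runs share a biological latent, so the independent
            # sampling unit is the biological replicate
            key = design["group"] + "." + design["biological_replicate"]
            rep_means = counts.T.groupby(key.reindex(counts.columns)).mean().T
            a = rep_means.loc[:, rep_means.columns.str.startswith("virgin")]
            b = rep_means.loc[:, rep_means.columns.str.startswith("mated")]
            diff = a.mean(axis=1) - b.mean(axis=1)
            se = np.sqrt(
                a.var(axis=1, ddof=1) / a.shape[1]
                + b.var(axis=1, ddof=1) / b.shape[1]
            )
            ok += int((diff.abs() < 3 * se).sum())
            total += 30
        assert ok / total >= 0.95

    def test_poisson_limit_variance_to_mean(self):
        cfg = SimulationConfig(seed=0, dispersion_range=(1e-8, 1e-7),
                               mean_range=(200.0, 200.0), library_size_sd=1e-12,
                               n_bio_replicates=400, n_technical_runs=1)
        design = make_design(cfg)
        truth = _de_truth([f"g{i}" for i in range(20)], [0.0] * 20)
        counts, _ = simulate_counts(design, truth, cfg,
                                    rng=np.random.default_rng(1))
        ratio = counts.var(axis=1, ddof=1) / counts.mean(axis=1)
        assert ratio.mean() == pytest.approx(1.0, abs=0.15)

    def test_nb_moments_recover_config_parameters(self):
        cfg = SimulationConfig(seed=0, dispersion_range=(0.2, 0.2),
                               mean_range=(300.0, 300.0), library_size_sd=1e-12,
                               n_bio_replicates=600, n_technical_runs=1)
        design = make_design(cfg)
        truth = _de_truth([f"g{i}" for i in range(10)], [0.0] * 10)
        counts, params = simulate_counts(design, truth, cfg,
                                         rng=np.random.default_rng(2))
        mean_hat = counts.mean(axis=1)
        alpha_hat = (counts.var(axis=1, ddof=1) - mean_hat) / mean_hat**2
        assert mean_hat.mean() == pytest.approx(300.0, rel=0.05)
        assert alpha_hat.mean() == pytest.approx(0.2, rel=0.25)

    def test_planted_fold_change_realized(self):
        cfg = SimulationConfig(seed=0)
        design = make_design(cfg)
        truth = _de_truth([f"g{i}" for i in range(40)], [2.0] * 40)
        counts, _ = simulate_counts(design, truth, cfg,
                                    rng=np.random.default_rng(3))
        grp = design["group"]
        ratio = (
            counts.loc[:, (grp == "mated").to_numpy()].mean(axis=1)
            / counts.loc[:, (grp == "virgin").to_numpy()].mean(axis=1)
        )
        assert np.log2(ratio).mean() == pytest.approx(2.0, abs=0.15)

    def test_technical_runs_share_biological_latent(self):
        # within-biorep variation (Poisson only) is smaller than
        # across-biorep variation (Gamma latent + Poisson)
        cfg = SimulationConfig(seed=0, dispersion_range=(0.3, 0.3),
                               mean_range=(500.0, 500.0), library_size_sd=1e-12)
        design = make_design(cfg)
        truth = _de_truth([f"g{i}" for i in range(40)], [0.0] * 40)
        counts, _ = simulate_counts(design, truth, cfg,
                                    rng=np.random.default_rng(4))
        key = design["group"] + "." + design["biological_replicate"]
        within = counts.T.groupby(key.reindex(counts.columns)).std().mean().mean()
        biorep_means = counts.T.groupby(key.reindex(counts.columns)).mean()
        across = biorep_means.std().mean()
        assert within < across

    def test_copula_pair_spearman_near_target(self):
        cfg = SimulationConfig(seed=0)
        design = make_design(cfg)
        rhos = []
        for seed in range(10):
            truth = _de_truth(["lnc", "mrna"] + [f"g{i}" for i in range(8)],
                              [0.0] * 10)
            truth.pairs = pd.DataFrame(
                {"lncrna_id": ["lnc"], "mrna_id": ["mrna"],
                 "copula_rho": [0.95], "group": ["mated"]}
            )
            counts, _ = simulate_counts(design, truth, cfg,
                                        rng=np.random.default_rng(seed))
            grp = design["group"]
            cols = (grp == "mated").to_numpy()
            rhos.append(
                stats.spearmanr(
                    counts.loc["lnc"].to_numpy()[cols],
                    counts.loc["mrna"].to_numpy()[cols],
                ).statistic
            )
        assert np.mean(rhos) >= 0.85

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=0, mean_range=(0.0, 100.0))


class TestTriplexPlant:
    def test_plant_recovered_by_search(self, dataset):
        from lncscout.triplex import find_triplexes

        truth = dataset.truth.triplex.iloc[0]
        seqs = dataset.sequences()
        lnc_seq = seqs[truth["lncrna_id"]]
        tract = dataset.genome[truth["scaffold"]][
            truth["tts_start"] : truth["tts_end"]
        ]
        assert set(tract) <= {"G", "A"}  # purity 1.0 by default
        matches = find_triplexes(lnc_seq, tract)
        assert any(
            m.errors == 0 and m.length == len(tract) for m in matches
        )

    def test_low_purity_tract_defeats_search(self):
        cfg = SimulationConfig(seed=6, triplex_ga_purity=0.5, **SMALL)
        ds = simulate_all(cfg)
        from lncscout.triplex import find_triplexes

        truth = ds.truth.triplex.iloc[0]
        tract = ds.genome[truth["scaffold"]][truth["tts_start"]: truth["tts_end"]]
        lnc_seq = ds.sequences()[truth["lncrna_id"]]
        full = [
            m for m in find_triplexes(lnc_seq, tract)
            if m.length == len(tract) and m.errors == 0
        ]
        assert full == []

    def test_same_seed_same_plant_coordinates(self):
        cfg = SimulationConfig(seed=9, **SMALL)
        t1 = simulate_all(cfg).truth.triplex
        t2 = simulate_all(cfg).truth.triplex
        assert t1.equals(t2)

    def test_unknown_lncrna_raises(self, dataset):
        with pytest.raises(ConfigError, match="unknown lncRNA"):
            plant_triplex(dataset.genome, dataset.all_transcripts, "nope",
                          dataset.config)

    def test_tfo_written_into_transcript(self, dataset):
        truth = dataset.truth.triplex.iloc[0]
        seqs = dataset.sequences()
        lnc_seq = seqs[truth["lncrna_id"]]
        tfo = lnc_seq[truth["tfo_start"]: truth["tfo_end"]]
        tract = dataset.genome[truth["scaffold"]][
            truth["tts_start"]: truth["tts_end"]
        ]
        # parallel pyrimidine motif: tract A->T(U), G->C, same order
        assert tfo == "".join("T" if b == "A" else "C" for b in tract)


class TestTruthBookkeeping:
    def test_every_entity_has_one_truth_record(self, dataset):
        ids = [t.transcript_id for t in dataset.all_transcripts]
        recorded = dataset.truth.transcripts["transcript_id"]
        assert sorted(ids) == sorted(recorded)
        assert not recorded.duplicated().any()
        assert sorted(dataset.truth.de["transcript_id"]) == sorted(ids)

    def test_counts_cover_all_transcripts(self, dataset):
        assert sorted(dataset.counts.index) == sorted(
            t.transcript_id for t in dataset.all_transcripts
        )
        assert (dataset.lengths > 0).all()
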