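"""Seeded generators for every input the pipeline consumes, with ground truth.

The generator emulates the downstream products of a 32-library,
two-condition brain RNA-seq design: a reference annotation with multi-exon, ORF-bearing mRNAs and
spliced (>= 2 exon) lncRNAs; planted single-exon novel transcripts of class
codes i/y/p/u plus exon-overlapping decoys; negative-binomial counts for
2 conditions x 4 biological replicates x 4 technical runs (32 libraries)
with planted fold-changes; lncRNA:mRNA pairs coupled through a Gaussian
copula; and a GA-rich triplex target tract written into the first intron of
an mRNA with the complementary pyrimidine-motif TFO written into a lncRNA.

Everything is deterministic given ``SimulationConfig.seed``: each stage
draws from its own stream forked off one SeedSequence, so stages can be
re-run independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import GenomicInterval, SequenceRecord, TranscriptModel, reverse_complement

CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    # genome layout; the gene panel is large enough that no single induced
    # gene dominates library totals (TPM self-normalization stays benign)
    n_scaffolds: int = 4
    scaffold_length: int = 650_000
    gene_slot: int = 12_000  # genomic footprint reserved per reference gene
    n_ref_mrna: int = 130
    n_ref_lncrna: int = 70
    # novel plants per class code, and exon-overlapping decoys
    n_novel_i: int = 4
    n_novel_y: int = 2
    n_novel_p: int = 3
    n_novel_u: int = 4
    n_decoy_coding_overlap: int = 3
    novel_length_range: tuple[int, int] = (250, 600)
    # composition gap between coding and noncoding sequence
    hexamer_bias_strength: float = 0.8  # Dirichlet-ish concentration of codon usage
    noncoding_base_probs: tuple[float, ...] = (0.30, 0.20, 0.20, 0.30)  # ACGT
    # expression design: 2 groups x biological replicates x technical runs
    n_bio_replicates: int = 4
    n_technical_runs: int = 4
    mean_range: tuple[float, float] = (20.0, 500.0)
    # planted co-regulated pairs emulate highly expressed focal genes;
    # low means would drown the rank correlation in count ties
    pair_mean_range: tuple[float, float] = (150.0, 500.0)
    dispersion_range: tuple[float, float] = (0.05, 0.3)
    library_size_sd: float = 0.1  # log-normal sd of per-library scale factors
    # planted differential expression (mated vs virgin log2 fold-changes)
    planted_log2fc_mrna: tuple[float, ...] = (2.0, 2.0, -2.0, -2.0, 3.0, -1.5)
    planted_log2fc_lncrna: tuple[float, ...] = (2.5, -2.0, 2.0, 3.0)
    # planted correlated DEL:DEG pairs: (lnc slot, mrna slot, copula rho, group)
    planted_pairs: tuple[tuple[int, int, float, str], ...] = (
        (0, 2, -0.95, "mated"),
        (2, 0, 0.95, "mated"),
        (3, 1, 0.95, "virgin"),
    )
    # triplex plant
    triplex_tract_length: int = 30
    triplex_ga_purity: float = 1.0
    triplex_g_fraction: float = 0.5  # G share among purine positions

    def __post_init__(self) -> None:
        for name in (
            "n_scaffolds", "scaffold_length", "n_ref_mrna", "n_ref_lncrna",
            "n_novel_i", "n_novel_y", "n_novel_p", "n_novel_u",
            "n_decoy_coding_overlap", "n_bio_replicates", "n_technical_runs",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dispersion_range[0] <= 0:
            raise ValueError("dispersion must be positive")
        if self.mean_range[0] <= 0:
            raise ValueError("NB means must be positive")
        for pair in self.planted_pairs:
            if abs(pair[2]) > 1:
                raise ValueError("|target rho| must be <= 1")
        if not (0.0 <= self.triplex_ga_purity <= 1.0):
            raise ValueError("triplex_ga_purity must lie in [0, 1]")


class ConfigError(ValueError):
    pass


@dataclass
class TruthTable:
    """Ground-truth labels for every generated entity."""

    transcripts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["transcript_id", "gene_id", "biotype", "true_class_code", "cohort"]
        )
    )
    de: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["transcript_id", "log2fc", "is_de", "biotype"]
        )
    )
    pairs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["lncrna_id", "mrna_id", "copula_rho", "group"]
        )
    )
    triplex: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=[
                "lncrna_id", "mrna_id", "scaffold", "tts_start", "tts_end",
                "tfo_start", "tfo_end", "intron_index",
            ]
        )
    )


def _streams(config: SimulationConfig) -> dict[str, np.random.Generator]:
    names = ["genome", "novel", "counts", "triplex"]
    seqs = np.random.SeedSequence(config.seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, seqs)}


# ---------------------------------------------------------------------------
# Sequence generators


def noncoding_sequence(rng: np.random.Generator, length: int,
                       probs: tuple[float, ...]) -> str:
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def _codon_weights(rng: np.random.Generator, strength: float) -> np.ndarray:
    """A skewed codon-usage distribution; `strength` in [0,1] interpolates
    between uniform (0) and a sparse, strongly biased usage (1)."""
    raw = rng.dirichlet(np.full(len(CODONS), 0.3))
    uniform = np.full(len(CODONS), 1.0 / len(CODONS))
    w = strength * raw + (1.0 - strength) * uniform
    return w / w.sum()


def coding_sequence(
    rng: np.random.Generator,
    n_codons: int,
    codon_weights: np.ndarray,
    utr5: int = 30,
    utr3: int = 30,
    noncoding_probs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25),
) -> str:
    """UTR + ATG + biased codons + stop + UTR; ORF length 3*(n_codons+2) nt."""
    body = "".join(rng.choice(CODONS, size=n_codons, p=codon_weights))
    stop = rng.choice(["TAA", "TAG", "TGA"])
    orf = "ATG" + body + stop
    return (
        noncoding_sequence(rng, utr5, noncoding_probs)
        + orf
        + noncoding_sequence(rng, utr3, noncoding_probs)
    )


# ---------------------------------------------------------------------------
# Genome + reference annotation


def _split_into_exons(
    rng: np.random.Generator, scaffold: str, strand: str, start: int,
    spliced_len: int, n_exons: int, intron_range: tuple[int, int],
) -> list[GenomicInterval]:
    cuts = np.sort(rng.choice(np.arange(1, spliced_len), size=n_exons - 1,
                              replace=False)) if n_exons > 1 else np.array([], dtype=int)
    sizes = np.diff(np.concatenate(([0], cuts, [spliced_len])))
    sizes = np.maximum(sizes, 20)  # no micro-exons
    exons = []
    pos = start
    for i, size in enumerate(sizes):
        exons.append(GenomicInterval(scaffold, pos, pos + int(size), strand))
        pos += int(size)
        if i < len(sizes) - 1:
            pos += int(rng.integers(*intron_range))
    return exons


def _write_spliced(genome: dict[str, bytearray], tx_exons: list[GenomicInterval],
                   strand: str, spliced_seq: str) -> None:
    """Write a designed spliced sequence into the exon positions so that
    strand-aware extraction returns it."""
    genomic = spliced_seq if strand != "-" else reverse_complement(spliced_seq)
    pos = 0
    for exon in tx_exons:
        chunk = genomic[pos : pos + exon.length]
        genome[exon.scaffold][exon.start : exon.end] = chunk.encode()
        pos += exon.length


def simulate_genome_and_annotation(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], list[TranscriptModel], TruthTable]:
    """Scaffold sequences plus the reference annotation (mRNAs + lncRNAs).

    mRNAs are multi-exon with a codon-biased ORF of >= 100 codons planted in
    the spliced sequence; reference lncRNAs have >= 2 exons and noncoding
    composition (the background composition of the scaffolds).
    """
    rng = rng if rng is not None else _streams(config)["genome"]
    scaffold_ids = [f"scaffold_{i+1:02d}" for i in range(config.n_scaffolds)]
    genome: dict[str, bytearray] = {
        s: bytearray(
            noncoding_sequence(rng, config.scaffold_length,
                               config.noncoding_base_probs).encode()
        )
        for s in scaffold_ids
    }
    codon_weights = _codon_weights(rng, config.hexamer_bias_strength)

    n_genes = config.n_ref_mrna + config.n_ref_lncrna
    slots_per_scaffold = (config.scaffold_length - 4_000) // config.gene_slot
    if n_genes > slots_per_scaffold * config.n_scaffolds:
        raise ConfigError(
            f"scaffolds too short: {n_genes} reference genes need "
            f"{n_genes * config.gene_slot + 4_000} bp total"
        )

    kinds = ["mRNA"] * config.n_ref_mrna + ["lncRNA"] * config.n_ref_lncrna
    rng.shuffle(kinds)
    transcripts: list[TranscriptModel] = []
    truth_rows = []
    im, il = 0, 0
    for gi, kind in enumerate(kinds):
        scaffold = scaffold_ids[gi % config.n_scaffolds]
        slot = gi // config.n_scaffolds
        slot_start = 2_000 + slot * config.gene_slot
        start = slot_start + int(rng.integers(0, 500))
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == "mRNA":
            im += 1
            tid, gid = f"mrna_{im:03d}", f"gene_m{im:03d}"
            n_codons = int(rng.integers(100, 220))
            seq = coding_sequence(rng, n_codons, codon_weights)
            n_exons = int(rng.integers(3, 6))
            exons = _split_into_exons(
                rng, scaffold, strand, start, len(seq), n_exons,
                intron_range=(400, 1200),
            )
        else:
            il += 1
            tid, gid = f"lnc_{il:03d}", f"gene_l{il:03d}"
            length = int(rng.integers(300, 900))
            seq = noncoding_sequence(rng, length, config.noncoding_base_probs)
            n_exons = int(rng.integers(2, 4))
            exons = _split_into_exons(
                rng, scaffold, strand, start, length, n_exons,
                intron_range=(150, 500),
            )
        if exons[-1].end > slot_start + config.gene_slot:
            raise ConfigError(
                f"gene {tid} exceeds its slot; increase gene_slot or scaffold_length"
            )
        spliced_len = sum(e.length for e in exons)
        seq = seq[:spliced_len].ljust(spliced_len, "A")
        tx = TranscriptModel(tid, gid, exons, biotype=kind)
        _write_spliced(genome, tx.exons, strand, seq)
        transcripts.append(tx)
        truth_rows.append(
            {
                "transcript_id": tid,
                "gene_id": gid,
                "biotype": kind,
                "true_class_code": "=",
                "cohort": "reference",
            }
        )

    truth = TruthTable()
    truth.transcripts = pd.DataFrame(truth_rows, columns=truth.transcripts.columns)
    genome_str = {s: bytes(b).decode() for s, b in genome.items()}
    return genome_str, transcripts, truth


# ---------------------------------------------------------------------------
# Novel transcript plants


def _room_after(tx: TranscriptModel, refs: list[TranscriptModel],
                scaffold_len: int) -> int:
    """Intergenic room between a transcript's end and the next reference."""
    nxt = [r.interval.start for r in refs
           if r.scaffold == tx.scaffold and r.interval.start >= tx.interval.end]
    bound = min(nxt) if nxt else scaffold_len
    return bound - tx.interval.end


def simulate_novel_transcripts(
    annotation: list[TranscriptModel],
    genome: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Plant novel transcript cohorts for class codes i, y, p, u plus
    exon-overlapping decoys.

    i/p/u plants and decoys are single-exon (the shape newly assembled
    lncRNAs typically take); class-y plants need two exons so their intron can enclose
    a full reference transcript. Returns (novels, truth rows).
    """
    if not annotation:
        raise ConfigError("annotation is empty")
    rng = rng if rng is not None else _streams(config)["novel"]
    scaffold_len = {s: len(seq) for s, seq in genome.items()}
    novels: list[TranscriptModel] = []
    rows = []

    def _record(tx: TranscriptModel, code: str, cohort: str) -> None:
        novels.append(tx)
        rows.append(
            {
                "transcript_id": tx.transcript_id,
                "gene_id": tx.gene_id,
                "biotype": "novel",
                "true_class_code": code,
                "cohort": cohort,
            }
        )

    lo, hi = config.novel_length_range

    # class i: single exon strictly inside a reference intron
    host_introns = [
        (tx, iv)
        for tx in annotation
        for iv in tx.introns()
        if iv.length >= lo + 40
    ]
    rng.shuffle(host_introns)
    if config.n_novel_i > len(host_introns):
        raise ConfigError(
            f"not enough long introns for {config.n_novel_i} class-i plants"
        )
    for k in range(config.n_novel_i):
        host, intron = host_introns[k]
        length = int(min(hi, intron.length - 40))
        length = int(rng.integers(lo, length + 1)) if length > lo else lo
        start = intron.start + int(rng.integers(10, intron.length - length - 10))
        strand = "+" if rng.random() < 0.5 else "-"
        tid = f"nov_i_{k+1:02d}"
        _record(
            TranscriptModel(
                tid, f"gene_{tid}",
                [GenomicInterval(intron.scaffold, start, start + length, strand)],
            ),
            "i", "novel_i",
        )

    # class y: two exons whose intron encloses a full reference transcript
    hosts = sorted(annotation, key=lambda t: t.interval.length)
    y_hosts = [t for t in hosts if _room_after(t, annotation,
                                               scaffold_len[t.scaffold]) >= 600]
    if config.n_novel_y > len(y_hosts):
        raise ConfigError("not enough clear-flanked references for class-y plants")
    for k in range(config.n_novel_y):
        host = y_hosts[k]
        span = host.interval
        exlen = 150
        left = GenomicInterval(span.scaffold, span.start - 300 - exlen,
                               span.start - 300, "+")
        right = GenomicInterval(span.scaffold, span.end + 300,
                                span.end + 300 + exlen, "+")
        tid = f"nov_y_{k+1:02d}"
        _record(TranscriptModel(tid, f"gene_{tid}", [left, right]), "y", "novel_y")

    # class p: run-on fragment within the downstream window of a '+' reference
    p_hosts = [
        t for t in annotation
        if t.strand == "+"
        and _room_after(t, annotation, scaffold_len[t.scaffold]) >= hi + 1400
    ]
    used_y = {t.transcript_id for t in y_hosts[: config.n_novel_y]}
    p_hosts = [t for t in p_hosts if t.transcript_id not in used_y]
    if config.n_novel_p > len(p_hosts):
        raise ConfigError("not enough downstream room for class-p plants")
    for k in range(config.n_novel_p):
        host = p_hosts[k]
        length = int(rng.integers(lo, hi))
        gap = int(rng.integers(50, 1200))
        start = host.interval.end + gap
        tid = f"nov_p_{k+1:02d}"
        _record(
            TranscriptModel(
                tid, f"gene_{tid}",
                [GenomicInterval(host.scaffold, start, start + length, "+")],
            ),
            "p", "novel_p",
        )

    # class u: intergenic, > 2000 bp from every reference
    gaps = []
    for scaf, slen in scaffold_len.items():
        spans = sorted(
            (t.interval.start, t.interval.end)
            for t in annotation + novels
            if t.scaffold == scaf
        )
        prev = 0
        for s, e in spans + [(slen, slen)]:
            if s - prev >= 2 * 2000 + hi + 200:
                gaps.append((scaf, prev, s))
            prev = max(prev, e)
    if config.n_novel_u > len(gaps):
        raise ConfigError("not enough deep-intergenic gaps for class-u plants")
    rng.shuffle(gaps)
    for k in range(config.n_novel_u):
        scaf, gs, ge = gaps[k]
        length = int(rng.integers(lo, hi))
        start = gs + 2000 + int(rng.integers(100, ge - gs - 4000 - length - 100))
        strand = "+" if rng.random() < 0.5 else "-"
        tid = f"nov_u_{k+1:02d}"
        _record(
            TranscriptModel(
                tid, f"gene_{tid}",
                [GenomicInterval(scaf, start, start + length, strand)],
            ),
            "u", "novel_u",
        )

    # decoys: single exon overlapping a reference exon -> class o, never kept
    wide_exons = [
        (t, e) for t in annotation for e in t.exons if e.length >= 120
    ]
    rng.shuffle(wide_exons)
    if config.n_decoy_coding_overlap > len(wide_exons):
        raise ConfigError("not enough reference exons for decoy plants")
    for k in range(config.n_decoy_coding_overlap):
        host, exon = wide_exons[k]
        length = int(rng.integers(max(lo, 200), hi))
        start = exon.start + exon.length // 2
        tid = f"decoy_{k+1:02d}"
        _record(
            TranscriptModel(
                tid, f"gene_{tid}",
                [GenomicInterval(exon.scaffold, start, start + length, host.strand)],
            ),
            "o", "decoy",
        )

    return novels, pd.DataFrame(
        rows,
        columns=["transcript_id", "gene_id", "biotype", "true_class_code", "cohort"],
    )


# ---------------------------------------------------------------------------
# Count simulation


def make_design(config: SimulationConfig) -> pd.DataFrame:
    """Sample sheet: 2 groups x biological replicates x technical runs."""
    rows = []
    for group in ("virgin", "mated"):
        for b in range(1, config.n_bio_replicates + 1):
            for t in range(1, config.n_technical_runs + 1):
                rows.append(
                    {
                        "sample_id": f"{group}_b{b}_t{t}",
                        "group": group,
                        "biological_replicate": f"b{b}",
                        "technical_run": f"t{t}",
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_counts(
    design: pd.DataFrame,
    truth: TruthTable,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB counts for every transcript in ``truth.de`` under the design.

    Counts follow NB(mean_g x 2^log2fc for mated samples, dispersion_g):
    a Gamma latent per (gene, biological replicate) shared by its technical
    runs, scaled by a per-library size factor, then Poisson. Genes in
    ``truth.pairs`` are instead drawn through a Gaussian copula on the NB
    marginals within the target group (independently elsewhere), which
    plants high-|rho| Spearman structure.

    Returns (counts, gene_params) where gene_params records the true mean
    and dispersion per gene.
    """
    if set(design["group"]) != {"virgin", "mated"}:
        raise ConfigError("design must contain exactly the virgin and mated groups")
    rng = rng if rng is not None else _streams(config)["counts"]
    genes = truth.de["transcript_id"].tolist()
    lfc = truth.de.set_index("transcript_id")["log2fc"].astype(float)

    lo, hi = config.mean_range
    means = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(genes)))
    dlo, dhi = config.dispersion_range
    disps = rng.uniform(dlo, dhi, size=len(genes))
    paired_ids = set(truth.pairs["lncrna_id"]) | set(truth.pairs["mrna_id"])
    plo, phi = config.pair_mean_range
    for gi, gene in enumerate(genes):
        if gene in paired_ids:
            means[gi] = np.exp(rng.uniform(np.log(plo), np.log(phi)))
    gene_params = pd.DataFrame(
        {"mean": means, "dispersion": disps}, index=pd.Index(genes, name="transcript_id")
    )

    lib = np.exp(rng.normal(0.0, config.library_size_sd, size=len(design)))
    lib_s = pd.Series(lib, index=design.index)

    group_arr = design["group"].to_numpy()
    biorep_arr = (design["group"] + "." + design["biological_replicate"]).to_numpy()
    bioreps = pd.unique(biorep_arr)

    paired = set(truth.pairs["lncrna_id"]) | set(truth.pairs["mrna_id"])
    counts = np.zeros((len(genes), len(design)), dtype=np.int64)
    for gi, gene in enumerate(genes):
        mu0 = means[gi]
        alpha = disps[gi]
        fc = 2.0 ** float(lfc.get(gene, 0.0))
        mu_sample = np.where(group_arr == "mated", mu0 * fc, mu0) * lib
        if gene in paired:
            # marginal NB per sample; the copula overwrite happens below
            n_param = 1.0 / alpha
            p_param = n_param / (n_param + mu_sample)
            counts[gi] = rng.negative_binomial(n_param, p_param)
        else:
            lam = np.empty(len(design))
            for br in bioreps:
                mask = biorep_arr == br
                mu_grp = mu_sample[mask][0] / lib[mask][0]
                lam[mask] = rng.gamma(1.0 / alpha, mu_grp * alpha)
            counts[gi] = rng.poisson(lam * lib)

    counts_df = pd.DataFrame(counts, index=gene_params.index, columns=design.index)

    # Gaussian copula for planted correlated pairs (within the target group)
    for _, pr in truth.pairs.iterrows():
        gpair = [pr["lncrna_id"], pr["mrna_id"]]
        # copula_rho is the target Spearman; a Gaussian copula with
        # correlation r gives Spearman (6/pi)*asin(r/2), so invert that
        rho_s = float(pr["copula_rho"])
        r = 2.0 * np.sin(np.pi * rho_s / 6.0)
        mask = group_arr == pr["group"]
        n = int(mask.sum())
        cov = np.array([[1.0, r], [r, 1.0]])
        z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        u = stats.norm.cdf(z)
        for k, gene in enumerate(gpair):
            mu0 = gene_params.loc[gene, "mean"]
            alpha = gene_params.loc[gene, "dispersion"]
            fc = 2.0 ** float(lfc.get(gene, 0.0))
            mu = np.where(pr["group"] == "mated", mu0 * fc, mu0) * lib[mask]
            n_param = 1.0 / alpha
            p_param = n_param / (n_param + mu)
            vals = stats.nbinom.ppf(u[:, k], n_param, p_param)
            col_idx = np.where(mask)[0]
            counts_df.iloc[gi_lookup(counts_df, gene), col_idx] = vals.astype(np.int64)
    return counts_df, gene_params


def gi_lookup(df: pd.DataFrame, gene: str) -> int:
    return int(df.index.get_loc(gene))


# ---------------------------------------------------------------------------
# Triplex plant


def _purine_tract(rng: np.random.Generator, length: int, g_fraction: float) -> str:
    return "".join(
        "G" if rng.random() < g_fraction else "A" for _ in range(length)
    )


def _degrade(rng: np.random.Generator, tract: str, purity: float) -> str:
    out = []
    for b in tract:
        if rng.random() < purity:
            out.append(b)
        else:
            out.append("C" if rng.random() < 0.5 else "T")
    return "".join(out)


def _transcript_position(tx: TranscriptModel, genomic_start: int, length: int) -> int:
    """Transcript coordinate of a genomic sub-interval lying inside one exon."""
    order = tx.exons if tx.strand != "-" else list(reversed(tx.exons))
    offset = 0
    for exon in order:
        if exon.start <= genomic_start and genomic_start + length <= exon.end:
            if tx.strand != "-":
                return offset + (genomic_start - exon.start)
            return offset + (exon.end - (genomic_start + length))
        offset += exon.length
    raise ValueError("interval not contained in a single exon")


def plant_triplex(
    genome: dict[str, str],
    annotation: list[TranscriptModel],
    lncrna_id: str,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    target_mrna_id: str | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Write a GA-rich tract into the first intron of an mRNA and the
    complementary pyrimidine-motif TFO into the chosen lncRNA.

    The tract (purine strand, '+' genome orientation) pairs the TFO under
    the parallel pyrimidine motif (U.A / C.G); ``triplex_ga_purity`` < 1
    degrades tract positions to pyrimidines, creating triplex errors.
    Returns the updated genome and the truth rows.
    """
    rng = rng if rng is not None else _streams(config)["triplex"]
    tlen = config.triplex_tract_length
    by_id = {t.transcript_id: t for t in annotation}
    if lncrna_id not in by_id:
        raise ConfigError(f"unknown lncRNA {lncrna_id!r}")

    candidates = [t for t in annotation if t.biotype == "mRNA" and t.n_exons >= 2]
    if target_mrna_id is not None:
        candidates = [t for t in candidates if t.transcript_id == target_mrna_id]
    host = None
    first_intron = None
    for tx in candidates:
        introns = tx.introns() if tx.strand != "-" else list(reversed(tx.introns()))
        if introns and introns[0].length >= tlen + 40:
            host, first_intron = tx, introns[0]
            break
    if host is None:
        raise ConfigError("no mRNA has a first intron long enough for the tract")

    tract = _purine_tract(rng, tlen, config.triplex_g_fraction)
    planted = _degrade(rng, tract, config.triplex_ga_purity)
    tts_start = first_intron.start + int(
        rng.integers(10, first_intron.length - tlen - 10)
    )
    scaf = bytearray(genome[first_intron.scaffold].encode())
    scaf[tts_start : tts_start + tlen] = planted.encode()

    # pyrimidine-motif TFO, parallel: A -> U(T), G -> C, aligned 5'->3'
    tfo_dna = "".join("T" if b == "A" else "C" for b in tract)
    lnc = by_id[lncrna_id]
    exon = max(lnc.exons, key=lambda e: e.length)
    if exon.length < tlen + 20:
        raise ConfigError(f"lncRNA {lncrna_id} has no exon long enough for the TFO")
    g_start = exon.start + int(rng.integers(10, exon.length - tlen - 10))
    write_seq = tfo_dna if lnc.strand != "-" else reverse_complement(tfo_dna)
    if lnc.scaffold == first_intron.scaffold:
        scaf[g_start : g_start + tlen] = write_seq.encode()
        genome = dict(genome)
        genome[first_intron.scaffold] = bytes(scaf).decode()
    else:
        genome = dict(genome)
        genome[first_intron.scaffold] = bytes(scaf).decode()
        other = bytearray(genome[lnc.scaffold].encode())
        other[g_start : g_start + tlen] = write_seq.encode()
        genome[lnc.scaffold] = bytes(other).decode()
    tfo_start = _transcript_position(lnc, g_start, tlen)

    row = pd.DataFrame(
        [
            {
                "lncrna_id": lncrna_id,
                "mrna_id": host.transcript_id,
                "scaffold": first_intron.scaffold,
                "tts_start": tts_start,
                "tts_end": tts_start + tlen,
                "tfo_start": tfo_start,
                "tfo_end": tfo_start + tlen,
                "intron_index": 1,
            }
        ]
    )
    return genome, row


# ---------------------------------------------------------------------------
# End-to-end dataset


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: dict[str, str]
    reference: list[TranscriptModel]
    novels: list[TranscriptModel]
    counts: pd.DataFrame
    samples: pd.DataFrame
    lengths: pd.Series
    gene_params: pd.DataFrame
    truth: TruthTable

    @property
    def all_transcripts(self) -> list[TranscriptModel]:
        return self.reference + self.novels

    def sequences(self) -> dict[str, str]:
        from .models import extract_spliced_sequence

        return {
            t.transcript_id: extract_spliced_sequence(t, self.genome)
            for t in self.all_transcripts
        }


def simulate_all(config: SimulationConfig) -> SyntheticDataset:
    """Generate the complete synthetic study: genome, annotation, novel
    plants, triplex plant, and the 32-library count matrix with truth."""
    streams = _streams(config)
    genome, reference, truth = simulate_genome_and_annotation(
        config, rng=streams["genome"]
    )
    novels, novel_rows = simulate_novel_transcripts(
        reference, genome, config, rng=streams["novel"]
    )
    truth.transcripts = pd.concat(
        [truth.transcripts, novel_rows], ignore_index=True
    )

    everything = reference + novels

    # assign planted fold-changes: mRNA slots to the first reference mRNAs,
    # lncRNA slots to planted-u novels first, then reference lncRNAs
    mrnas = [t.transcript_id for t in reference if t.biotype == "mRNA"]
    lnc_pool = [t.transcript_id for t in novels if t.transcript_id.startswith("nov_u")]
    lnc_pool += [t.transcript_id for t in reference if t.biotype == "lncRNA"]
    de_rows = []
    slot_mrna: dict[int, str] = {}
    slot_lnc: dict[int, str] = {}
    for i, fc in enumerate(config.planted_log2fc_mrna):
        if i < len(mrnas):
            slot_mrna[i] = mrnas[i]
    for i, fc in enumerate(config.planted_log2fc_lncrna):
        if i < len(lnc_pool):
            slot_lnc[i] = lnc_pool[i]
    planted_fc = {tid: config.planted_log2fc_mrna[i] for i, tid in slot_mrna.items()}
    planted_fc.update(
        {tid: config.planted_log2fc_lncrna[i] for i, tid in slot_lnc.items()}
    )
    for t in everything:
        fc = planted_fc.get(t.transcript_id, 0.0)
        de_rows.append(
            {
                "transcript_id": t.transcript_id,
                "log2fc": fc,
                "is_de": fc != 0.0,
                "biotype": t.biotype,
            }
        )
    truth.de = pd.DataFrame(de_rows, columns=truth.de.columns)

    pair_rows = []
    for lnc_slot, mrna_slot, rho, group in config.planted_pairs:
        if lnc_slot in slot_lnc and mrna_slot in slot_mrna:
            pair_rows.append(
                {
                    "lncrna_id": slot_lnc[lnc_slot],
                    "mrna_id": slot_mrna[mrna_slot],
                    "copula_rho": rho,
                    "group": group,
                }
            )
    truth.pairs = pd.DataFrame(pair_rows, columns=truth.pairs.columns)

    # triplex plant: carrier = first lncRNA DE slot with a long-enough exon
    tlen = config.triplex_tract_length
    carrier = None
    for i in sorted(slot_lnc):
        tx = next(t for t in everything if t.transcript_id == slot_lnc[i])
        if max(e.length for e in tx.exons) >= tlen + 20:
            carrier = tx.transcript_id
            break
    if carrier is not None:
        # plant the tract in the carrier's copula-paired mRNA when that mRNA
        # has a long-enough first intron, so the correlation network points
        # the triplex scan at the right locus
        target = None
        partners = truth.pairs.loc[
            truth.pairs["lncrna_id"] == carrier, "mrna_id"
        ].tolist()
        by_id = {t.transcript_id: t for t in everything}
        for mid in partners:
            tx = by_id[mid]
            introns = (
                tx.introns() if tx.strand != "-" else list(reversed(tx.introns()))
            )
            if introns and introns[0].length >= tlen + 40:
                target = mid
                break
        genome, triplex_rows = plant_triplex(
            genome, everything, carrier, config,
            rng=streams["triplex"], target_mrna_id=target,
        )
        truth.triplex = triplex_rows

    design = make_design(config)
    counts, gene_params = simulate_counts(
        design, truth, config, rng=streams["counts"]
    )
    lengths = pd.Series(
        {t.transcript_id: t.spliced_length for t in everything}, name="length"
    ).reindex(counts.index)
    return SyntheticDataset(
        config=config,
        genome=genome,
        reference=reference,
        novels=novels,
        counts=counts,
        samples=design,
        lengths=lengths,
        gene_params=gene_params,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Emit genome.fasta, reference.gtf, novel.gtf, transcripts.fasta,
    counts.tsv, samples.tsv, lengths.tsv and the truth tables."""
    from pathlib import Path

    from . import io as io_mod

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io_mod.write_fasta(
        [SequenceRecord(s, seq) for s, seq in ds.genome.items()],
        out / "genome.fasta",
    )
    io_mod.write_gtf(ds.reference, out / "reference.gtf")
    io_mod.write_gtf(ds.novels, out / "novel.gtf")
    seqs = ds.sequences()
    io_mod.write_fasta(
        [SequenceRecord(t, s) for t, s in seqs.items()], out / "transcripts.fasta"
    )
    io_mod.write_counts_tsv(ds.counts, out / "counts.tsv")
    ds.samples.to_csv(out / "samples.tsv", sep="\t")
    ds.lengths.rename("length").to_csv(out / "lengths.tsv", sep="\t",
                                       index_label="transcript_id")
    ds.truth.transcripts.to_csv(out / "truth_transcripts.tsv", sep="\t", index=False)
    ds.truth.de.to_csv(out / "truth_de.tsv", sep="\t", index=False)
    ds.truth.pairs.to_csv(out / "truth_pairs.tsv", sep="\t", index=False)
    ds.truth.triplex.to_csv(out / "truth_triplex.tsv", sep="\t", index=False)
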