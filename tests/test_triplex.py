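"""Hoogsteen triplex search: motif rules, constraint boundaries, maximality,
oracle equivalence, coordinate lifting and TTS clustering."""

import numpy as np
import pytest

from lncscout.io import read_bed, write_bed
from lncscout.models import GenomicInterval, TranscriptModel, reverse_complement
from lncscout.triplex import (
    annotate_feature,
    cluster_tts,
    find_triplexes,
    hoogsteen_match,
    match_base_pairs,
    scan_lncrna_vs_locus,
)
from oracles import triplex_oracle


def _keys(matches):
    return {
        (m.tfo_start, m.tfo_end, m.tts.start, m.tts.end, m.tts.strand,
         m.motif, m.orientation)
        for m in matches
    }


class TestHoogsteenRules:
    @pytest.mark.parametrize(
        "tfo,dna,motif,expected",
        [
            ("U", "A", "pyrimidine", True),
            ("C", "G", "pyrimidine", True),
            ("C", "A", "pyrimidine", False),
            ("G", "G", "purine", True),
            ("A", "A", "purine", True),
            ("U", "A", "purine", False),
            ("U", "A", "mixed", True),
            ("G", "G", "mixed", True),
            ("C", "G", "mixed", False),
            ("N", "A", "pyrimidine", False),
            ("U", "N", "mixed", False),
        ],
    )
    def test_triplet_table(self, tfo, dna, motif, expected):
        assert hoogsteen_match(tfo, dna, motif) is expected

    def test_t_treated_as_u(self):
        assert hoogsteen_match("T", "A", "pyrimidine")

    def test_unknown_motif_raises(self):
        with pytest.raises(ValueError):
            hoogsteen_match("U", "A", "hoogsteen")


class TestFindTriplexes:
    def test_perfect_ga_repeat_single_match(self):
        dna = "GAGAGAGAGAGAGAGA"  # 16 nt purine tract on '+'
        rna = "CUCUCUCUCUCUCUCU"
        matches = [
            m for m in find_triplexes(rna, dna) if m.motif == "pyrimidine"
        ]
        assert len(matches) == 1
        (m,) = matches
        assert (m.length, m.errors) == (16, 0)
        assert m.tts_guanine_fraction == pytest.approx(0.5)
        assert m.tts_ga_fraction == 1.0
        assert (m.tts.start, m.tts.end, m.tts.strand) == (0, 16, "+")

    def test_below_min_length_no_match(self):
        dna = "GAGAGAGAGAGAGA"  # 14 nt
        rna = "CUCUCUCUCUCUCU"
        assert find_triplexes(rna, dna) == []

    def test_centered_error_run_splits_matches(self):
        # 36-nt perfect context with a 4-error run in the middle: no single
        # match contains the whole run; the maximal flank matches extend
        # exactly 3 errors into it (the consecutive-error limit)
        dna = "GA" * 8 + "TTTT" + "GA" * 8
        rna = "CU" * 8 + "AGGA" + "CU" * 8
        matches = [
            m for m in find_triplexes(rna, dna)
            if m.motif == "pyrimidine" and m.tfo_start == m.tts.start
        ]
        spans = {(m.tts.start, m.tts.end) for m in matches}
        assert spans == {(0, 19), (17, 36)}
        assert all(
            not (m.tts.start <= 16 and m.tts.end >= 20) for m in matches
        )
        assert all(m.errors == 3 for m in matches)

    def test_guanine_content_boundary(self):
        # all-A tract: guanine fraction 0 < 0.2, rejected
        assert find_triplexes("U" * 15, "A" * 15) == []
        # exactly 3 G in 15 = 0.2: inclusive bound, accepted
        dna = "GAAAA" * 3
        rna = "".join("C" if b == "G" else "U" for b in dna)
        matches = [m for m in find_triplexes(rna, dna) if m.motif == "pyrimidine"]
        assert len(matches) == 1
        assert matches[0].tts_guanine_fraction == pytest.approx(0.2)

    def test_error_rate_strictly_below_20_percent(self):
        # 15-mer with 2 errors (13.3%) passes; 3 errors (20%) fails
        dna = "G" * 15
        rna2 = "C" * 6 + "A" + "C" * 5 + "A" + "C" * 2  # errors at 6 and 12
        rna3 = "C" * 3 + "A" + "C" * 3 + "A" + "C" * 3 + "A" + "C" * 3
        m2 = [m for m in find_triplexes(rna2, dna)
              if m.motif == "pyrimidine" and m.length == 15]
        m3 = [m for m in find_triplexes(rna3, dna)
              if m.motif == "pyrimidine" and m.length == 15]
        assert any(m.errors == 2 for m in m2)
        assert all(m.errors < 3 for m in m3)

    def test_max_three_consecutive_errors(self):
        # 21-mer: a 3-error run inside an otherwise perfect G tract passes,
        # a 4-error run cannot be spanned
        dna = "G" * 21
        rna_ok = "C" * 9 + "AAA" + "C" * 9
        rna_bad = "C" * 9 + "AAAA" + "C" * 8
        ok = [m for m in find_triplexes(rna_ok, dna)
              if m.motif == "pyrimidine" and m.length == 21]
        bad = [m for m in find_triplexes(rna_bad, dna)
               if m.motif == "pyrimidine" and m.length == 21]
        assert len(ok) == 1 and ok[0].errors == 3
        assert bad == []

    def test_purine_motif_antiparallel_orientation(self):
        dna = "G" * 16
        rna = "G" * 16
        matches = [m for m in find_triplexes(rna, dna) if m.motif == "purine"]
        assert matches
        assert all(m.orientation == "antiparallel" for m in matches)

    def test_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(10)
        for trial in range(20):
            if trial % 2 == 0:
                dna = "".join(rng.choice(list("GAGACT"),
                                         p=[.3, .3, .1, .1, .1, .1], size=100))
                rna = "".join(rng.choice(list("CUCUAG"),
                                         p=[.3, .3, .1, .1, .1, .1], size=70))
            else:
                dna = "".join(rng.choice(list("ACGT"), size=100))
                rna = "".join(rng.choice(list("ACGU"), size=70))
            assert _keys(find_triplexes(rna, dna)) == triplex_oracle(rna, dna)

    def test_reverse_complement_consistency(self):
        rng = np.random.default_rng(11)
        dna = "".join(rng.choice(list("GAGACT"), p=[.3, .3, .1, .1, .1, .1],
                                 size=80))
        rna = "".join(rng.choice(list("CUCUAG"), p=[.3, .3, .1, .1, .1, .1],
                                 size=60))
        fwd = _keys(find_triplexes(rna, dna))
        rev = _keys(find_triplexes(rna, reverse_complement(dna)))
        n = len(dna)
        flipped = {
            (t0, t1, n - e, n - s, {"+": "-", "-": "+"}[strand], motif, ori)
            for (t0, t1, s, e, strand, motif, ori) in rev
        }
        assert fwd == flipped

    def test_error_positions_reverify_under_hoogsteen_rules(self):
        # corrupt a perfect complement so matches carry scattered errors on
        # both strands/orientations
        rng = np.random.default_rng(12)
        dna = "".join(rng.choice(list("GACT"), p=[.4, .4, .1, .1], size=150))
        comp = {"G": "C", "A": "U", "C": "A", "T": "G"}
        rna = "".join(comp[b] for b in dna[20:120])
        rna = "".join(
            b if rng.random() > 0.08 else "G" for b in rna
        )
        matches = find_triplexes(rna, dna)
        assert matches, "fixture should produce at least one match"
        for m in matches:
            pairs = match_base_pairs(m, rna, dna)
            for k, (tfo_base, pur_base) in enumerate(pairs):
                is_error = k in m.error_positions
                assert hoogsteen_match(tfo_base, pur_base, m.motif) != is_error


class TestLocusScan:
    def test_planted_tract_found_in_first_intron(self, dataset):
        truth = dataset.truth.triplex.iloc[0]
        seqs = dataset.sequences()
        tx = next(
            t for t in dataset.all_transcripts
            if t.transcript_id == truth["mrna_id"]
        )
        span = tx.interval
        locus = GenomicInterval(span.scaffold, max(0, span.start - 500),
                                span.end + 500, ".")
        matches = scan_lncrna_vs_locus(
            seqs[truth["lncrna_id"]], locus, dataset.genome, [tx]
        )
        covering = [
            m for m in matches
            if m.tts.start < truth["tts_end"] and m.tts.end > truth["tts_start"]
        ]
        assert covering
        assert any(m.feature == "intron_1" for m in covering)

    def test_locus_outside_scaffold_raises(self, dataset):
        bad = GenomicInterval("scaffold_01", 0, 10**9, ".")
        with pytest.raises(ValueError, match="outside"):
            scan_lncrna_vs_locus("ACGU" * 10, bad, dataset.genome, [])

    def test_lifted_coordinates_roundtrip_through_bed(self, dataset, tmp_path):
        truth = dataset.truth.triplex.iloc[0]
        seqs = dataset.sequences()
        tx = next(
            t for t in dataset.all_transcripts
            if t.transcript_id == truth["mrna_id"]
        )
        locus = GenomicInterval(tx.scaffold, tx.interval.start - 200,
                                tx.interval.end + 200, ".")
        matches = scan_lncrna_vs_locus(
            seqs[truth["lncrna_id"]], locus, dataset.genome, [tx]
        )
        p = tmp_path / "tts.bed"
        write_bed([m.tts for m in matches], p)
        back = read_bed(p)
        assert [(b.scaffold, b.start, b.end) for b in back] == [
            (m.tts.scaffold, m.tts.start, m.tts.end) for m in matches
        ]

    def test_intron_numbering_respects_strand(self):
        tx_minus = TranscriptModel(
            "t", "g",
            [GenomicInterval("s", 100, 200, "-"),
             GenomicInterval("s", 300, 400, "-"),
             GenomicInterval("s", 500, 600, "-")],
        )
        # genomic interval (400,500) is the first intron in transcript
        # orientation for a '-' transcript
        assert annotate_feature(GenomicInterval("s", 420, 460, "."), [tx_minus]) \
            == "intron_1"
        assert annotate_feature(GenomicInterval("s", 220, 260, "."), [tx_minus]) \
            == "intron_2"
        assert annotate_feature(GenomicInterval("s", 110, 130, "."), [tx_minus]) \
            == "exon_3"
        assert annotate_feature(GenomicInterval("s", 10, 30, "."), [tx_minus]) \
            == "flank"


def _match_at(scaf, start, end):
    from lncscout.triplex import TriplexMatch

    return TriplexMatch(
        tfo_start=0, tfo_end=end - start,
        tts=GenomicInterval(scaf, start, end, "+"),
        motif="pyrimidine", orientation="parallel",
        errors=0, error_positions=(),
        tts_guanine_fraction=0.5, tts_ga_fraction=1.0,
    )


class TestClusterTts:
    def test_overlap_merging(self):
        matches = [
            _match_at("s", 100, 120),
            _match_at("s", 110, 130),
            _match_at("s", 400, 420),
        ]
        clusters = cluster_tts(matches, gap=0)
        spans = [(c.interval.start, c.interval.end, c.n_members) for c in clusters]
        assert spans == [(100, 130, 2), (400, 420, 1)]

    def test_single_match_single_cluster(self):
        (c,) = cluster_tts([_match_at("s", 5, 25)])
        assert c.n_members == 1 and not c.high_frequency

    def test_pure_ga_tract_fraction_one(self):
        genome = {"s": "T" * 100 + "GAGAGAGAGAGAGAGAGAGA" + "T" * 100}
        (c,) = cluster_tts([_match_at("s", 100, 120)], genome=genome)
        assert c.ga_fraction == 1.0

    def test_gap_parameter_bridges_nearby_sites(self):
        matches = [_match_at("s", 0, 20), _match_at("s", 25, 45)]
        assert len(cluster_tts(matches, gap=0)) == 2
        assert len(cluster_tts(matches, gap=5)) == 1

    def test_high_frequency_flag(self):
        matches = [_match_at("s", 100 + i, 120 + i) for i in range(12)]
        (c,) = cluster_tts(matches, high_frequency_k=10)
        assert c.high_frequency and c.n_members == 12

    def test_empty_input(self):
        assert cluster_tts([]) == []
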