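import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protoselect.genome_qc import GenomeRecord
from protoselect.strain_tracking import (
    Detection,
    PrevalenceTable,
    axp_rank,
    build_kmer_db,
    canonical_kmers,
    detect_strains,
    mean_ani_per_strain,
    prevalence,
)
from protoselect.synthetic_data import SimulationConfig, simulate_genomes, simulate_metagenome
from _oracles import canonical_kmers_naive


def _decode(code: int, k: int) -> str:
    return "".join("ACGT"[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


class TestKmerDatabase:
    def test_small_contig_matches_hand_enumeration(self):
        seq = "ACGTACGTA"
        got = {_decode(c, 5) for c in canonical_kmers(seq, 5)}
        assert got == canonical_kmers_naive(seq, 5)
        assert len(got) <= 5

    @given(st.text(alphabet="ACGTN", min_size=7, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_canonicalization_matches_string_oracle(self, seq):
        got = {_decode(c, 7) for c in canonical_kmers(seq, 7)}
        assert got == canonical_kmers_naive(seq, 7)

    def test_identical_genomes_identical_sets(self):
        g1 = GenomeRecord("a", ["ACGTACGTAC" * 10], coverage=50.0)
        g2 = GenomeRecord("b", ["ACGTACGTAC" * 10], coverage=50.0)
        db = build_kmer_db([g1, g2], k=7)
        assert np.array_equal(db.strain_kmers["a"], db.strain_kmers["b"])

    def test_all_n_genome_is_an_error(self):
        g = GenomeRecord("n", ["N" * 100], coverage=50.0)
        with pytest.raises(ValueError, match="no valid k-mers"):
            build_kmer_db([g], k=7)

    def test_even_k_rejected(self):
        g = GenomeRecord("a", ["ACGT" * 30], coverage=50.0)
        with pytest.raises(ValueError, match="odd"):
            build_kmer_db([g], k=8)


@pytest.fixture(scope="module")
def strain_panel():
    rates = {f"S{i + 1}": 0.003 * i for i in range(6)}
    cfg = SimulationConfig(
        seed=21, genome_length=20_000, n_strains=6, substitution_rates=rates
    )
    genomes, _ = simulate_genomes(cfg)
    return cfg, genomes


class TestDetection:
    def test_single_strain_sample_detects_only_that_strain(self, strain_panel):
        cfg, genomes = strain_panel
        cfg_mix = SimulationConfig(
            seed=22, genome_length=cfg.genome_length, n_strains=6,
            substitution_rates=cfg.substitution_rates,
            strain_mixtures={"s": {"S3": 1.0}},
            reads_per_sample=700,  # ~5x coverage of 20 kb at 150 bp
        )
        samples, _ = simulate_metagenome(cfg_mix, genomes)
        db = build_kmer_db(genomes)
        dets = detect_strains(db, samples["s"])
        assert [d.strain_id for d in dets] == ["S3"]

    def test_empty_sample_yields_no_detections(self, strain_panel):
        _, genomes = strain_panel
        db = build_kmer_db(genomes)
        assert detect_strains(db, []) == []

    def test_mixture_recovered_within_two_iterations(self, strain_panel):
        cfg, genomes = strain_panel
        cfg_mix = SimulationConfig(
            seed=23, genome_length=cfg.genome_length, n_strains=6,
            substitution_rates=cfg.substitution_rates,
            strain_mixtures={"s": {"S1": 0.5, "S6": 0.5}},
            reads_per_sample=20_000,
        )
        samples, _ = simulate_metagenome(cfg_mix, genomes)
        db = build_kmer_db(genomes)
        dets = detect_strains(db, samples["s"])
        assert {d.strain_id for d in dets} == {"S1", "S6"}
        assert max(d.iteration for d in dets) <= 2

    def test_adding_reads_of_a_strain_never_lowers_its_first_round_score(self, strain_panel):
        cfg, genomes = strain_panel
        db = build_kmer_db(genomes)
        target = genomes[3]
        reads = [target.sequence[i : i + 150] for i in range(0, 3_000, 150)]
        extra = [target.sequence[i : i + 150] for i in range(3_000, 6_000, 150)]

        def first_score(read_set):
            pool = read_set or None
            dets = detect_strains(db, read_set, min_score=0.0, max_iterations=1)
            return next(d.score for d in dets if d.strain_id == target.genome_id)

        assert first_score(reads + extra) >= first_score(reads)

    def test_detection_is_deterministic(self, strain_panel):
        cfg, genomes = strain_panel
        db = build_kmer_db(genomes)
        reads = [genomes[0].sequence[i : i + 150] for i in range(0, 6_000, 150)]
        a = detect_strains(db, reads)
        b = detect_strains(db, reads)
        assert a == b


class TestPrevalence:
    def test_detected_in_half_the_samples(self):
        dets = [Detection("s1", "A", 0.9, 1), Detection("s3", "A", 0.8, 1)]
        table = prevalence(dets, n_samples=4)
        assert table.prevalence["A"] == 0.5

    def test_never_detected_strain_is_zero(self):
        table = prevalence([], n_samples=4, strain_ids=["A"])
        assert table.prevalence["A"] == 0.0

    def test_double_detection_in_one_sample_counts_once(self):
        dets = [Detection("s1", "A", 0.9, 1), Detection("s1", "A", 0.5, 2)]
        table = prevalence(dets, n_samples=2)
        assert table.prevalence["A"] == 0.5

    def test_unknown_sample_rejected(self):
        dets = [Detection("ghost", "A", 0.9, 1)]
        with pytest.raises(ValueError, match="unknown sample"):
            prevalence(dets, n_samples=2, sample_ids=["s1", "s2"])


class TestAxP:
    def test_formula_examples(self):
        table = PrevalenceTable({"A": 0.5, "B": 0.0, "C": 1.0}, n_samples=4)
        scores = {
            s.strain_id: s for s in axp_rank({"A": 0.98, "B": 0.99, "C": 1.0}, table)
        }
        assert scores["A"].axp == pytest.approx(49.0)
        assert scores["B"].axp == 0.0
        assert scores["C"].axp == 100.0

    def test_missing_strain_rejected(self):
        table = PrevalenceTable({"A": 0.5}, n_samples=2)
        with pytest.raises(ValueError, match="missing"):
            axp_rank({}, table)

    @given(
        st.dictionaries(
            st.sampled_from([f"S{i}" for i in range(8)]),
            st.tuples(
                st.floats(min_value=0, max_value=1),
                st.floats(min_value=0, max_value=1),
            ),
            min_size=1,
        )
    )
    @settings(max_examples=300, deadline=None)
    def test_axp_contract_and_bounds(self, data):
        mean_ani = {s: v[0] for s, v in data.items()}
        table = PrevalenceTable({s: v[1] for s, v in data.items()}, n_samples=10)
        scores = axp_rank(mean_ani, table)
        for s in scores:
            assert s.axp == s.mean_ani * s.prevalence * 100
            assert 0.0 <= s.axp <= 100.0
        assert [s.axp for s in scores] == sorted((s.axp for s in scores), reverse=True)

    def test_ranking_invariant_under_prevalence_scaling(self):
        mean_ani = {"A": 0.99, "B": 0.97, "C": 0.95}
        prev = {"A": 0.2, "B": 0.8, "C": 0.5}
        r1 = [s.strain_id for s in axp_rank(mean_ani, PrevalenceTable(prev, 10))]
        scaled = {k: v / 2 for k, v in prev.items()}
        r2 = [s.strain_id for s in axp_rank(mean_ani, PrevalenceTable(scaled, 10))]
        assert r1 == r2

    def test_mean_ani_excludes_self(self):
        matrix = {("A", "B"): 0.9, ("A", "C"): 0.7, ("B", "C"): 0.8}
        out = mean_ani_per_strain(matrix)
        assert out["A"] == pytest.approx(0.8)
        assert out["B"] == pytest.approx(0.85)
        assert out["C"] == pytest.approx(0.75)
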