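import math

import numpy as np
import pytest

from protoselect.synthetic_data import (
    SimulationConfig,
    expected_identity,
    simulate_counts,
    simulate_genome_clusters,
    simulate_genomes,
    simulate_metagenome,
    simulate_proteomes,
    write_fastq,
)


def test_zero_rates_reproduce_the_ancestor():
    cfg = SimulationConfig(
        seed=1, genome_length=6_000, n_strains=3,
        substitution_rates={"A": 0.0, "B": 0.0, "C": 0.0},
    )
    genomes, truth = simulate_genomes(cfg)
    for g in genomes:
        assert g.sequence == truth.ancestor
    assert all(v == 1.0 for v in truth.expected_identity.values())


def test_expected_identity_closed_form():
    assert expected_identity(0.0, 0.01) == pytest.approx(0.99)
    # both lineages mutated: 1/3 chance of converging on the same base
    assert expected_identity(0.5, 0.5) == pytest.approx(0.25 + 0.25 / 3)


def test_same_seed_gives_byte_identical_fasta(tmp_path):
    from protoselect.genome_qc import write_genome_fasta

    cfg = SimulationConfig(seed=7, genome_length=8_000, n_strains=5)
    outputs = []
    for run in range(2):
        genomes, _ = simulate_genomes(cfg)
        path = tmp_path / f"run{run}.fasta"
        with open(path, "w") as fh:
            pass
        for g in genomes:
            write_genome_fasta(g, tmp_path / f"{run}_{g.genome_id}.fasta")
        outputs.append(
            b"".join(
                (tmp_path / f"{run}_{g.genome_id}.fasta").read_bytes() for g in genomes
            )
        )
    assert outputs[0] == outputs[1]


def test_empirical_substitution_rate_within_3_sigma():
    rate = 0.02
    L = 50_000
    cfg = SimulationConfig(
        seed=3, genome_length=L, n_strains=2, substitution_rates={"A": rate, "B": 0.0}
    )
    genomes, truth = simulate_genomes(cfg)
    n_mut = truth.mutations["A"].size
    sigma = math.sqrt(L * rate * (1 - rate))
    assert abs(n_mut - L * rate) < 3 * sigma
    # recorded positions really differ from the ancestor
    anc = truth.ancestor
    seq = genomes[0].sequence
    assert all(seq[p] != anc[p] for p in truth.mutations["A"][:100])


def test_rate_above_limit_rejected():
    cfg = SimulationConfig(
        seed=1, genome_length=6_000, n_strains=2, substitution_rates={"A": 0.5, "B": 0.0}
    )
    with pytest.raises(ValueError, match="0.3"):
        simulate_genomes(cfg)


def test_cluster_generator_records_labels():
    genomes, truth = simulate_genome_clusters(
        SimulationConfig(seed=5, genome_length=6_000), n_clusters=2, strains_per_cluster=3
    )
    assert len(genomes) == 6
    assert set(truth.cluster_of.values()) == {"C1", "C2"}


class TestMetagenome:
    def test_pure_sample_reads_are_exact_substrings(self):
        cfg = SimulationConfig(
            seed=2, genome_length=6_000, n_strains=2,
            substitution_rates={"A": 0.0, "B": 0.01},
            strain_mixtures={"s1": {"A": 1.0}}, reads_per_sample=200,
        )
        genomes, _ = simulate_genomes(cfg)
        samples, truth = simulate_metagenome(cfg, genomes)
        genome_a = next(g for g in genomes if g.genome_id == "A").sequence
        for read_id, seq in samples["s1"]:
            assert seq in genome_a
            assert truth.read_provenance[read_id] == "A"

    def test_zero_reads_gives_empty_valid_fastq(self, tmp_path):
        cfg = SimulationConfig(
            seed=2, genome_length=6_000, n_strains=2, reads_per_sample=0,
            strain_mixtures={"s1": {"S1": 1.0}},
        )
        genomes, _ = simulate_genomes(cfg)
        samples, _ = simulate_metagenome(cfg, genomes)
        assert samples["s1"] == []
        write_fastq(samples["s1"], tmp_path / "empty.fastq")
        assert (tmp_path / "empty.fastq").read_text() == ""

    def test_mixture_proportions_within_binomial_error(self):
        n_reads = 10_000
        cfg = SimulationConfig(
            seed=9, genome_length=6_000, n_strains=2,
            substitution_rates={"A": 0.0, "B": 0.01},
            strain_mixtures={"s1": {"A": 0.5, "B": 0.5}}, reads_per_sample=n_reads,
        )
        genomes, _ = simulate_genomes(cfg)
        _, truth = simulate_metagenome(cfg, genomes)
        n_a = sum(1 for s in truth.read_provenance.values() if s == "A")
        sigma = math.sqrt(n_reads * 0.25)
        assert abs(n_a - n_reads / 2) < 3 * sigma

    def test_bad_abundance_sum_rejected(self):
        cfg = SimulationConfig(seed=2, genome_length=6_000, n_strains=2)
        genomes, _ = simulate_genomes(cfg)
        cfg2 = SimulationConfig(seed=2, genome_length=6_000, n_strains=2)
        cfg2.strain_mixtures = {"s1": {"S1": 0.6, "S2": 0.6}}
        with pytest.raises(ValueError, match="sum"):
            simulate_metagenome(cfg2, genomes)


class TestProteomes:
    def test_planted_unique_families(self):
        cfg = SimulationConfig(
            seed=4, n_strains=3, n_core_families=6, n_accessory_families=2,
            planted_unique={"S1": 5},
        )
        proteomes, truth = simulate_proteomes(cfg)
        assert len(truth.unique_families["S1"]) == 5
        for fam in truth.unique_families["S1"]:
            members = truth.families[fam]
            assert len(members) == 1 and members[0][0] == "S1"

    def test_zero_divergence_core_members_identical(self):
        cfg = SimulationConfig(
            seed=4, n_strains=3, n_core_families=4, n_accessory_families=0,
            protein_divergence=0.0,
        )
        proteomes, truth = simulate_proteomes(cfg)
        for fam, members in truth.families.items():
            seqs = {
                dict(proteomes[strain])[gene] for strain, gene in members
            }
            assert len(seqs) == 1

    def test_family_and_protein_counts_by_construction(self):
        cfg = SimulationConfig(
            seed=4, n_strains=2, n_core_families=9, n_accessory_families=0,
            planted_unique={"S1": 1, "S2": 1},
        )
        proteomes, truth = simulate_proteomes(cfg)
        assert sum(len(p) for p in proteomes.values()) == 20
        assert len(truth.families) == 11

    def test_every_gene_belongs_to_exactly_one_family(self):
        cfg = SimulationConfig(
            seed=8, n_strains=4, n_core_families=5, n_accessory_families=5,
            planted_unique={"S2": 2},
        )
        proteomes, truth = simulate_proteomes(cfg)
        from_families = sorted(m for mem in truth.families.values() for m in mem)
        from_proteomes = sorted(
            (strain, gene) for strain, prots in proteomes.items() for gene, _ in prots
        )
        assert from_families == from_proteomes


class TestCounts:
    def test_no_planted_genes_means_all_null(self):
        cfg = SimulationConfig(seed=6, n_genes_expr=50)
        _, truth = simulate_counts(cfg)
        assert truth.de_genes == {}

    def test_poisson_limit_variance_tracks_mean(self):
        cfg = SimulationConfig(
            seed=6, n_genes_expr=1_000, nb_dispersion=0.0, n_samples_per_group=10,
            mean_log_sd=0.0,
        )
        m, _ = simulate_counts(cfg)
        means = m.counts.mean(axis=1)
        variances = m.counts.var(axis=1, ddof=1)
        # pooled over 1,000 genes the variance/mean ratio concentrates at 1
        assert np.mean(variances / means) == pytest.approx(1.0, abs=0.05)

    def test_planted_fold_change_shows_in_group_means(self):
        planted = {f"g{i + 1:05d}": 2.0 for i in range(50)}
        cfg = SimulationConfig(
            seed=6, n_genes_expr=200, planted_log2fc=planted, mean_log_sd=0.0,
            baseline_mean=100.0, n_samples_per_group=5,
        )
        m, _ = simulate_counts(cfg)
        ctrl = m.counts[:, m.group_mask("control")].mean(axis=1)
        trt = m.counts[:, m.group_mask("treated")].mean(axis=1)
        ratios = trt[:50] / ctrl[:50]
        in_interval = ((ratios >= 3.0) & (ratios <= 5.3)).mean()
        assert in_interval >= 0.9

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, nb_dispersion=-0.1)
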