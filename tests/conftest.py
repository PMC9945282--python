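import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from protoselect.genome_qc import GenomeRecord, write_genome_fasta
from protoselect.pipeline import RunConfig
from protoselect.synthetic_data import (
    SimulationConfig,
    simulate_genomes,
    simulate_metagenome,
    simulate_proteomes,
    write_fastq,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def planted_pair():
    """Two 20 kb genomes at substitution rate 0.01 (expected identity 0.99)."""
    cfg = SimulationConfig(
        seed=11,
        genome_length=20_000,
        n_strains=2,
        substitution_rates={"A": 0.0, "B": 0.01},
    )
    genomes, truth = simulate_genomes(cfg)
    return genomes, truth


@pytest.fixture
def toy_genome():
    return GenomeRecord("toy", ["ACGT" * 2500], coverage=50.0)


def mutate_dna(seq: str, rate: float, seed: int) -> str:
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for h in np.flatnonzero(rng.random(arr.size) < rate):
        choices = bases[bases != arr[h]]
        arr[h] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def diverge_proteome(prots, rate, seed):
    rng = np.random.default_rng(seed)
    out = []
    for gid, seq in prots:
        chars = list(seq)
        for i in np.flatnonzero(rng.random(len(chars)) < rate):
            chars[i] = _AA[rng.integers(0, 20)]
        out.append((gid, "".join(chars)))
    return out


def build_selection_inputs(root: Path) -> Path:
    """Write a full synthetic selection-pipeline input tree under ``root``.

    S1 is the planted prototype: zero divergence from the ancestor (highest
    centrality) and present in every metagenome sample; the biobank holds a
    near (0.5 % diverged) and a far (3 %) relative of S1.
    """
    rates = {"S1": 0.0, "S2": 0.004, "S3": 0.008, "S4": 0.012, "S5": 0.016}
    cfg = SimulationConfig(
        seed=61, genome_length=15_000, n_strains=5, substitution_rates=rates,
        strain_mixtures={
            "m1": {"S1": 0.5, "S2": 0.5},
            "m2": {"S1": 0.5, "S4": 0.5},
            "m3": {"S1": 0.6, "S5": 0.4},
        },
        reads_per_sample=4_000,
    )
    genomes, _ = simulate_genomes(cfg)
    (root / "genomes").mkdir()
    meta = []
    for g in genomes:
        write_genome_fasta(g, root / "genomes" / f"{g.genome_id}.fasta")
        meta.append((g.genome_id, g.coverage, "public"))
    pd.DataFrame(meta, columns=["genome_id", "coverage", "source"]).to_csv(
        root / "metadata.tsv", sep="\t", index=False
    )
    samples, _ = simulate_metagenome(cfg, genomes)
    (root / "samples").mkdir()
    for sid, reads in samples.items():
        write_fastq(reads, root / "samples" / f"{sid}.fastq")

    pcfg = SimulationConfig(seed=61, n_core_families=8, n_accessory_families=0)
    proteomes, _ = simulate_proteomes(pcfg, strain_ids=sorted(rates))
    (root / "proteomes").mkdir()
    for strain, prots in proteomes.items():
        with open(root / "proteomes" / f"{strain}.faa", "w") as fh:
            for gid, seq in prots:
                fh.write(f">{gid}\n{seq}\n")

    s1 = next(g for g in genomes if g.genome_id == "S1")
    (root / "biobank").mkdir()
    for name, rate, pseed in (("B_near", 0.005, 1), ("B_far", 0.03, 2)):
        g = GenomeRecord(name, [mutate_dna(s1.sequence, rate, pseed)], coverage=80.0)
        write_genome_fasta(g, root / "biobank" / f"{name}.fasta")
        diverged = diverge_proteome(proteomes["S1"], rate * 2, pseed)
        with open(root / "biobank" / f"{name}.faa", "w") as fh:
            for gid, seq in diverged:
                fh.write(f">{gid}\n{seq}\n")
    return root


def selection_config(root: Path, outdir: Path) -> RunConfig:
    return RunConfig(
        outdir=outdir,
        genomes=sorted((root / "genomes").glob("*.fasta")),
        metadata=root / "metadata.tsv",
        samples=sorted((root / "samples").glob("*.fastq")),
        proteomes={p.stem: p for p in (root / "proteomes").glob("*.faa")},
        biobank_genomes=sorted((root / "biobank").glob("*.fasta")),
        biobank_proteomes={p.stem: p for p in (root / "biobank").glob("*.faa")},
        seed=61,
    )


@pytest.fixture(scope="session")
def selection_inputs(tmp_path_factory):
    return build_selection_inputs(tmp_path_factory.mktemp("inputs"))
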