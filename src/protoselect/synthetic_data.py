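"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the statistical structure the downstream analyses
assume, so that each stage can be verified against planted truth without any
external download:

* a species' genome set as independent substitution (and optional single-base
  indel) processes applied to one common ancestor, so the expected pairwise
  nucleotide identity is closed-form;
* shotgun-metagenome samples as uniform read draws from known strain genomes
  at known relative abundances;
* strain proteomes with planted core / accessory / strain-unique gene
  families;
* RNA-seq count matrices as negative-binomial draws with planted log2 fold
  changes between two groups.

All randomness flows from a single master seed; each generator derives its
own stream with a fixed spawn key, so stages are individually reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from protoselect.genome_qc import GenomeRecord
from protoselect.dge import CountMatrix

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "simulate_genomes",
    "simulate_genome_clusters",
    "simulate_metagenome",
    "simulate_proteomes",
    "simulate_counts",
    "write_fastq",
    "expected_identity",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA = "ACDEFGHIKLMNPQRSTVWY"

# fixed spawn keys: one independent RNG stream per generator
_STREAM_GENOMES = 1
_STREAM_METAGENOME = 2
_STREAM_PROTEOMES = 3
_STREAM_COUNTS = 4
_STREAM_CLUSTERS = 5


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


@dataclass
class SimulationConfig:
    """Knobs for every generator; unused blocks may keep their defaults.

    Rates are fractions in [0, 1]; strain mixtures must each sum to 1.
    """

    seed: int = 0
    # genomes
    genome_length: int = 50_000
    n_strains: int = 5
    substitution_rates: dict[str, float] | None = None  # strain -> rate vs ancestor
    indel_rate: float = 0.0
    n_contigs: int = 1
    coverage: dict[str, float] | float = 100.0
    source: str = "public"
    # metagenome
    n_samples: int = 4
    strain_mixtures: dict[str, dict[str, float]] | None = None  # sample -> strain -> abundance
    reads_per_sample: int = 5_000
    read_length: int = 150
    read_error_rate: float = 0.0
    # proteomes
    n_core_families: int = 10
    n_accessory_families: int = 5
    planted_unique: dict[str, int] = field(default_factory=dict)  # strain -> count
    protein_length_range: tuple[int, int] = (80, 200)
    protein_divergence: float = 0.02
    # counts
    n_genes_expr: int = 2_000
    n_samples_per_group: int = 5
    nb_dispersion: float = 0.1
    planted_log2fc: dict[str, float] = field(default_factory=dict)  # gene -> log2fc
    baseline_mean: float = 100.0
    mean_log_sd: float = 1.0
    library_size_factors: Sequence[float] | None = None

    def __post_init__(self) -> None:
        for name in ("indel_rate", "read_error_rate", "protein_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        for name in (
            "genome_length",
            "n_strains",
            "n_contigs",
            "n_samples",
            "read_length",
            "n_core_families",
            "n_genes_expr",
            "n_samples_per_group",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.reads_per_sample < 0 or self.n_accessory_families < 0:
            raise ValueError("counts must be non-negative")
        if self.substitution_rates is not None:
            for s, r in self.substitution_rates.items():
                if not 0.0 <= r <= 1.0:
                    raise ValueError(f"substitution rate for {s} outside [0, 1]")
        if self.strain_mixtures is not None:
            for sample, mix in self.strain_mixtures.items():
                total = sum(mix.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"sample {sample!r}: abundances sum to {total}, expected 1"
                    )

    def resolved_rates(self) -> dict[str, float]:
        if self.substitution_rates is not None:
            return dict(self.substitution_rates)
        # default: evenly spread rates, strain S1 closest to the ancestor
        return {
            f"S{i + 1}": 0.002 * i for i in range(self.n_strains)
        }


@dataclass
class TruthSet:
    """Planted ground truth; each generator fills the fields it owns."""

    ancestor: str | None = None
    mutations: dict[str, np.ndarray] = field(default_factory=dict)
    expected_identity: dict[tuple[str, str], float] = field(default_factory=dict)
    cluster_of: dict[str, str] = field(default_factory=dict)
    sample_composition: dict[str, dict[str, float]] = field(default_factory=dict)
    read_provenance: dict[str, str] = field(default_factory=dict)  # read_id -> strain
    families: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    unique_families: dict[str, list[str]] = field(default_factory=dict)
    de_genes: dict[str, float] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "ancestor": self.ancestor,
            "mutations": {k: v.tolist() for k, v in self.mutations.items()},
            "expected_identity": {f"{a}|{b}": v for (a, b), v in self.expected_identity.items()},
            "cluster_of": self.cluster_of,
            "sample_composition": self.sample_composition,
            "read_provenance": self.read_provenance,
            "families": {k: [list(m) for m in v] for k, v in self.families.items()},
            "unique_families": self.unique_families,
            "de_genes": self.de_genes,
        }


def expected_identity(p_i: float, p_j: float) -> float:
    """Expected per-site identity of two genomes mutated independently from
    one ancestor at rates ``p_i`` and ``p_j`` (substitutions to a uniformly
    chosen different base).

    A site matches when neither lineage mutated, or both mutated and landed
    on the same base (probability 1/3 given both mutated).
    """
    return (1.0 - p_i) * (1.0 - p_j) + p_i * p_j / 3.0


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Substitute bases i.i.d. at ``rate``; returns (mutated copy, positions)."""
    out = seq.copy()
    if rate <= 0:
        return out, np.empty(0, dtype=np.int64)
    hits = np.flatnonzero(rng.random(seq.size) < rate)
    if hits.size:
        # map current base to one of the other three, uniformly
        offsets = rng.integers(1, 4, size=hits.size)
        base_idx = np.empty(hits.size, dtype=np.int64)
        for b, code in enumerate(_BASES):
            base_idx[out[hits] == code] = b
        out[hits] = _BASES[(base_idx + offsets) % 4]
    return out, hits


def _apply_indels(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return seq
    u = rng.random(seq.size)
    keep = u >= rate / 2.0  # deletion with prob rate/2
    insert_here = (u >= rate / 2.0) & (u < rate)  # insertion with prob rate/2
    pieces: list[np.ndarray] = []
    ins_pos = np.flatnonzero(insert_here)
    ins_bases = _BASES[rng.integers(0, 4, size=ins_pos.size)]
    kept = seq[keep]
    if ins_pos.size == 0:
        return kept
    # insert after each flagged (kept or not) position; rebuild by segments
    out = []
    prev = 0
    kept_mask_cum = np.cumsum(keep)
    for p, b in zip(ins_pos, ins_bases):
        k = kept_mask_cum[p]
        out.append(kept[prev:k])
        out.append(np.array([b], dtype=np.uint8))
        prev = k
    out.append(kept[prev:])
    return np.concatenate(out)


def _split_contigs(seq: np.ndarray, n_contigs: int) -> list[str]:
    bounds = np.linspace(0, seq.size, n_contigs + 1).astype(int)
    return [
        seq[bounds[i] : bounds[i + 1]].tobytes().decode("ascii")
        for i in range(n_contigs)
        if bounds[i + 1] > bounds[i]
    ]


def _coverage_for(config: SimulationConfig, strain: str) -> float:
    if isinstance(config.coverage, dict):
        return float(config.coverage.get(strain, 100.0))
    return float(config.coverage)


def simulate_genomes(config: SimulationConfig) -> tuple[list[GenomeRecord], TruthSet]:
    """Derive one genome per strain from a random common ancestor.

    Each strain accumulates i.i.d. substitutions at its configured rate
    (and, optionally, single-base indels).  The truth set records the
    ancestor, every substituted position, and the closed-form expected
    pairwise identity matrix.
    """
    if config.genome_length < 5_000:
        raise ValueError("genome_length must be at least 5,000 bp")
    if config.n_strains < 2:
        raise ValueError("need at least 2 strains")
    rates = config.resolved_rates()
    for s, r in rates.items():
        if r > 0.3:
            raise ValueError(
                f"substitution rate {r} for {s!r} exceeds 0.3; identity model breaks down"
            )
    rng = _rng(config.seed, _STREAM_GENOMES)
    ancestor = _BASES[rng.integers(0, 4, size=config.genome_length)]
    truth = TruthSet(ancestor=ancestor.tobytes().decode("ascii"))
    genomes: list[GenomeRecord] = []
    for strain in sorted(rates):
        mutated, positions = _mutate(ancestor, rates[strain], rng)
        mutated = _apply_indels(mutated, config.indel_rate, rng)
        truth.mutations[strain] = positions
        genomes.append(
            GenomeRecord(
                strain,
                _split_contigs(mutated, config.n_contigs),
                coverage=_coverage_for(config, strain),
                source=config.source,
            )
        )
    strains = sorted(rates)
    for i, a in enumerate(strains):
        for b in strains[i + 1 :]:
            e = expected_identity(rates[a], rates[b])
            truth.expected_identity[(a, b)] = e
            truth.expected_identity[(b, a)] = e
        truth.expected_identity[(a, a)] = 1.0
    return genomes, truth


def simulate_genome_clusters(
    config: SimulationConfig,
    n_clusters: int,
    strains_per_cluster: int,
    within_rate: float = 0.002,
    between_rate: float = 0.02,
) -> tuple[list[GenomeRecord], TruthSet]:
    """Two-level genome set with planted ANI cluster structure.

    Cluster ancestors diverge from the master ancestor at ``between_rate``;
    members diverge from their cluster ancestor at ``within_rate``.  Within a
    cluster the expected identity is ``(1-w)^2``-level (high); across
    clusters divergence accumulates along both branches, keeping clusters
    separable by an ANI threshold.  Truth records the cluster label per
    strain.
    """
    if max(within_rate, between_rate) > 0.3:
        raise ValueError("rates above 0.3 break the identity model")
    rng = _rng(config.seed, _STREAM_CLUSTERS)
    ancestor = _BASES[rng.integers(0, 4, size=config.genome_length)]
    truth = TruthSet(ancestor=ancestor.tobytes().decode("ascii"))
    genomes: list[GenomeRecord] = []
    for ci in range(n_clusters):
        cluster_anc, _ = _mutate(ancestor, between_rate, rng)
        for mi in range(strains_per_cluster):
            strain = f"C{ci + 1}M{mi + 1}"
            seq, positions = _mutate(cluster_anc, within_rate, rng)
            truth.mutations[strain] = positions
            truth.cluster_of[strain] = f"C{ci + 1}"
            genomes.append(
                GenomeRecord(
                    strain,
                    _split_contigs(seq, config.n_contigs),
                    coverage=_coverage_for(config, strain),
                    source=config.source,
                )
            )
    return genomes, truth


def _default_mixtures(config: SimulationConfig, strain_ids: list[str]) -> dict[str, dict[str, float]]:
    # each sample: the first two strains at 50/50 (deterministic default)
    mix = {strain_ids[0]: 0.5, strain_ids[1]: 0.5} if len(strain_ids) > 1 else {strain_ids[0]: 1.0}
    return {f"sample{i + 1}": dict(mix) for i in range(config.n_samples)}


def simulate_metagenome(
    config: SimulationConfig, genomes: Sequence[GenomeRecord]
) -> tuple[dict[str, list[tuple[str, str]]], TruthSet]:
    """Draw reads from known strains at known relative abundances.

    Returns ``{sample_id: [(read_id, sequence), ...]}`` plus a truth set
    mapping every read id to its source strain.  Reads are uniform substrings
    of a uniformly chosen contig (weighted by eligible start positions);
    sequencing error substitutes bases i.i.d. at ``read_error_rate``.
    """
    by_id = {g.genome_id: g for g in genomes}
    mixtures = config.strain_mixtures or _default_mixtures(config, sorted(by_id))
    for sample, mix in mixtures.items():
        total = sum(mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"sample {sample!r}: abundances sum to {total}, expected 1")
        unknown = set(mix) - set(by_id)
        if unknown:
            raise ValueError(f"sample {sample!r} references unknown strains {sorted(unknown)}")
    rng = _rng(config.seed, _STREAM_METAGENOME)
    truth = TruthSet()
    samples: dict[str, list[tuple[str, str]]] = {}
    L = config.read_length
    for sample in sorted(mixtures):
        mix = mixtures[sample]
        truth.sample_composition[sample] = dict(mix)
        strains = sorted(mix)
        probs = np.array([mix[s] for s in strains])
        origins = rng.choice(len(strains), size=config.reads_per_sample, p=probs)
        reads: list[tuple[str, str]] = []
        for ri, oi in enumerate(origins):
            strain = strains[oi]
            g = by_id[strain]
            eligible = [max(len(c) - L + 1, 0) for c in g.contigs]
            total_starts = sum(eligible)
            if total_starts == 0:
                raise ValueError(f"strain {strain!r}: every contig shorter than read length")
            flat = int(rng.integers(0, total_starts))
            for contig, n_start in zip(g.contigs, eligible):
                if flat < n_start:
                    seq = contig[flat : flat + L]
                    break
                flat -= n_start
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
            if config.read_error_rate > 0:
                arr, _ = _mutate(arr, config.read_error_rate, rng)
            read_id = f"{sample}_r{ri + 1}"
            reads.append((read_id, arr.tobytes().decode("ascii")))
            truth.read_provenance[read_id] = strain
        samples[sample] = reads
    return samples, truth


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write reads as FASTQ with constant quality 'I' per base."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(_AA[i] for i in rng.integers(0, len(_AA), size=length))


def _diverge_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for h in hits:
        choices = _AA.replace(chars[h], "")
        chars[h] = choices[int(rng.integers(0, len(choices)))]
    return "".join(chars)


def simulate_proteomes(
    config: SimulationConfig, strain_ids: Sequence[str] | None = None
) -> tuple[dict[str, list[tuple[str, str]]], TruthSet]:
    """Per-strain proteomes with planted core, accessory and unique families.

    Core families occur in every strain (members diverge from a family
    ancestor at ``protein_divergence``); accessory families occur in a random
    subset of at least two strains; planted unique families occur in exactly
    one strain.  Returns ``{strain: [(gene_id, sequence), ...]}`` and the
    family-membership truth.
    """
    if config.n_core_families < 1:
        raise ValueError("need at least one core family")
    if strain_ids is None:
        strain_ids = [f"S{i + 1}" for i in range(config.n_strains)]
    strain_ids = list(strain_ids)
    unknown = set(config.planted_unique) - set(strain_ids)
    if unknown:
        raise ValueError(f"planted_unique references unknown strains {sorted(unknown)}")
    rng = _rng(config.seed, _STREAM_PROTEOMES)
    lo, hi = config.protein_length_range
    truth = TruthSet()
    proteomes: dict[str, list[tuple[str, str]]] = {s: [] for s in strain_ids}

    def add_family(fam_id: str, members: Sequence[str]) -> None:
        anc = _random_protein(int(rng.integers(lo, hi + 1)), rng)
        truth.families[fam_id] = []
        for strain in members:
            gene_id = f"{strain}|{fam_id}"
            seq = _diverge_protein(anc, config.protein_divergence, rng)
            proteomes[strain].append((gene_id, seq))
            truth.families[fam_id].append((strain, gene_id))

    for i in range(config.n_core_families):
        add_family(f"core{i + 1:03d}", strain_ids)
    for i in range(config.n_accessory_families):
        if len(strain_ids) < 3:
            size = len(strain_ids)
        else:
            size = int(rng.integers(2, len(strain_ids)))  # 2 .. n-1 strains
        members = sorted(rng.choice(strain_ids, size=size, replace=False).tolist())
        add_family(f"acc{i + 1:03d}", members)
    for strain in sorted(config.planted_unique):
        truth.unique_families.setdefault(strain, [])
        for j in range(config.planted_unique[strain]):
            fam_id = f"uniq_{strain}_{j + 1:03d}"
            add_family(fam_id, [strain])
            truth.unique_families[strain].append(fam_id)
    return proteomes, truth


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, TruthSet]:
    """Two-group negative-binomial count matrix with planted fold changes.

    Gene-wise base means are log-normal around ``baseline_mean``; counts are
    NB with variance mu + dispersion * mu^2.  Genes named in
    ``planted_log2fc`` have their treated-group mean multiplied by
    ``2**log2fc``.  Dispersion 0 falls back to Poisson.
    """
    if config.n_samples_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    if config.nb_dispersion < 0:
        raise ValueError("negative dispersion")
    rng = _rng(config.seed, _STREAM_COUNTS)
    n = config.n_genes_expr
    gene_ids = [f"g{i + 1:05d}" for i in range(n)]
    unknown = set(config.planted_log2fc) - set(gene_ids)
    if unknown:
        raise ValueError(f"planted_log2fc references unknown genes {sorted(unknown)}")
    base = np.exp(
        rng.normal(math.log(config.baseline_mean), config.mean_log_sd, size=n)
    )
    lfc = np.zeros(n)
    for g, v in config.planted_log2fc.items():
        lfc[gene_ids.index(g)] = v
    k = config.n_samples_per_group
    sample_ids = [f"ctrl{i + 1}" for i in range(k)] + [f"trt{i + 1}" for i in range(k)]
    groups = {s: ("control" if s.startswith("ctrl") else "treated") for s in sample_ids}
    factors = np.asarray(
        config.library_size_factors if config.library_size_factors is not None else np.ones(2 * k)
    )
    if factors.size != 2 * k:
        raise ValueError("library_size_factors length must equal total sample count")
    mean_matrix = np.empty((n, 2 * k))
    mean_matrix[:, :k] = base[:, None]
    mean_matrix[:, k:] = (base * 2.0 ** lfc)[:, None]
    mean_matrix *= factors[None, :]
    phi = config.nb_dispersion
    if phi == 0:
        counts = rng.poisson(mean_matrix)
    else:
        r = 1.0 / phi
        p = r / (r + mean_matrix)
        counts = rng.negative_binomial(r, p)
    truth = TruthSet(de_genes=dict(config.planted_log2fc))
    matrix = CountMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        counts=counts.astype(np.int64),
        groups=groups,
    )
    return matrix, truth
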