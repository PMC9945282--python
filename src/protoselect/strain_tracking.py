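"""Strain detection in metagenomes, prevalence, and the AxP ranking index.

Detection follows the iterative winner-takes-all scheme of reference-based
strain typing: all canonical k-mers of a sample's reads are pooled, each
database strain is scored by the fraction of its own k-mers found in the
pool (a containment score), the best-scoring strain above the threshold is
emitted, its k-mers are removed from the pool, and the procedure repeats.

The AxP index ranks database strains for prototype selection by combining
phylogenomic centrality with ecological success:

    AxP = (mean ANI to all other database genomes) x (prevalence) x 100

with both terms as fractions in [0, 1], so AxP lies in [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from protoselect.genome_qc import GenomeRecord

__all__ = [
    "KmerDatabase",
    "Detection",
    "PrevalenceTable",
    "AxPScore",
    "canonical_kmers",
    "build_kmer_db",
    "detect_strains",
    "prevalence",
    "axp_rank",
    "mean_ani_per_strain",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def canonical_kmers(seq: str, k: int) -> np.ndarray:
    """Distinct canonical k-mers of ``seq`` as 2-bit-packed integers.

    The canonical form is the numerically smaller of a k-mer's forward and
    reverse-complement encodings; windows containing non-ACGT characters are
    skipped.
    """
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    valid = ~(win == 255).any(axis=1)
    if not valid.any():
        return np.empty(0, dtype=np.int64)
    win = win[valid].astype(np.int64)
    p_desc = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    p_asc = 4 ** np.arange(k, dtype=np.int64)
    fwd = win @ p_desc
    rc = (3 - win) @ p_asc
    return np.unique(np.minimum(fwd, rc))


@dataclass
class KmerDatabase:
    k: int
    strain_kmers: dict[str, np.ndarray]  # strain -> sorted distinct canonical k-mers

    @property
    def strain_ids(self) -> list[str]:
        return sorted(self.strain_kmers)


@dataclass(frozen=True)
class Detection:
    sample_id: str
    strain_id: str
    score: float
    iteration: int


@dataclass
class PrevalenceTable:
    prevalence: dict[str, float]  # strain -> fraction of samples detected in
    n_samples: int


@dataclass(frozen=True)
class AxPScore:
    strain_id: str
    mean_ani: float
    prevalence: float
    axp: float


def build_kmer_db(genomes: Sequence[GenomeRecord], k: int = 23) -> KmerDatabase:
    """Index the distinct canonical k-mers of every (dereplicated) genome."""
    if k % 2 == 0:
        raise ValueError("k must be odd (canonical form is otherwise ambiguous)")
    strain_kmers: dict[str, np.ndarray] = {}
    for g in genomes:
        if k > max(len(c) for c in g.contigs):
            raise ValueError(f"k={k} exceeds the longest contig of {g.genome_id!r}")
        kmers = [canonical_kmers(c, k) for c in g.contigs]
        merged = np.unique(np.concatenate(kmers)) if kmers else np.empty(0, dtype=np.int64)
        if merged.size == 0:
            raise ValueError(f"genome {g.genome_id!r} yields no valid k-mers")
        strain_kmers[g.genome_id] = merged
    return KmerDatabase(k=k, strain_kmers=strain_kmers)


def detect_strains(
    db: KmerDatabase,
    reads: Iterable[tuple[str, str] | str],
    sample_id: str = "sample",
    min_score: float = 0.1,
    max_iterations: int = 5,
) -> list[Detection]:
    """Iterative winner-takes-all strain detection in one sample.

    Scores are containment fractions of each strain's k-mer set in the
    pooled distinct read k-mers; after each emitted strain its k-mers are
    removed from the pool.  An empty sample yields an empty list.
    """
    chunks = []
    for r in reads:
        seq = r[1] if isinstance(r, tuple) else r
        if len(seq) < db.k:
            raise ValueError(f"read shorter than k={db.k}")
        chunks.append(canonical_kmers(seq, db.k))
    if not chunks:
        return []
    pool = np.unique(np.concatenate(chunks))
    detections: list[Detection] = []
    for iteration in range(1, max_iterations + 1):
        if pool.size == 0:
            break
        best: tuple[float, str] | None = None
        # strain_ids is sorted, so strict > keeps the lexicographically
        # smallest strain on ties
        for strain in db.strain_ids:
            kmers = db.strain_kmers[strain]
            score = float(np.isin(kmers, pool, assume_unique=True).mean())
            if best is None or score > best[0]:
                best = (score, strain)
        if best is None or best[0] < min_score:
            break
        score, strain = best
        detections.append(Detection(sample_id, strain, score, iteration))
        pool = pool[~np.isin(pool, db.strain_kmers[strain], assume_unique=True)]
    return detections


def prevalence(
    detections: Iterable[Detection],
    n_samples: int,
    strain_ids: Sequence[str] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> PrevalenceTable:
    """Fraction of samples in which each strain was detected at least once.

    ``strain_ids`` fixes the table universe (undetected strains get 0);
    ``sample_ids``, when given, validates that detections reference known
    samples.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    known_samples = set(sample_ids) if sample_ids is not None else None
    seen: dict[str, set[str]] = {}
    for d in detections:
        if known_samples is not None and d.sample_id not in known_samples:
            raise ValueError(f"detection references unknown sample {d.sample_id!r}")
        seen.setdefault(d.strain_id, set()).add(d.sample_id)
    universe = list(strain_ids) if strain_ids is not None else sorted(seen)
    table = {s: len(seen.get(s, ())) / n_samples for s in universe}
    return PrevalenceTable(prevalence=table, n_samples=n_samples)


def mean_ani_per_strain(ani_matrix: Mapping[tuple[str, str], float]) -> dict[str, float]:
    """Average ANI of each strain to every *other* strain in the matrix."""
    strains = sorted({s for pair in ani_matrix for s in pair})
    out = {}
    for s in strains:
        vals = [
            ani_matrix[(min(s, t), max(s, t))]
            if (min(s, t), max(s, t)) in ani_matrix
            else ani_matrix[(s, t)]
            for t in strains
            if t != s
        ]
        if not vals:
            raise ValueError(f"strain {s!r} has no ANI entries")
        out[s] = float(np.mean(vals))
    return out


def axp_rank(
    mean_ani: Mapping[str, float], prevalence_table: PrevalenceTable
) -> list[AxPScore]:
    """AxP = mean_ani x prevalence x 100, sorted descending (ties by id)."""
    strains = sorted(prevalence_table.prevalence)
    missing = [s for s in strains if s not in mean_ani]
    if missing:
        raise ValueError(f"strains missing from ANI input: {missing}")
    missing = [s for s in mean_ani if s not in prevalence_table.prevalence]
    if missing:
        raise ValueError(f"strains missing from prevalence input: {sorted(missing)}")
    scores = [
        AxPScore(
            strain_id=s,
            mean_ani=float(mean_ani[s]),
            prevalence=float(prevalence_table.prevalence[s]),
            axp=float(mean_ani[s]) * float(prevalence_table.prevalence[s]) * 100.0,
        )
        for s in strains
    ]
    return sorted(scores, key=lambda x: (-x.axp, x.strain_id))
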