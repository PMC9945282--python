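"""Fragment-based average nucleotide identity (ANI) and genome dereplication.

ANI is estimated ANIb-style: the query genome is chopped into
non-overlapping 1,000 bp fragments, each fragment is placed on the reference
by shared 16-mer seeding (both strands) and aligned globally to the seeded
candidate region, and the ANI in one direction is the mean identity of the
retained fragments (aligned over >= 70 % of the fragment with >= 30 %
identity).  The reported value is the mean of the two directions, so it is
symmetric by construction.

Dereplication collapses genomes with ANI at or above a threshold (default
0.99) into clusters by greedy centroid clustering, seeded in descending
order of an assembly-quality score.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import edlib

from protoselect.genome_qc import GenomeRecord

__all__ = [
    "ANIResult",
    "GenomeCluster",
    "NoAlignableFragments",
    "compute_ani",
    "dereplicate",
    "qc_score",
]

_COMP = str.maketrans("ACGTN", "TGCAN")
_CIGAR_OP = re.compile(r"(\d+)([=XIDM])")


class NoAlignableFragments(ValueError):
    """Raised when no fragment of either genome aligns to the other."""


@dataclass(frozen=True)
class ANIResult:
    query_id: str
    ref_id: str
    ani: float
    n_fragments_used: int
    n_fragments_total: int


@dataclass
class GenomeCluster:
    representative_id: str
    member_ids: set[str]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _fragments(genome: GenomeRecord, fragment_length: int) -> list[str]:
    """Non-overlapping full-length fragments, chopped per contig."""
    frags = []
    for contig in genome.contigs:
        for i in range(0, len(contig) - fragment_length + 1, fragment_length):
            frags.append(contig[i : i + fragment_length])
    return frags


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _seed_diagonal(fragment: str, index: dict[str, list[int]], k: int, stride: int = 4):
    """Most supported (diagonal, support) for one strand, or None."""
    diags: Counter[int] = Counter()
    for off in range(0, len(fragment) - k + 1, stride):
        kmer = fragment[off : off + k]
        if "N" in kmer:
            continue
        for pos in index.get(kmer, ()):
            diags[pos - off] += 1
    if not diags:
        return None
    # deterministic: highest support, then smallest diagonal
    diag, support = min(diags.items(), key=lambda kv: (-kv[1], kv[0]))
    return diag, support


def _cigar_identity(cigar: str) -> tuple[int, int]:
    matches = columns = 0
    for count, op in _CIGAR_OP.findall(cigar):
        n = int(count)
        columns += n
        if op == "=":
            matches += n
    return matches, columns


def _one_direction(
    query: GenomeRecord,
    ref_seq: str,
    index: dict[str, list[int]],
    fragment_length: int,
    k: int,
    min_cov: float,
    min_identity: float,
) -> tuple[float, int, int]:
    """(summed identity, n retained, n total) of query fragments on ref."""
    pad = int(0.2 * fragment_length)
    total_ident = 0.0
    used = 0
    frags = _fragments(query, fragment_length)
    for frag in frags:
        best = None
        for strand_seq in (frag, revcomp(frag)):
            hit = _seed_diagonal(strand_seq, index, k)
            if hit is None:
                continue
            if best is None or hit[1] > best[1]:
                best = (strand_seq, hit[1], hit[0])
        if best is None:
            continue
        strand_seq, _, diag = best
        lo = max(diag - pad, 0)
        hi = min(diag + fragment_length + pad, len(ref_seq))
        region = ref_seq[lo:hi]
        if not region:
            continue
        aln = edlib.align(strand_seq, region, mode="HW", task="path")
        if aln["editDistance"] < 0 or not aln.get("cigar"):
            continue
        matches, columns = _cigar_identity(aln["cigar"])
        if columns < min_cov * fragment_length:
            continue
        identity = matches / columns
        if identity < min_identity:
            continue
        total_ident += identity
        used += 1
    return total_ident, used, len(frags)


def compute_ani(
    a: GenomeRecord,
    b: GenomeRecord,
    fragment_length: int = 1000,
    k: int = 16,
    min_cov: float = 0.7,
    min_identity: float = 0.3,
) -> ANIResult:
    """Symmetric fragment-based ANI between two genomes.

    Raises :class:`NoAlignableFragments` when either direction retains zero
    fragments (e.g. unrelated random sequences that share no 16-mer seed).
    """
    for g in (a, b):
        if g.length < 2 * fragment_length:
            raise ValueError(
                f"genome {g.genome_id!r} shorter than 2 x fragment_length"
            )
    # concatenate contigs with an N spacer so no k-mer or alignment spans a join
    spacer = "N" * k
    seq_a = spacer.join(a.contigs)
    seq_b = spacer.join(b.contigs)
    idx_b = _kmer_index(seq_b, k)
    idx_a = _kmer_index(seq_a, k)
    sum_ab, used_ab, tot_ab = _one_direction(a, seq_b, idx_b, fragment_length, k, min_cov, min_identity)
    sum_ba, used_ba, tot_ba = _one_direction(b, seq_a, idx_a, fragment_length, k, min_cov, min_identity)
    if used_ab == 0 or used_ba == 0:
        raise NoAlignableFragments(
            f"no alignable fragments between {a.genome_id!r} and {b.genome_id!r}"
        )
    ani = 0.5 * (sum_ab / used_ab + sum_ba / used_ba)
    return ANIResult(
        query_id=a.genome_id,
        ref_id=b.genome_id,
        ani=ani,
        n_fragments_used=used_ab + used_ba,
        n_fragments_total=tot_ab + tot_ba,
    )


def qc_score(genome: GenomeRecord) -> float:
    """Centroid-ordering score: coverage x (1 / n_contigs) x total length."""
    cov = genome.coverage if genome.coverage is not None else 0.0
    return cov * (1.0 / len(genome.contigs)) * genome.length


def dereplicate(
    genomes: Sequence[GenomeRecord],
    threshold: float = 0.99,
    ani_fn: Callable[[GenomeRecord, GenomeRecord], ANIResult] | None = None,
) -> list[GenomeCluster]:
    """Greedy centroid clustering at an ANI threshold.

    Genomes are visited in descending quality-score order (ties broken by
    genome_id); the best unassigned genome seeds a cluster and every
    unassigned genome at ANI >= threshold to the seed joins it.  Pairs that
    raise :class:`NoAlignableFragments` are treated as ANI 0.
    """
    if ani_fn is None:
        ani_fn = compute_ani
    order = sorted(genomes, key=lambda g: (-qc_score(g), g.genome_id))
    unassigned = {g.genome_id: g for g in order}
    clusters: list[GenomeCluster] = []
    for seed in order:
        if seed.genome_id not in unassigned:
            continue
        del unassigned[seed.genome_id]
        members = {seed.genome_id}
        for gid in sorted(unassigned):
            try:
                res = ani_fn(seed, unassigned[gid])
                ani = res.ani
            except NoAlignableFragments:
                ani = 0.0
            if ani >= threshold:
                members.add(gid)
        for gid in members - {seed.genome_id}:
            del unassigned[gid]
        clusters.append(GenomeCluster(representative_id=seed.genome_id, member_ids=members))
    return clusters
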