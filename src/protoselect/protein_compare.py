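"""Protein local alignment, the PPOS statistic, and proteome-average PPOS.

PPOS (percentage of positive-scoring matches) is the fraction of alignment
columns that are identical or similar residues:

    PPOS = 100 x (identities + similar matches) / alignment length

where "similar" means a BLOSUM62 substitution score > 0 (identities are
themselves positive-scoring, so the numerator is simply the BLAST
"positives" count).  Gap columns count toward the alignment length and never
toward the numerator.

Alignments are Smith-Waterman with BLOSUM62 and affine gaps (open 11,
extend 1, BLAST convention: a length-L gap costs 11 + L), computed with
Bio.Align.PairwiseAligner.  E-values use fixed gapped Karlin-Altschul
constants (lambda = 0.267, K = 0.041, no length correction), which is
accurate enough near the cutoffs used here.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "ProteinAlignment",
    "PposSummary",
    "NoHomology",
    "local_align",
    "ppos",
    "best_hits",
    "proteome_mean_ppos",
    "LAMBDA",
    "KAPPA",
]

LAMBDA = 0.267
KAPPA = 0.041

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_VALID = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX]+$")

_SEED_K = 3


class NoHomology(ValueError):
    """No qualifying hit between two proteomes."""


@dataclass(frozen=True)
class ProteinAlignment:
    query_id: str
    subject_id: str
    raw_score: int
    identities: int
    positives: int
    alignment_length: int  # columns, including gap columns
    query_cov: float
    subject_cov: float
    evalue: float


@dataclass(frozen=True)
class PposSummary:
    proteome_a: str
    proteome_b: str
    mean_ppos: float
    n_pairs: int


def _aligner() -> PairwiseAligner:
    a = PairwiseAligner(mode="local")
    a.substitution_matrix = _BLOSUM62
    a.open_gap_score = -12.0  # BLAST open 11 + first extension 1
    a.extend_gap_score = -1.0
    return a


_ALIGNER = _aligner()


def _check(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name} sequence is empty")
    seq = seq.upper()
    if not _VALID.match(seq):
        raise ValueError(f"{name} sequence contains characters outside the amino-acid alphabet")
    return seq


def evalue(raw_score: float, m: int, n: int) -> float:
    return KAPPA * m * n * math.exp(-LAMBDA * raw_score)


def local_align(
    p: str, q: str, query_id: str = "query", subject_id: str = "subject"
) -> ProteinAlignment:
    """Optimal Smith-Waterman local alignment of two protein sequences."""
    p = _check(p, "query")
    q = _check(q, "subject")
    alignments = _ALIGNER.align(p, q)
    if len(alignments) == 0 or alignments.score <= 0:
        return ProteinAlignment(query_id, subject_id, 0, 0, 0, 0, 0.0, 0.0, math.inf)
    aln = alignments[0]
    blocks = aln.aligned  # ((p_start, p_end), ...), ((q_start, q_end), ...)
    p_blocks, q_blocks = blocks
    identities = positives = 0
    columns = 0
    for (ps, pe), (qs, qe) in zip(p_blocks, q_blocks):
        for i in range(pe - ps):
            a, b = p[ps + i], q[qs + i]
            if a == b:
                identities += 1
            # identities always count as positives (covers X-X, which
            # BLOSUM62 scores negatively)
            if a == b or _BLOSUM62[a, b] > 0:
                positives += 1
        columns += pe - ps
    # internal gap columns between consecutive aligned blocks
    for i in range(1, len(p_blocks)):
        columns += (p_blocks[i][0] - p_blocks[i - 1][1]) + (q_blocks[i][0] - q_blocks[i - 1][1])
    p_span = p_blocks[-1][1] - p_blocks[0][0]
    q_span = q_blocks[-1][1] - q_blocks[0][0]
    score = int(round(aln.score))
    return ProteinAlignment(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=score,
        identities=identities,
        positives=positives,
        alignment_length=columns,
        query_cov=p_span / len(p),
        subject_cov=q_span / len(q),
        evalue=evalue(score, len(p), len(q)),
    )


def ppos(alignment: ProteinAlignment) -> float:
    """100 x positives / alignment length."""
    if alignment.alignment_length == 0:
        raise ValueError("zero-length alignment")
    return 100.0 * alignment.positives / alignment.alignment_length


def _seed_words(seq: str) -> set[str]:
    return {seq[i : i + _SEED_K] for i in range(len(seq) - _SEED_K + 1)}


def _as_items(proteome) -> list[tuple[str, str]]:
    if isinstance(proteome, Mapping):
        return sorted(proteome.items())
    return sorted(proteome)


def best_hits(
    proteome_a, proteome_b, max_evalue: float = 1e-5
) -> list[ProteinAlignment]:
    """Best hit in B for every protein of A passing the e-value cutoff.

    Subject candidates are prefiltered to those sharing at least one
    3-letter word with the query (hits excluded by that filter score far
    below any practical e-value cutoff); candidates are aligned exactly.
    Ties in score are broken by the lexicographically smaller subject id.
    """
    items_a = _as_items(proteome_a)
    items_b = _as_items(proteome_b)
    if not items_a or not items_b:
        raise ValueError("proteomes must be non-empty")
    words_b = [(sid, seq, _seed_words(seq)) for sid, seq in items_b]
    hits: list[ProteinAlignment] = []
    for qid, qseq in items_a:
        qwords = _seed_words(qseq)
        best: ProteinAlignment | None = None
        for sid, sseq, swords in words_b:
            if not (qwords & swords):
                continue
            aln = local_align(qseq, sseq, query_id=qid, subject_id=sid)
            if aln.evalue > max_evalue:
                continue
            if (
                best is None
                or aln.raw_score > best.raw_score
                or (aln.raw_score == best.raw_score and sid < best.subject_id)
            ):
                best = aln
        if best is not None:
            hits.append(best)
    return hits


def proteome_mean_ppos(
    proteome_a,
    proteome_b,
    name_a: str = "A",
    name_b: str = "B",
    max_evalue: float = 1e-5,
    bidirectional: bool = False,
) -> PposSummary:
    """Mean PPOS over A-to-B best-hit pairs (optionally averaged with B-to-A)."""
    hits = best_hits(proteome_a, proteome_b, max_evalue=max_evalue)
    if not hits:
        raise NoHomology(f"no best hits between {name_a!r} and {name_b!r}")
    mean_ab = sum(ppos(h) for h in hits) / len(hits)
    n_pairs = len(hits)
    if bidirectional:
        back = best_hits(proteome_b, proteome_a, max_evalue=max_evalue)
        if not back:
            raise NoHomology(f"no best hits between {name_b!r} and {name_a!r}")
        mean_ab = 0.5 * (mean_ab + sum(ppos(h) for h in back) / len(back))
    return PposSummary(proteome_a=name_a, proteome_b=name_b, mean_ppos=mean_ab, n_pairs=n_pairs)
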