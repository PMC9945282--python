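"""Biobank prototype selection: rank local strains against a reference genome.

The ecologically optimal strain identified from public data is usually not
physically available, so the closest strain in a local biobank is selected
instead.  Each candidate is scored against the reference by whole-genome ANI
(as a percentage) and by the proteome-average PPOS of its best-hit protein
pairs, combined as a weighted mean (default: unweighted average of the two
percentages).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from protoselect.ani_core import NoAlignableFragments, compute_ani
from protoselect.genome_qc import GenomeRecord
from protoselect.protein_compare import NoHomology, proteome_mean_ppos

__all__ = ["SelectorRanking", "select_prototype"]


@dataclass(frozen=True)
class SelectorRanking:
    candidate_id: str
    ani_pct: float
    mean_ppos: float
    combined: float
    rank: int
    flagged: bool = False  # True when no protein homology was found


def select_prototype(
    reference: GenomeRecord,
    reference_proteome,
    biobank: Sequence[GenomeRecord],
    biobank_proteomes: Mapping[str, object],
    ani_weight: float = 0.5,
) -> list[SelectorRanking]:
    """Rank biobank candidates by combined ANI% / mean-PPOS closeness.

    ``combined = ani_weight * ani_pct + (1 - ani_weight) * mean_ppos``;
    candidates are sorted descending, ties broken by ani_pct then id.
    A candidate whose proteome shares no homology with the reference is kept
    in the ranking with mean_ppos 0 and ``flagged=True`` rather than
    aborting the run.
    """
    if not biobank:
        raise ValueError("biobank is empty")
    if not 0.0 <= ani_weight <= 1.0:
        raise ValueError("ani_weight must be in [0, 1]")
    ids = [g.genome_id for g in biobank]
    if reference.genome_id in ids:
        raise ValueError("reference genome must not be part of the biobank")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate candidate ids in biobank")
    rows = []
    for cand in sorted(biobank, key=lambda g: g.genome_id):
        try:
            ani = compute_ani(cand, reference).ani
        except NoAlignableFragments:
            ani = 0.0
        flagged = False
        try:
            summary = proteome_mean_ppos(
                biobank_proteomes[cand.genome_id],
                reference_proteome,
                name_a=cand.genome_id,
                name_b=reference.genome_id,
            )
            mean_ppos = summary.mean_ppos
        except NoHomology:
            mean_ppos = 0.0
            flagged = True
        ani_pct = 100.0 * ani
        combined = ani_weight * ani_pct + (1.0 - ani_weight) * mean_ppos
        rows.append((cand.genome_id, ani_pct, mean_ppos, combined, flagged))
    rows.sort(key=lambda r: (-r[3], -r[1], r[0]))
    return [
        SelectorRanking(cid, ani_pct, mp, comb, rank=i + 1, flagged=fl)
        for i, (cid, ani_pct, mp, comb, fl) in enumerate(rows)
    ]
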