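"""Pangenome gene-family clustering and focal-strain unique genes.

Predicted proteomes are compared all-vs-all; a pair of genes is connected
when a local alignment passes all of e-value <= 1e-10, identity >= 50 %
(computed over alignment columns, gaps included), and coverage >= 80 % of
BOTH sequences.  The resulting weighted graph is partitioned into clusters
of orthologous genes (gene families) with the Markov clustering algorithm,
and a family present in the focal strain but absent from every other strain
is reported as a focal-unique gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from protoselect.protein_compare import local_align, _seed_words

__all__ = [
    "GeneFamily",
    "PresenceAbsenceMatrix",
    "all_vs_all_hits",
    "mcl_cluster",
    "presence_absence",
    "unique_genes",
]

MAX_EDGE_WEIGHT = 200.0
_PRUNE = 1e-8


@dataclass(frozen=True)
class GeneFamily:
    family_id: str
    members: tuple[tuple[str, str], ...]  # (strain_id, gene_id)


@dataclass
class PresenceAbsenceMatrix:
    """Gene-family occupancy: rows = family_id, columns = strain_id,
    cells = number of member genes of that family in that strain."""

    table: pd.DataFrame

    @property
    def family_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def strain_ids(self) -> list[str]:
        return list(self.table.columns)


def all_vs_all_hits(
    proteomes: Mapping[str, Sequence[tuple[str, str]]],
    max_evalue: float = 1e-10,
    min_identity: float = 0.5,
    min_coverage: float = 0.8,
) -> nx.Graph:
    """Thresholded all-vs-all protein hit graph.

    Nodes are (strain_id, gene_id); an undirected edge requires
    e-value <= ``max_evalue``, identity >= ``min_identity`` over alignment
    columns, and aligned coverage >= ``min_coverage`` of both sequences.
    The alignment is symmetric in the two sequences, so one alignment per
    unordered pair decides the edge.  Edge weight is -log10(e-value),
    capped at 200.  Within-strain pairs (paralogs) are compared too.
    """
    if len(proteomes) < 2:
        raise ValueError("need at least 2 proteomes")
    genes: list[tuple[str, str, str]] = []  # (strain, gene_id, seq)
    for strain in sorted(proteomes):
        for gene_id, seq in sorted(proteomes[strain]):
            genes.append((strain, gene_id, seq))
    graph = nx.Graph()
    words = [_seed_words(seq) for _, _, seq in genes]
    for strain, gene_id, _ in genes:
        graph.add_node((strain, gene_id))
    for i in range(len(genes)):
        si, gi, pi = genes[i]
        for j in range(i + 1, len(genes)):
            sj, gj, pj = genes[j]
            if not (words[i] & words[j]):
                continue
            aln = local_align(pi, pj, query_id=gi, subject_id=gj)
            if aln.alignment_length == 0 or aln.evalue > max_evalue:
                continue
            identity = aln.identities / aln.alignment_length
            if identity < min_identity:
                continue
            if aln.query_cov < min_coverage or aln.subject_cov < min_coverage:
                continue
            weight = min(MAX_EDGE_WEIGHT, -np.log10(max(aln.evalue, 10.0 ** -MAX_EDGE_WEIGHT)))
            graph.add_edge((si, gi), (sj, gj), weight=weight)
    return graph


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 1.5,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> list[GeneFamily]:
    """Markov clustering of the hit graph into gene families.

    Self-loops are added with weight equal to each node's maximum incident
    edge weight (1 for isolated nodes); the column-stochastic matrix is
    alternately squared (expansion) and entrywise powered and renormalised
    (inflation), pruning entries below 1e-8, until the largest entry change
    falls below ``tol``.  Families are the connected components of the limit
    matrix; isolated genes become singleton families.  Family ids are
    assigned in order of each family's smallest member gene.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return []
    idx = {node: i for i, node in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        m[idx[u], idx[v]] = w
        m[idx[v], idx[u]] = w
    loops = m.max(axis=0)
    loops[loops <= 0] = 1.0
    m[np.diag_indices(n)] = loops
    m = m / m.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        expanded = m @ m
        inflated = expanded ** inflation
        inflated[inflated < _PRUNE] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated = inflated / colsum
        if np.max(np.abs(inflated - m)) < tol:
            m = inflated
            converged = True
            break
        m = inflated
    if not converged:
        warnings.warn(
            f"Markov clustering did not converge within {max_iter} iterations; "
            "returning the current partition",
            RuntimeWarning,
        )
    limit = nx.Graph()
    limit.add_nodes_from(range(n))
    rows, cols = np.nonzero(m > _PRUNE)
    limit.add_edges_from((int(r), int(c)) for r, c in zip(rows, cols) if r != c)
    comps = [sorted(nodes[i] for i in comp) for comp in nx.connected_components(limit)]
    comps.sort(key=lambda members: members[0])
    return [
        GeneFamily(family_id=f"F{i + 1:05d}", members=tuple(members))
        for i, members in enumerate(comps)
    ]


def presence_absence(
    families: Sequence[GeneFamily], strain_ids: Sequence[str] | None = None
) -> PresenceAbsenceMatrix:
    """Count matrix of family members per strain."""
    if strain_ids is None:
        strain_ids = sorted({s for fam in families for s, _ in fam.members})
    table = pd.DataFrame(
        0, index=[f.family_id for f in families], columns=list(strain_ids), dtype=int
    )
    for fam in families:
        for strain, _ in fam.members:
            table.loc[fam.family_id, strain] += 1
    return PresenceAbsenceMatrix(table=table)


def unique_genes(matrix: PresenceAbsenceMatrix, focal: str) -> list[str]:
    """Families with >= 1 member in ``focal`` and 0 members everywhere else."""
    if focal not in matrix.table.columns:
        raise ValueError(f"unknown focal strain {focal!r}")
    others = [c for c in matrix.table.columns if c != focal]
    mask = (matrix.table[focal] >= 1) & (matrix.table[others].sum(axis=1) == 0)
    return list(matrix.table.index[mask])
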