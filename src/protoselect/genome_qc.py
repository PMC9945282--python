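"""Genome records, assembly statistics, and quality filtering.

Public genome databases mix finished genomes with fragmented, low-coverage
draft assemblies.  Before any genome-to-genome comparison the database is
reduced to assemblies with sequencing coverage above 30-fold and fewer than
100 contigs; both thresholds are strict (a genome at exactly 30x or exactly
100 contigs is rejected).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "GenomeRecord",
    "AssemblyStats",
    "QCReject",
    "assembly_stats",
    "qc_filter",
    "read_genomes",
    "write_genome_fasta",
]

_VALID_CHARS = re.compile(r"^[ACGTN]*$")

#: QC thresholds: retain iff coverage > COVERAGE_MIN and n_contigs < MAX_CONTIGS.
COVERAGE_MIN = 30.0
MAX_CONTIGS = 100


@dataclass
class GenomeRecord:
    """One strain assembly: contigs plus coverage metadata and source label."""

    genome_id: str
    contigs: list[str]
    coverage: float | None = None
    source: str = "public"

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError(f"genome {self.genome_id!r} has no contigs")
        for c in self.contigs:
            if not _VALID_CHARS.match(c):
                raise ValueError(
                    f"genome {self.genome_id!r}: contig alphabet must be A/C/G/T/N"
                )
        if self.coverage is not None and self.coverage < 0:
            raise ValueError(f"genome {self.genome_id!r}: negative coverage")
        if self.source not in ("public", "biobank"):
            raise ValueError(f"genome {self.genome_id!r}: unknown source {self.source!r}")

    @property
    def length(self) -> int:
        return sum(len(c) for c in self.contigs)

    @property
    def sequence(self) -> str:
        """All contigs concatenated (used for whole-genome alignment oracles)."""
        return "".join(self.contigs)


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    total_length: int
    n50: int


@dataclass(frozen=True)
class QCReject:
    genome: GenomeRecord
    reason: str  # "low_coverage" | "too_many_contigs"


def assembly_stats(genome: GenomeRecord) -> AssemblyStats:
    """Contig count, total length, and N50.

    N50 is the length of the smallest contig in the descending-sorted prefix
    whose cumulative length first reaches half the total assembly length.
    """
    lengths = sorted((len(c) for c in genome.contigs), reverse=True)
    total = sum(lengths)
    half = total / 2
    acc = 0
    n50 = lengths[-1]
    for ln in lengths:
        acc += ln
        if acc >= half:
            n50 = ln
            break
    return AssemblyStats(n_contigs=len(lengths), total_length=total, n50=n50)


def qc_filter(
    genomes: Iterable[GenomeRecord],
) -> tuple[list[GenomeRecord], list[QCReject]]:
    """Partition genomes into retained and rejected-with-reason.

    Retained iff coverage > 30-fold AND fewer than 100 contigs.  Coverage
    metadata is mandatory: a genome without it raises rather than silently
    passing or failing the filter.
    """
    retained: list[GenomeRecord] = []
    rejected: list[QCReject] = []
    seen: set[str] = set()
    for g in genomes:
        if g.genome_id in seen:
            raise ValueError(f"duplicate genome_id {g.genome_id!r}")
        seen.add(g.genome_id)
        if g.coverage is None:
            raise ValueError(f"genome {g.genome_id!r}: coverage metadata missing")
        if not g.coverage > COVERAGE_MIN:
            rejected.append(QCReject(g, "low_coverage"))
        elif not len(g.contigs) < MAX_CONTIGS:
            rejected.append(QCReject(g, "too_many_contigs"))
        else:
            retained.append(g)
    return retained, rejected


def read_genomes(fasta_paths: Iterable[str | Path], metadata_tsv: str | Path | None = None):
    """Read one genome per FASTA file, joining coverage/source metadata by genome_id.

    The metadata TSV has columns genome_id, coverage and optionally source;
    the genome_id is the FASTA file stem.
    """
    import pandas as pd

    meta = {}
    if metadata_tsv is not None:
        df = pd.read_csv(metadata_tsv, sep="\t", dtype={"genome_id": str})
        for row in df.itertuples(index=False):
            meta[row.genome_id] = row
    genomes = []
    for p in fasta_paths:
        p = Path(p)
        gid = p.stem
        contigs = [str(rec.seq).upper() for rec in SeqIO.parse(str(p), "fasta")]
        cov = None
        source = "public"
        if gid in meta:
            cov = float(meta[gid].coverage)
            source = getattr(meta[gid], "source", "public")
        genomes.append(GenomeRecord(gid, contigs, coverage=cov, source=source))
    return genomes


def write_genome_fasta(genome: GenomeRecord, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for i, contig in enumerate(genome.contigs, start=1):
            fh.write(f">{genome.genome_id}_contig{i}\n")
            for j in range(0, len(contig), width):
                fh.write(contig[j : j + width] + "\n")
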