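"""End-to-end orchestration of the prototype-selection and DGE stages.

``run_selection`` executes genome QC -> pairwise ANI -> dereplication ->
strain tracking -> prevalence -> AxP ranking -> biobank selection and writes
per-stage TSVs plus one JSON report.  ``run_interactome`` executes the
CPM-filter -> TMM -> exact-test differential-expression stage on a
two-condition count matrix.  Both are deterministic given the same inputs
and master seed, and reruns produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from protoselect import (
    ani_core,
    biobank_selector,
    dge,
    genome_qc,
    strain_tracking,
)

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_selection",
    "run_interactome",
    "read_fastq",
    "read_proteome_fasta",
]

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the offending detail."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Resolved inputs and stage parameters for one pipeline run."""

    outdir: Path
    genomes: list[Path] = field(default_factory=list)
    metadata: Path | None = None
    samples: list[Path] = field(default_factory=list)
    proteomes: dict[str, Path] = field(default_factory=dict)
    biobank_genomes: list[Path] = field(default_factory=list)
    biobank_proteomes: dict[str, Path] = field(default_factory=dict)
    counts: Path | None = None
    groups: Path | None = None
    seed: int = 0
    ani_threshold: float = 0.99
    fragment_length: int = 1000
    k: int = 23
    min_score: float = 0.1
    max_iterations: int = 5
    ani_weight: float = 0.5
    min_cpm: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw["outdir"] = Path(raw.get("outdir", "."))
        for key in ("genomes", "samples", "biobank_genomes"):
            raw[key] = [Path(p) for p in raw.get(key, [])]
        for key in ("proteomes", "biobank_proteomes"):
            raw[key] = {k: Path(v) for k, v in raw.get(key, {}).items()}
        for key in ("metadata", "counts", "groups"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(**raw)

    def resolved_dict(self) -> dict:
        d = asdict(self)

        def conv(v):
            if isinstance(v, Path):
                return str(v)
            if isinstance(v, list):
                return [conv(x) for x in v]
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            return v

        return {k: conv(v) for k, v in sorted(d.items())}


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def read_proteome_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _write_resolved_config(config: RunConfig, outdir: Path) -> None:
    _write_json({"schema_version": REPORT_SCHEMA_VERSION, "config": config.resolved_dict()}, outdir / "resolved_config.json")


def run_selection(config: RunConfig) -> dict:
    """Execute the full selection pipeline; returns the JSON-able report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_resolved_config(config, outdir)

    # --- qc ---
    try:
        genomes = genome_qc.read_genomes(config.genomes, config.metadata)
        retained, rejected = genome_qc.qc_filter(genomes)
    except Exception as e:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError("qc", str(e)) from e
    pd.DataFrame(
        [(g.genome_id, "retained", "") for g in retained]
        + [(r.genome.genome_id, "rejected", r.reason) for r in rejected]
    ).rename(columns={0: "genome_id", 1: "status", 2: "reason"}).to_csv(
        outdir / "qc.tsv", sep="\t", index=False
    )
    if not retained:
        raise PipelineError("qc", "no genome passed the quality filter")

    # --- pairwise ANI ---
    try:
        ani_matrix: dict[tuple[str, str], float] = {}
        rows = []
        ordered = sorted(retained, key=lambda g: g.genome_id)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                try:
                    res = ani_core.compute_ani(a, b, fragment_length=config.fragment_length)
                    ani = res.ani
                    used, tot = res.n_fragments_used, res.n_fragments_total
                except ani_core.NoAlignableFragments:
                    ani, used, tot = 0.0, 0, 0
                ani_matrix[(a.genome_id, b.genome_id)] = ani
                rows.append((a.genome_id, b.genome_id, ani, used, tot))
        pd.DataFrame(rows, columns=["query", "ref", "ani", "fragments_used", "fragments_total"]).to_csv(
            outdir / "ani.tsv", sep="\t", index=False, float_format="%.6f"
        )
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("ani", str(e)) from e

    # --- dereplication ---
    def cached_ani(a, b):
        key = (min(a.genome_id, b.genome_id), max(a.genome_id, b.genome_id))
        return ani_core.ANIResult(a.genome_id, b.genome_id, ani_matrix[key], 0, 0)

    clusters = ani_core.dereplicate(retained, threshold=config.ani_threshold, ani_fn=cached_ani)
    pd.DataFrame(
        [(c.representative_id, m) for c in clusters for m in sorted(c.member_ids)],
        columns=["representative", "member"],
    ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    reps = {c.representative_id for c in clusters}
    rep_genomes = [g for g in retained if g.genome_id in reps]

    # --- strain tracking ---
    try:
        db = strain_tracking.build_kmer_db(rep_genomes, k=config.k)
        detections = []
        sample_ids = []
        for fq in sorted(config.samples):
            sample_id = Path(fq).stem
            sample_ids.append(sample_id)
            reads = read_fastq(fq)
            detections.extend(
                strain_tracking.detect_strains(
                    db,
                    reads,
                    sample_id=sample_id,
                    min_score=config.min_score,
                    max_iterations=config.max_iterations,
                )
            )
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("track", str(e)) from e
    if not sample_ids:
        raise PipelineError("track", "no metagenome samples provided")
    pd.DataFrame(
        [(d.sample_id, d.strain_id, d.score, d.iteration) for d in detections],
        columns=["sample_id", "strain_id", "score", "iteration"],
    ).to_csv(outdir / "detections.tsv", sep="\t", index=False, float_format="%.6f")

    # --- prevalence + AxP ---
    table = strain_tracking.prevalence(
        detections, n_samples=len(sample_ids), strain_ids=sorted(reps), sample_ids=sample_ids
    )
    rep_ani = {
        (a, b): v for (a, b), v in ani_matrix.items() if a in reps and b in reps
    }
    if len(reps) < 2:
        raise PipelineError("axp", "need at least two dereplicated genomes for mean ANI")
    mean_ani = strain_tracking.mean_ani_per_strain(rep_ani)
    scores = strain_tracking.axp_rank(mean_ani, table)
    pd.DataFrame(
        [(s.strain_id, s.mean_ani, s.prevalence, s.axp, i + 1) for i, s in enumerate(scores)],
        columns=["strain_id", "mean_ani", "prevalence", "axp", "rank"],
    ).to_csv(outdir / "axp.tsv", sep="\t", index=False, float_format="%.6f")
    top = scores[0].strain_id

    # --- biobank selection ---
    try:
        if not config.biobank_genomes:
            raise PipelineError("select", "biobank is empty")
        if top not in config.proteomes:
            raise PipelineError("select", f"no proteome provided for top strain {top!r}")
        reference = next(g for g in rep_genomes if g.genome_id == top)
        reference_proteome = read_proteome_fasta(config.proteomes[top])
        biobank = genome_qc.read_genomes(config.biobank_genomes)
        for g in biobank:
            g.source = "biobank"
        biobank_proteomes = {
            gid: read_proteome_fasta(p) for gid, p in config.biobank_proteomes.items()
        }
        ranking = biobank_selector.select_prototype(
            reference, reference_proteome, biobank, biobank_proteomes, ani_weight=config.ani_weight
        )
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("select", str(e)) from e
    pd.DataFrame(
        [(r.candidate_id, r.ani_pct, r.mean_ppos, r.combined, r.rank, r.flagged) for r in ranking],
        columns=["candidate_id", "ani_pct", "mean_ppos", "combined", "rank", "flagged"],
    ).to_csv(outdir / "selector.tsv", sep="\t", index=False, float_format="%.6f")

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "n_input_genomes": len(genomes),
        "n_retained": len(retained),
        "n_clusters": len(clusters),
        "representatives": sorted(reps),
        "n_samples": len(sample_ids),
        "axp_ranking": [
            {
                "strain_id": s.strain_id,
                "mean_ani": round(s.mean_ani, 6),
                "prevalence": round(s.prevalence, 6),
                "axp": round(s.axp, 6),
            }
            for s in scores
        ],
        "top_axp_strain": top,
        "selector_ranking": [
            {
                "candidate_id": r.candidate_id,
                "ani_pct": round(r.ani_pct, 6),
                "mean_ppos": round(r.mean_ppos, 6),
                "combined": round(r.combined, 6),
                "rank": r.rank,
            }
            for r in ranking
        ],
        "prototype": ranking[0].candidate_id,
    }
    _write_json(report, outdir / "selection_report.json")
    return report


def run_interactome(config: RunConfig) -> dict:
    """CPM filter -> TMM -> exact NB test on the configured count matrix."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.counts is None or config.groups is None:
        raise PipelineError("dge", "counts and groups paths are required")
    try:
        matrix = dge.read_counts_tsv(config.counts, config.groups)
        filtered = dge.cpm_filter(matrix, min_cpm=config.min_cpm)
        factors = dge.tmm_factors(filtered)
        results = dge.test_de(filtered, factors)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("dge", str(e)) from e
    df = dge.results_frame(results)
    df.to_csv(outdir / "dge_results.tsv", sep="\t", index=False, float_format="%.6g")
    df[["gene_id", "log2fc", "neg_log10_fdr"]].to_csv(
        outdir / "volcano.tsv", sep="\t", index=False, float_format="%.6g"
    )
    sig = df[df["significant"]]
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "n_genes_input": len(matrix.gene_ids),
        "n_genes_tested": len(filtered.gene_ids),
        "tmm_factors": {
            s: round(float(f), 6) for s, f in zip(filtered.sample_ids, factors)
        },
        "n_significant": int(len(sig)),
        "n_up": int((sig["log2fc"] > 0).sum()),
        "n_down": int((sig["log2fc"] < 0).sum()),
    }
    _write_json(report, outdir / "dge_report.json")
    return report
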