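"""Differential expression on a two-condition count matrix.

The stage mirrors the standard small-sample RNA-seq workflow: genes with
counts-per-million (CPM) below 1 are filtered, library composition bias is
corrected with trimmed-mean-of-M-values (TMM) factors, and each gene is
tested with an exact negative-binomial conditional test on group sums.
A gene is called significant when its fold change is at least 2-fold
(|log2FC| >= 1) and its Benjamini-Hochberg FDR is at most 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "DGEResult",
    "cpm_filter",
    "tmm_factors",
    "test_de",
    "read_counts_tsv",
    "results_frame",
]

FC_THRESHOLD = 2.0
FDR_THRESHOLD = 0.05
PRIOR_COUNT = 0.5


@dataclass
class CountMatrix:
    """Genes x samples integer counts with a sample-to-group map."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    groups: Mapping[str, str]  # sample -> "control" | "treated"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match gene/sample ids")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        labels = {self.groups[s] for s in self.sample_ids}
        if labels != {"control", "treated"}:
            raise ValueError(
                f"groups must contain both 'control' and 'treated', got {sorted(labels)}"
            )

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def group_mask(self, label: str) -> np.ndarray:
        return np.array([self.groups[s] == label for s in self.sample_ids])

    def cpm(self, prior_count: float = 0.0, effective_lib: np.ndarray | None = None) -> np.ndarray:
        lib = self.library_sizes if effective_lib is None else effective_lib
        return (self.counts + prior_count) / (lib + 2 * prior_count)[None, :] * 1e6

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class DGEResult:
    gene_id: str
    log2fc: float
    pvalue: float
    fdr: float
    significant: bool


def cpm_filter(
    m: CountMatrix, min_cpm: float = 1.0, min_samples: int | None = None
) -> CountMatrix:
    """Drop genes whose CPM is below ``min_cpm`` in too many samples.

    A gene is retained when CPM >= ``min_cpm`` in at least ``min_samples``
    samples (default: the size of the smaller group, so a gene expressed in
    one full group survives).
    """
    lib = m.library_sizes
    if (lib == 0).any():
        raise ValueError("sample with zero library size")
    if min_samples is None:
        n_ctrl = int(m.group_mask("control").sum())
        n_trt = int(m.group_mask("treated").sum())
        min_samples = min(n_ctrl, n_trt)
    cpm = m.counts / lib[None, :] * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError("CPM filter removed every gene")
    return CountMatrix(
        gene_ids=[g for g, k in zip(m.gene_ids, keep) if k],
        sample_ids=list(m.sample_ids),
        counts=m.counts[keep],
        groups=dict(m.groups),
    )


def _choose_reference(counts: np.ndarray, lib: np.ndarray) -> int:
    """Sample whose upper-quartile count fraction is closest to the mean."""
    f75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])])
    return int(np.argmin(np.abs(f75 - f75.mean())))


def tmm_factors(
    m: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref: int | None = None,
) -> np.ndarray:
    """Per-sample TMM scaling factors (geometric mean 1).

    For each sample against the reference, gene-wise log ratios
    M = log2((y_j/N_j)/(y_r/N_r)) and abundances A on genes with nonzero
    counts in both samples are doubly trimmed (``trim_m`` of M on each side,
    ``trim_a`` of A), and the factor is 2 to the precision-weighted mean of
    the surviving M values, with inverse weights from the delta-method
    binomial variance.
    """
    counts = m.counts
    lib = m.library_sizes
    if (lib == 0).any():
        raise ValueError("sample with zero library size")
    if ref is None:
        ref = _choose_reference(counts, lib)
    n_samples = counts.shape[1]
    factors = np.ones(n_samples)
    yr = counts[:, ref].astype(float)
    for j in range(n_samples):
        if j == ref:
            continue
        yj = counts[:, j].astype(float)
        ok = (yj > 0) & (yr > 0)
        if ok.sum() == 0:
            continue
        pj = yj[ok] / lib[j]
        pr = yr[ok] / lib[ref]
        M = np.log2(pj / pr)
        A = 0.5 * np.log2(pj * pr)
        v = (lib[j] - yj[ok]) / (lib[j] * yj[ok]) + (lib[ref] - yr[ok]) / (lib[ref] * yr[ok])
        if np.max(np.abs(M)) < 1e-6:
            continue
        n = M.size
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rm = stats.rankdata(M)
        ra = stats.rankdata(A)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if keep.sum() == 0 or not np.isfinite(v[keep]).all():
            continue
        w = 1.0 / v[keep]
        f = np.sum(w * M[keep]) / np.sum(w)
        if np.isfinite(f):
            factors[j] = 2.0 ** f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def _moment_dispersions(norm_counts: np.ndarray, masks: Sequence[np.ndarray]) -> np.ndarray:
    """Gene-wise NB dispersion by method of moments, floored at zero and
    shrunk halfway toward the matrix-wide mean."""
    per_gene = np.zeros(norm_counts.shape[0])
    n_used = np.zeros(norm_counts.shape[0])
    for mask in masks:
        grp = norm_counts[:, mask]
        mu = grp.mean(axis=1)
        var = grp.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = (var - mu) / mu**2
        ok = mu > 0
        per_gene[ok] += np.maximum(phi[ok], 0.0)
        n_used[ok] += 1
    per_gene = np.where(n_used > 0, per_gene / np.maximum(n_used, 1), 0.0)
    return 0.5 * per_gene + 0.5 * per_gene.mean()


def _exact_conditional_pvalue(s1: int, t: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact test of S1 given S1+S2=t under a shared NB mean.

    Sums the conditional probabilities of all outcomes no more likely than
    the observed one.  With dispersion ~0 the conditional law is binomial
    (the Poisson case); otherwise it is the ratio of two NB pmfs, using
    sum_of_n_iid NB(mu, phi) = NB(n*mu, phi/n).
    """
    if t == 0:
        return 1.0
    k = np.arange(t + 1)
    if phi < 1e-8:
        logp = stats.binom.logpmf(k, t, n1 / (n1 + n2))
    else:
        mu = t / (n1 + n2)
        r1, r2 = n1 / phi, n2 / phi
        logp = stats.nbinom.logpmf(k, r1, r1 / (r1 + n1 * mu)) + stats.nbinom.logpmf(
            t - k, r2, r2 / (r2 + n2 * mu)
        )
        logp -= logsumexp_stable(logp)
    p_obs = logp[s1]
    mask = logp <= p_obs + 1e-10
    return float(min(1.0, np.exp(logsumexp_stable(logp[mask]))))


def logsumexp_stable(x: np.ndarray) -> float:
    m = np.max(x)
    if not np.isfinite(m):
        return m
    return float(m + np.log(np.sum(np.exp(x - m))))


def test_de(m: CountMatrix, factors: np.ndarray | None = None) -> list[DGEResult]:
    """Exact NB test per gene with TMM-effective library sizes.

    Counts are rescaled to a common (geometric-mean) effective library size
    and rounded; group sums are compared with the exact conditional test.
    log2FC is computed between group means of CPM with a prior count of
    0.5.  Significance requires |fold change| >= 2 and BH-FDR <= 0.05.
    """
    if factors is None:
        factors = tmm_factors(m)
    ctrl = m.group_mask("control")
    trt = m.group_mask("treated")
    if ctrl.sum() < 2 or trt.sum() < 2:
        raise ValueError("need at least 2 samples per group")
    lib = m.library_sizes
    eff = lib * np.asarray(factors)
    common = np.exp(np.mean(np.log(eff)))
    norm = np.rint(m.counts * (common / eff)[None, :]).astype(np.int64)
    phi = _moment_dispersions(norm.astype(float), [ctrl, trt])

    cpm = m.cpm(prior_count=PRIOR_COUNT, effective_lib=eff)
    log2fc = np.log2(cpm[:, trt].mean(axis=1)) - np.log2(cpm[:, ctrl].mean(axis=1))

    n1, n2 = int(ctrl.sum()), int(trt.sum())
    s1 = norm[:, ctrl].sum(axis=1)
    s2 = norm[:, trt].sum(axis=1)
    pvals = np.array(
        [
            _exact_conditional_pvalue(int(a), int(a + b), n1, n2, float(ph))
            for a, b, ph in zip(s1, s2, phi)
        ]
    )
    fdr = stats.false_discovery_control(pvals, method="bh")
    results = []
    for gid, lfc, p, q in zip(m.gene_ids, log2fc, pvals, fdr):
        sig = bool(abs(lfc) >= np.log2(FC_THRESHOLD) and q <= FDR_THRESHOLD)
        results.append(DGEResult(gid, float(lfc), float(p), float(q), sig))
    return results


def results_frame(results: Sequence[DGEResult]) -> pd.DataFrame:
    """Results as a TSV-ready table, plus a -log10 FDR column for volcano plots."""
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "log2fc": [r.log2fc for r in results],
            "pvalue": [r.pvalue for r in results],
            "fdr": [r.fdr for r in results],
            "significant": [r.significant for r in results],
        }
    )
    df["neg_log10_fdr"] = -np.log10(np.maximum(df["fdr"], 1e-300))
    return df


def read_counts_tsv(counts_tsv: str | Path, groups_tsv: str | Path) -> CountMatrix:
    """Counts: first column gene_id, remaining columns samples.
    Groups: two columns sample_id, group (control/treated)."""
    df = pd.read_csv(counts_tsv, sep="\t", index_col=0)
    gmap = pd.read_csv(groups_tsv, sep="\t", index_col=0)["group"].to_dict()
    return CountMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        counts=df.to_numpy(dtype=np.int64),
        groups={str(k): v for k, v in gmap.items()},
    )
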