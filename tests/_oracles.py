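"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the code paths (and, where possible, the
libraries) used by the implementation: the Smith-Waterman oracle is a plain
Gotoh dynamic program, N50 is computed by direct cumulative enumeration, and
whole-genome identity aligns the full sequences in one global pass.
"""

from __future__ import annotations

import re

import edlib
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_CIG = re.compile(r"(\d+)([=XID])")

# BLAST gap convention: a gap of length L costs OPEN + L * EXTEND
GAP_OPEN = 11
GAP_EXTEND = 1


def sw_score(p: str, q: str) -> int:
    """Exhaustive Gotoh local-alignment score, BLOSUM62, affine gaps."""
    m, n = len(p), len(q)
    neg = float("-inf")
    best = 0.0
    h_prev = [0.0] * (n + 1)
    e_prev = [neg] * (n + 1)
    for i in range(1, m + 1):
        h_cur = [0.0] * (n + 1)
        e_cur = [neg] * (n + 1)
        f = neg
        for j in range(1, n + 1):
            e_cur[j] = max(h_prev[j] - GAP_OPEN - GAP_EXTEND, e_prev[j] - GAP_EXTEND)
            f = max(h_cur[j - 1] - GAP_OPEN - GAP_EXTEND, f - GAP_EXTEND)
            diag = h_prev[j - 1] + _BLOSUM62[p[i - 1], q[j - 1]]
            h_cur[j] = max(0.0, diag, e_cur[j], f)
            best = max(best, h_cur[j])
        h_prev, e_prev = h_cur, e_cur
    return int(best)


def n50_bruteforce(lengths: list[int]) -> int:
    """Smallest contig in the descending prefix reaching half the total."""
    ordered = sorted(lengths, reverse=True)
    total = sum(ordered)
    acc = 0
    for ln in ordered:
        acc += ln
        if 2 * acc >= total:
            return ln
    return ordered[-1]


def global_identity(a: str, b: str) -> float:
    """Identity (matches / alignment columns) of one full-length global
    alignment of two sequences (edit-distance optimal path)."""
    res = edlib.align(a, b, mode="NW", task="path")
    matches = columns = 0
    for count, op in _CIG.findall(res["cigar"]):
        columns += int(count)
        if op == "=":
            matches += int(count)
    return matches / columns


def canonical_kmers_naive(seq: str, k: int) -> set[str]:
    """String-space canonical k-mer enumeration."""
    comp = str.maketrans("ACGT", "TGCA")
    out = set()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if set(w) - set("ACGT"):
            continue
        rc = w.translate(comp)[::-1]
        out.add(min(w, rc))
    return out
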