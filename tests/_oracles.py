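"""Independent brute-force oracles used by the tests.

These are deliberately naive (full dynamic programming, exhaustive scans,
quadratic set comparisons, closed-form statistics) and share no code with
the implementation paths they check.
"""

from __future__ import annotations

import math

import numpy as np

NEG = float("-inf")
_COMP = str.maketrans("ACGT", "TGCA")

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
    "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def dp_overlap_score(target: str, query: str, match=2.0, mismatch=-3.0,
                     open_=-8.0, ext=-1.0) -> float:
    """Full Gotoh DP, free end gaps; gap of length k costs open + (k-1)*ext."""
    n, m = len(target), len(query)
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    M[:, 0] = 0.0
    M[0, :] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if target[i - 1] == query[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1],
                          Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] + open_, Iy[i - 1, j] + open_,
                           Ix[i - 1, j] + ext)
            Iy[i, j] = max(M[i, j - 1] + open_, Ix[i, j - 1] + open_,
                           Iy[i, j - 1] + ext)
    best = NEG
    for i in range(n + 1):
        best = max(best, M[i, m], Ix[i, m], Iy[i, m])
    for j in range(m + 1):
        best = max(best, M[n, j], Ix[n, j], Iy[n, j])
    return best


def naive_site_scan(genome: dict[str, str], spacer: str, pam: str,
                    max_mm: int) -> set[tuple]:
    """Exhaustive per-position Hamming scan; returns {(chrom, start, strand, mm)}."""
    k, pl = len(spacer), len(pam)
    hits = set()
    for chrom, seq in genome.items():
        L = len(seq)
        for strand, s in (("+", seq), ("-", rc(seq))):
            for i in range(L - k - pl + 1):
                d = 0
                for a, b in zip(s[i:i + k], spacer):
                    if a != b:
                        d += 1
                        if d > max_mm:
                            break
                else:
                    if all(c in IUPAC_SETS[p] for c, p in
                           zip(s[i + k:i + k + pl], pam)):
                        start = i if strand == "+" else L - i - k
                        hits.add((chrom, start, strand, d))
    return hits


def naive_interval_overlap(points: list[tuple[str, int]],
                           intervals: list[tuple[str, int, int]]) -> int:
    """Count points falling in any half-open interval; O(n*m)."""
    n = 0
    for chrom, p in points:
        if any(c == chrom and lo <= p < hi for c, lo, hi in intervals):
            n += 1
    return n


def welch_t(x, y) -> float:
    """Closed-form Welch t statistic."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    return (x.mean() - y.mean()) / math.sqrt(vx + vy)


def entropy_bits(freqs) -> float:
    return -sum(f * math.log2(f) for f in freqs if f > 0)
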