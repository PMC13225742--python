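"""sgRNA-dependent off-target site prediction by exhaustive mismatch scan.

A desk-scale equivalent of spacer-similarity off-target predictors: every
genomic 20-mer (both strands) within a mismatch budget of the spacer and
followed 3' by a PAM match is enumerated, and called SNVs can be intersected
with the predicted loci (plus flanks) to ask whether de novo variants are
explained by guide similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from numpy.lib.stride_tricks import sliding_window_view

from .goti import SNVCallSet, encode_seq
from .sites import IUPAC, revcomp


@dataclass(frozen=True)
class PredictedSite:
    """A predicted protospacer locus. ``start``/``end`` are 0-based half-open
    forward-strand coordinates of the 20-mer footprint (PAM excluded)."""

    chrom: str
    start: int
    end: int
    strand: str
    mismatches: int
    matched_seq: str  # protospacer-strand sequence at the locus


def _pam_lookup(pam: str) -> list[np.ndarray]:
    tables = []
    for ch in pam.upper():
        t = np.zeros(256, dtype=bool)
        for b in IUPAC[ch]:
            t["ACGT".index(b)] = True
        tables.append(t)
    return tables


def _scan_strand(seq: str, spacer: str, pam: str, max_mm: int):
    """Yield (start0_on_this_strand, mismatches, matched) for one strand."""
    L, k, pl = len(seq), len(spacer), len(pam)
    if L < k + pl:
        return
    codes = encode_seq(seq)
    spacer_codes = encode_seq(spacer)
    windows = sliding_window_view(codes, k)[: L - k - pl + 1]
    mm = (windows != spacer_codes).sum(axis=1)
    ok = mm <= max_mm
    pam_tables = _pam_lookup(pam)
    for j, table in enumerate(pam_tables):
        col = codes[k + j: k + j + len(windows)]
        ok &= np.where(col < 4, table[col], False)
    for i in np.flatnonzero(ok):
        yield int(i), int(mm[i]), seq[i:i + k]


def enumerate_predicted_sites(genome: dict[str, str], spacer: str,
                              pam: str = "NGG",
                              max_mm: int = 3) -> list[PredictedSite]:
    """All loci with <= ``max_mm`` spacer mismatches and a 3'-adjacent PAM.

    Both strands are scanned; results are sorted by (mismatches, chrom,
    start, strand).  The spacer must be 20 nt.
    """
    if len(spacer) != 20:
        raise ValueError("spacer must be a 20-mer")
    spacer = spacer.upper()
    sites: list[PredictedSite] = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        L = len(seq)
        for i, mm, matched in _scan_strand(seq, spacer, pam, max_mm):
            sites.append(PredictedSite(chrom, i, i + 20, "+", mm, matched))
        for i, mm, matched in _scan_strand(revcomp(seq), spacer, pam, max_mm):
            # position i on the reverse strand -> forward footprint
            sites.append(PredictedSite(chrom, L - i - 20, L - i, "-", mm,
                                       matched))
    sites.sort(key=lambda s: (s.mismatches, s.chrom, s.start, s.strand))
    return sites


def sites_to_bed(sites: Sequence[PredictedSite], path: str | Path) -> None:
    pd.DataFrame([(s.chrom, s.start, s.end, s.matched_seq, s.mismatches,
                   s.strand) for s in sites],
                 columns=["chrom", "start", "end", "name", "score", "strand"]
                 ).to_csv(path, sep="\t", index=False, header=False)


def sites_from_bed(path: str | Path) -> list[PredictedSite]:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score",
                            "strand"], dtype={"chrom": str})
    return [PredictedSite(str(r.chrom), int(r.start), int(r.end),
                          str(r.strand), int(r.score), str(r.name))
            for r in df.itertuples(index=False)]


@dataclass
class PredictedOverlap:
    n_snvs: int
    n_overlapping: int
    pairs: list[tuple]  # (SNVCall, PredictedSite)

    @property
    def fraction(self) -> float:
        return self.n_overlapping / self.n_snvs if self.n_snvs else np.nan


def overlap_with_predicted(snvs: SNVCallSet, sites: Sequence[PredictedSite],
                           flank_bp: int = 25) -> PredictedOverlap:
    """SNVs falling within ``flank_bp`` of any predicted site footprint.

    An SNV at 1-based position p overlaps a site if p-1 (0-based) lies in
    [start - flank_bp, end + flank_bp).
    """
    trees: dict[str, IntervalTree] = {}
    for s in sites:
        trees.setdefault(s.chrom, IntervalTree()).addi(
            s.start - flank_bp, s.end + flank_bp, s)
    pairs = []
    n_overlapping = 0
    for call in snvs:
        tree = trees.get(call.chrom)
        hits = sorted(tree[call.pos - 1], key=lambda iv: iv.begin) if tree else []
        if hits:
            n_overlapping += 1
            for iv in hits:
                pairs.append((call, iv.data))
    return PredictedOverlap(n_snvs=len(snvs), n_overlapping=n_overlapping,
                            pairs=pairs)
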