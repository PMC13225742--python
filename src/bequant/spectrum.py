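"""Substitution spectra, flanking-context matrices and logo information content.

Deaminase-driven off-targets leave a characteristic signature: adenine
deamination reads out as A-to-G on the deaminated strand and T-to-C on the
opposite strand, with a preference for a 5' T neighbour (the TA motif on DNA,
UA on RNA).  This module classifies SNV sets into the 12 directed
substitution classes, builds strand-standardised flanking-context matrices
(every event oriented so position 0 is the deaminated A), and computes
per-position information content in bits for logo rendering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .goti import SNVCallSet
from .sites import DNA_BASES, revcomp

#: the 12 directed single-base substitution classes
SUBSTITUTION_CLASSES = tuple(f"{r}>{a}" for r in DNA_BASES for a in DNA_BASES
                             if r != a)

_BASE_INDEX = {b: i for i, b in enumerate(DNA_BASES)}


@dataclass
class SpectrumSummary:
    """Counts over the 12 directed substitution classes."""

    counts: pd.Series        # indexed by SUBSTITUTION_CLASSES
    n_excluded: int = 0      # calls with ambiguous/invalid bases

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def frac_AG_TC(self) -> float:
        """Combined fraction of A>G plus T>C (adenine-deamination signature)."""
        n = self.n_total
        return (self.counts["A>G"] + self.counts["T>C"]) / n if n else np.nan

    @property
    def frac_CT_GA(self) -> float:
        """Combined fraction of C>T plus G>A (cytosine-deamination signature)."""
        n = self.n_total
        return (self.counts["C>T"] + self.counts["G>A"]) / n if n else np.nan

    def fractions(self) -> pd.Series:
        n = self.n_total
        return self.counts / n if n else self.counts * np.nan

    def __add__(self, other: "SpectrumSummary") -> "SpectrumSummary":
        return SpectrumSummary(self.counts + other.counts,
                               self.n_excluded + other.n_excluded)


def _iter_calls(snvs) -> Iterable[tuple[str, int, str, str]]:
    if isinstance(snvs, SNVCallSet):
        for c in snvs:
            yield c.chrom, c.pos, c.ref, c.alt
    elif isinstance(snvs, pd.DataFrame):
        for r in snvs.itertuples(index=False):
            yield str(r.chrom), int(r.pos), str(r.ref), str(r.alt)
    else:
        for chrom, pos, ref, alt in snvs:
            yield chrom, pos, ref, alt


def mutation_spectrum(snvs) -> SpectrumSummary:
    """Classify calls into the 12 directed substitution classes.

    Accepts an :class:`~bequant.goti.SNVCallSet`, a DataFrame with
    chrom/pos/ref/alt columns, or an iterable of (chrom, pos, ref, alt).
    Calls with ambiguous or identical ref/alt bases are excluded and counted.
    """
    counts = pd.Series(0, index=list(SUBSTITUTION_CLASSES), dtype=int)
    n_excluded = 0
    for _, _, ref, alt in _iter_calls(snvs):
        ref, alt = ref.upper(), alt.upper()
        key = f"{ref}>{alt}"
        if ref in DNA_BASES and alt in DNA_BASES and ref != alt:
            counts[key] += 1
        else:
            n_excluded += 1
    return SpectrumSummary(counts, n_excluded)


@dataclass
class ContextMatrix:
    """Strand-standardised flanking-base counts around the deaminated A.

    ``base_counts[p, b]`` counts base ``b`` (A,C,G,T order) at offset
    ``p - flank`` from the mutated base, after orienting every A>G event on
    the forward strand and every T>C event on the reverse complement so the
    deaminated A always sits at offset 0.
    """

    flank: int
    base_counts: np.ndarray          # (2*flank+1, 4) int
    n_events: int
    n_excluded_class: int = 0        # non-A>G/T>C events
    n_skipped_edge: int = 0          # flank beyond contig end
    pseudocount: float = 0.5
    mode: str = "dna"

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)

    @property
    def base_labels(self) -> tuple[str, ...]:
        return ("A", "C", "G", "U") if self.mode == "rna" else ("A", "C", "G", "T")

    def frequencies(self, pseudocount: float | None = None) -> np.ndarray:
        """Per-position base frequencies with the stated pseudocount."""
        pc = self.pseudocount if pseudocount is None else pseudocount
        padded = self.base_counts + pc
        return padded / padded.sum(axis=1, keepdims=True)

    def information_content(self, pseudocount: float | None = None) -> np.ndarray:
        """Per-position IC in bits: 2 - Shannon entropy of base frequencies."""
        f = self.frequencies(pseudocount)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.where(f > 0, f * np.log2(f), 0.0).sum(axis=1)
        return 2.0 - h

    @property
    def ic(self) -> np.ndarray:
        return self.information_content()

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.base_counts, columns=list(self.base_labels))
        df.insert(0, "offset", self.offsets)
        df["ic"] = self.ic
        return df


def _get_context(reference: Mapping[str, str], chrom: str, pos: int,
                 flank: int) -> str | None:
    """Forward-strand window of width 2*flank+1 centred on 1-based ``pos``."""
    seq = reference[chrom]
    lo, hi = pos - 1 - flank, pos + flank
    if lo < 0 or hi > len(seq):
        return None
    return str(seq[lo:hi]).upper()


def oriented_contexts(snvs, reference: Mapping[str, str], flank: int = 3):
    """Yield deaminated-strand contexts for A>G/T>C events.

    A>G events are read on the forward strand; T>C events are
    reverse-complemented so that offset 0 is always the deaminated A.
    Returns (contexts, n_excluded_class, n_skipped_edge).
    """
    contexts: list[str] = []
    n_excluded = n_skipped = 0
    for chrom, pos, ref, alt in _iter_calls(snvs):
        ref, alt = ref.upper(), alt.upper()
        if (ref, alt) == ("A", "G"):
            ctx = _get_context(reference, chrom, pos, flank)
        elif (ref, alt) == ("T", "C"):
            ctx = _get_context(reference, chrom, pos, flank)
            ctx = revcomp(ctx) if ctx is not None else None
        else:
            n_excluded += 1
            continue
        if ctx is None or len(ctx) != 2 * flank + 1:
            n_skipped += 1
            continue
        contexts.append(ctx)
    return contexts, n_excluded, n_skipped


def context_logo(snvs, reference: Mapping[str, str], flank: int = 3,
                 mode: str = "dna", pseudocount: float = 0.5) -> ContextMatrix:
    """Flanking-context matrix and information content around oriented events.

    ``reference`` maps contig name to sequence (a dict or ``pyfaidx.Fasta``).
    Only A>G and T>C events contribute (others are excluded and counted);
    events whose flank extends past a contig end are skipped and counted.
    In ``rna`` mode base labels report U for T; the orientation logic is
    identical because calls are expected on the transcript strand.
    """
    if mode not in ("dna", "rna"):
        raise ValueError("mode must be 'dna' or 'rna'")
    contexts, n_excluded, n_skipped = oriented_contexts(snvs, reference, flank)
    counts = np.zeros((2 * flank + 1, 4), dtype=int)
    for ctx in contexts:
        for p, b in enumerate(ctx):
            if b in _BASE_INDEX:
                counts[p, _BASE_INDEX[b]] += 1
    return ContextMatrix(flank=flank, base_counts=counts,
                         n_events=len(contexts),
                         n_excluded_class=n_excluded,
                         n_skipped_edge=n_skipped,
                         pseudocount=pseudocount, mode=mode)


def ta_context_fraction(snvs, reference: Mapping[str, str]) -> float:
    """Fraction of oriented A>G/T>C events whose 5' neighbour is T.

    This is the TA-motif (UA on RNA) fraction: the base at offset -1 on the
    deaminated-A strand.  NaN if no event has a usable context.
    """
    contexts, _, _ = oriented_contexts(snvs, reference, flank=1)
    if not contexts:
        return np.nan
    return sum(ctx[0] == "T" for ctx in contexts) / len(contexts)


def plot_logo(matrix: ContextMatrix, ax=None):
    """Render a simple IC-scaled letter-height logo with matplotlib."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.6 * (2 * matrix.flank + 1), 2.5))
    freqs = matrix.frequencies()
    ic = matrix.ic
    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e",
              "T": "#d62728", "U": "#d62728"}
    for p, offset in enumerate(matrix.offsets):
        heights = freqs[p] * ic[p]
        order = np.argsort(heights)
        y = 0.0
        for b in order:
            label = matrix.base_labels[b]
            if heights[b] > 1e-3:
                ax.text(offset, y + heights[b] / 2, label, ha="center",
                        va="center", fontsize=9 + 8 * heights[b],
                        color=colors[label], fontweight="bold")
            y += heights[b]
    ax.set_xlim(-matrix.flank - 0.5, matrix.flank + 0.5)
    ax.set_ylim(0, 2)
    ax.set_xticks(matrix.offsets)
    ax.set_ylabel("bits")
    ax.set_xlabel("position relative to deaminated A")
    return ax
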