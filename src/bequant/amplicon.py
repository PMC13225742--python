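"""Per-position base-editing quantification for amplicon deep sequencing.

Given reads aligned to a protospacer site, this module builds per-position
substitution count matrices and the derived metrics an adenine-base-editor
characterisation needs:

* per-position A-to-G efficiency (``a2g``) and undesired C-editing frequency
  (``c_edit``) among substitution-only reads,
* the editing window (positions at >= 30% of the peak mean efficiency),
* bystander/purity ratios (A2/A5, A8/A5, C5/A5),
* perfect-edit and dual-edit read fractions.

By default indel-containing reads are excluded from the substitution
denominators and reported separately as ``indel_fraction``; pass
``include_indel_reads=True`` to :func:`quantify_site` to put them back in the
denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .align import AlignedRead
from .sites import DNA_BASES, ProtospacerSite

_BASE_INDEX = {b: i for i, b in enumerate(DNA_BASES)}


@dataclass
class EditingProfile:
    """Per-position substitution counts and frequencies for one site.

    Attributes
    ----------
    site_id : str
    ref_bases : str
        Protospacer reference bases (protospacer strand), positions 1..L.
    n_reads : int
        All aligned reads (incl. indel-containing).
    n_indel_reads : int
        Reads with a gap overlapping the protospacer +/- 10 bp.
    n_rejected : int
        Reads rejected before alignment (non-ACGTN / too short).
    counts : int array, shape (L, 4, 4)
        ``counts[p, r, o]``: substitution-only reads with reference base ``r``
        and observed base ``o`` at protospacer position p+1.  Only the row of
        the actual reference base is populated.
    """

    site_id: str
    ref_bases: str
    n_reads: int
    n_indel_reads: int
    counts: np.ndarray
    n_rejected: int = 0

    # -- derived quantities -------------------------------------------------

    @property
    def proto_len(self) -> int:
        return len(self.ref_bases)

    @property
    def coverage(self) -> np.ndarray:
        """Substitution-only reads with an unambiguous base at each position."""
        return self.counts.sum(axis=(1, 2))

    @property
    def a2g(self) -> np.ndarray:
        """A-to-G frequency per position; NaN where ref is not A or no coverage."""
        out = np.full(self.proto_len, np.nan)
        cov = self.coverage
        for p, ref in enumerate(self.ref_bases):
            if ref == "A" and cov[p] > 0:
                out[p] = self.counts[p, _BASE_INDEX["A"], _BASE_INDEX["G"]] / cov[p]
        return out

    @property
    def c_edit(self) -> np.ndarray:
        """C-to-(T/G/A) frequency per position; NaN where ref is not C."""
        out = np.full(self.proto_len, np.nan)
        cov = self.coverage
        ci = _BASE_INDEX["C"]
        for p, ref in enumerate(self.ref_bases):
            if ref == "C" and cov[p] > 0:
                out[p] = (cov[p] - self.counts[p, ci, ci]) / cov[p]
        return out

    @property
    def indel_fraction(self) -> float:
        return self.n_indel_reads / self.n_reads if self.n_reads else np.nan

    @property
    def flagged_positions(self) -> list[int]:
        """1-based positions with zero substitution-only coverage."""
        return [p + 1 for p in range(self.proto_len) if self.coverage[p] == 0]

    def count_matrix(self, position: int) -> np.ndarray:
        """4x4 (ref x observed) count matrix at a 1-based position."""
        return self.counts[position - 1]

    def to_dataframe(self) -> pd.DataFrame:
        a2g, c_edit, cov = self.a2g, self.c_edit, self.coverage
        return pd.DataFrame({
            "position": np.arange(1, self.proto_len + 1),
            "ref_base": list(self.ref_bases),
            "n": cov,
            "a2g": a2g,
            "c_edit": c_edit,
        })


def quantify_site(aligned_reads: Sequence[AlignedRead], site: ProtospacerSite,
                  include_indel_reads: bool = False,
                  n_rejected: int = 0) -> EditingProfile:
    """Tabulate per-position substitution counts for one site.

    Indel-containing reads count toward ``n_reads`` and ``indel_fraction``
    but are excluded from the substitution matrices unless
    ``include_indel_reads`` is set.  ``N`` bases never count as edits (they
    are dropped from the position's denominator).
    """
    if len(aligned_reads) == 0:
        raise ValueError(f"{site.site_id}: no aligned reads")
    L = site.proto_len
    counts = np.zeros((L, 4, 4), dtype=np.int64)
    ref_idx = np.array([_BASE_INDEX[b] for b in site.proto_ref_bases])
    n_indel = 0
    for read in aligned_reads:
        if read.has_indel:
            n_indel += 1
            if not include_indel_reads:
                continue
        for p in range(L):
            b = read.bases[p]
            if b in _BASE_INDEX:
                counts[p, ref_idx[p], _BASE_INDEX[b]] += 1
    return EditingProfile(site_id=site.site_id, ref_bases=site.proto_ref_bases,
                          n_reads=len(aligned_reads), n_indel_reads=n_indel,
                          counts=counts, n_rejected=n_rejected)


@dataclass
class MeanProfile:
    """Across-site unweighted mean efficiencies, per protospacer position."""

    proto_len: int
    mean_a2g: np.ndarray    # NaN where no site has an A
    n_sites_a: np.ndarray   # sites contributing an A at each position
    mean_c_edit: np.ndarray
    n_sites_c: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": np.arange(1, self.proto_len + 1),
            "mean_a2g": self.mean_a2g,
            "n_sites_a": self.n_sites_a,
            "mean_c_edit": self.mean_c_edit,
            "n_sites_c": self.n_sites_c,
        })


def aggregate_mean_profile(profiles: Sequence[EditingProfile]) -> MeanProfile:
    """Unweighted mean of per-site frequencies at each protospacer position.

    A site contributes to a position's A-to-G mean only if its reference base
    there is A (and analogously C for the C-edit mean); positions with no
    contributing site are NaN.
    """
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    L = profiles[0].proto_len
    if any(p.proto_len != L for p in profiles):
        raise ValueError("profiles have differing protospacer lengths")
    a_stack = np.vstack([p.a2g for p in profiles])
    c_stack = np.vstack([p.c_edit for p in profiles])
    n_a = np.sum(~np.isnan(a_stack), axis=0)
    n_c = np.sum(~np.isnan(c_stack), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean_a = np.nanmean(a_stack, axis=0)
        mean_c = np.nanmean(c_stack, axis=0)
    return MeanProfile(proto_len=L, mean_a2g=mean_a, n_sites_a=n_a,
                       mean_c_edit=mean_c, n_sites_c=n_c)


@dataclass
class WindowResult:
    """Editing window under the fraction-of-peak rule."""

    threshold_frac: float
    peak_position: int | None
    peak_value: float
    window_positions: tuple[int, ...]

    def contiguous_window(self) -> tuple[int, ...]:
        """Largest contiguous run of window positions containing the peak.

        Display helper: editing windows are conventionally reported as
        contiguous ranges (e.g. A2-A10) even though the threshold rule alone
        does not enforce contiguity.
        """
        if self.peak_position is None:
            return ()
        in_window = set(self.window_positions)
        lo = hi = self.peak_position
        while lo - 1 in in_window:
            lo -= 1
        while hi + 1 in in_window:
            hi += 1
        return tuple(range(lo, hi + 1))


def _profile_vector(profile) -> np.ndarray:
    if isinstance(profile, EditingProfile):
        return profile.a2g
    if isinstance(profile, MeanProfile):
        return profile.mean_a2g
    return np.asarray(profile, dtype=float)


def editing_window(mean_profile, threshold_frac: float = 0.30) -> WindowResult:
    """Positions whose mean efficiency is >= ``threshold_frac`` of the peak.

    The peak is the maximum of the profile (ties broken toward the smallest
    position index).  The window is reported as the full set of
    threshold-passing positions; use
    :meth:`WindowResult.contiguous_window` for the conventional contiguous
    range containing the peak.  An all-zero profile yields an empty window.
    """
    values = _profile_vector(mean_profile)
    if np.all(np.isnan(values)):
        raise ValueError("profile has no non-null positions")
    peak_idx = int(np.nanargmax(values))  # first occurrence on ties
    peak = float(values[peak_idx])
    if peak <= 0:
        return WindowResult(threshold_frac, None, 0.0, ())
    threshold = threshold_frac * peak
    window = tuple(int(i + 1) for i in range(len(values))
                   if not np.isnan(values[i]) and values[i] >= threshold)
    return WindowResult(threshold_frac, peak_idx + 1, peak, window)


@dataclass
class SiteEditingSummary:
    """Site-level purity and outcome metrics.

    Ratios compare bystander editing at A2/A8 (and undesired C editing at C5)
    to the desired peak A5 editing; they are NaN when the denominator A5
    efficiency is zero or undefined.
    """

    a2_over_a5: float = np.nan
    a8_over_a5: float = np.nan
    c5_over_a5: float = np.nan
    perfect_fraction: float = np.nan
    dual_fraction: float = np.nan
    indel_fraction: float = np.nan
    c_edit_fraction: float = np.nan

    @property
    def bystander_sum(self) -> float:
        return self.a2_over_a5 + self.a8_over_a5

    def to_dict(self) -> dict:
        return {
            "a2_over_a5": self.a2_over_a5,
            "a8_over_a5": self.a8_over_a5,
            "bystander_sum": self.bystander_sum,
            "c5_over_a5": self.c5_over_a5,
            "perfect_fraction": self.perfect_fraction,
            "dual_fraction": self.dual_fraction,
            "indel_fraction": self.indel_fraction,
            "c_edit_fraction": self.c_edit_fraction,
        }


def purity_metrics(profile, peak_position: int = 5,
                   bystander_positions: tuple[int, int] = (2, 8),
                   c_position: int = 5) -> SiteEditingSummary:
    """Bystander and C-editing ratios relative to the peak position.

    Accepts a single-site :class:`EditingProfile` or an across-site
    :class:`MeanProfile`.  For a single site whose ``c_position`` base is not
    a C, the C-edit numerator is 0 (there is no C to edit); for a mean
    profile it is the mean C-edit frequency over sites that do have a C
    there.  Ratios are NaN (with a warning) when A5 editing is zero.
    """
    if isinstance(profile, MeanProfile):
        a2g = profile.mean_a2g
        c_num = profile.mean_c_edit[c_position - 1]
        if np.isnan(c_num) and not np.isnan(a2g[peak_position - 1]):
            c_num = 0.0
    else:
        a2g = profile.a2g
        ce = profile.c_edit[c_position - 1]
        c_num = ce if not np.isnan(ce) else 0.0

    a5 = a2g[peak_position - 1]
    summary = SiteEditingSummary()
    if isinstance(profile, EditingProfile):
        summary.indel_fraction = profile.indel_fraction
        summary.c_edit_fraction = c_edit_fraction(profile)
    if np.isnan(a5) or a5 == 0:
        warnings.warn(f"A{peak_position} efficiency is zero or undefined; "
                      "purity ratios are NaN")
        return summary
    p_lo, p_hi = bystander_positions
    summary.a2_over_a5 = float(a2g[p_lo - 1] / a5)
    summary.a8_over_a5 = float(a2g[p_hi - 1] / a5)
    summary.c5_over_a5 = float(c_num / a5)
    return summary


def c_edit_fraction(profile: EditingProfile) -> float:
    """Site-level undesired C editing: max per-position C-edit frequency.

    Zero when the protospacer contains no C.
    """
    ce = profile.c_edit
    if np.all(np.isnan(ce)):
        return 0.0
    return float(np.nanmax(ce))


def perfect_and_dual_fractions(aligned_reads: Sequence[AlignedRead],
                               site: ProtospacerSite) -> tuple[float, float]:
    """Fractions of reads with a perfect edit and with the dual intended edit.

    A *perfect* read carries a G at every intended position, the reference
    base at every other protospacer position, and no indel.  A *dual* read
    (defined when the site has two or more intended positions) carries a G at
    all intended positions regardless of bystanders; indel reads cannot
    qualify because their per-position bases are undefined.  Both fractions
    are over all aligned reads.
    """
    if not site.intended_positions:
        raise ValueError(f"{site.site_id}: no intended positions configured")
    ref = site.proto_ref_bases
    intended = set(site.intended_positions)
    n_perfect = n_dual = 0
    for read in aligned_reads:
        if read.has_indel:
            continue
        bases = read.bases
        if all(bases[p - 1] == "G" for p in intended):
            n_dual += 1
            if all(bases[p - 1] == ref[p - 1]
                   for p in range(1, site.proto_len + 1) if p not in intended):
                n_perfect += 1
    n = len(aligned_reads)
    perfect = n_perfect / n if n else np.nan
    dual = (n_dual / n if n else np.nan) if len(intended) >= 2 else np.nan
    return perfect, dual


def summarize_site(aligned_reads: Sequence[AlignedRead], site: ProtospacerSite,
                   **purity_kwargs) -> SiteEditingSummary:
    """Full site summary: purity ratios plus perfect/dual/indel fractions."""
    profile = quantify_site(aligned_reads, site)
    summary = purity_metrics(profile, **purity_kwargs)
    if site.intended_positions:
        perfect, dual = perfect_and_dual_fractions(aligned_reads, site)
        summary.perfect_fraction = perfect
        summary.dual_fraction = dual
    return summary
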