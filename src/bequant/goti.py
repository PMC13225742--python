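"""Paired edited-vs-control de novo SNV analysis (GOTI-style).

In a GOTI experiment one blastomere of a two-cell embryo is edited and
lineage-marked; edited and non-edited progeny from the same embryo are sorted
and whole-genome sequenced, and de novo SNVs are called in the edited sample
with the non-edited sample as the matched reference.  This module provides a
desk-scale equivalent of that downstream analysis: a threshold-based paired
caller run under three profiles (emulating the three independent algorithms
used in practice), their consensus, replicate-overlap tables, and group
statistics (mean, SEM, fold over control, Welch t-tests).

Coordinates are 1-based for pileups and SNVs; BED-style intervals elsewhere
are 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sites import DNA_BASES

_BASE_INDEX = {b: i for i, b in enumerate(DNA_BASES)}
_BASE_CODES = np.frombuffer(DNA_BASES.encode(), dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A,C,G,T -> 0..3; anything else 255)."""
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(DNA_BASES):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


class Pileups:
    """Per-position base counts for one sample over one or more contigs.

    For each contig: reference base codes (uint8), total depth (int32) and a
    (L, 4) matrix of A/C/G/T observation counts.  Positions are implicit
    1..L.  Base counts may sum to less than depth (N/low-quality reads are
    excluded from the counts).
    """

    def __init__(self, ref: dict[str, np.ndarray], depth: dict[str, np.ndarray],
                 counts: dict[str, np.ndarray]):
        self.ref = ref
        self.depth = depth
        self.counts = counts

    @property
    def chroms(self) -> list[str]:
        return list(self.ref)

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for chrom in self.chroms:
            L = len(self.ref[chrom])
            frames.append(pd.DataFrame({
                "chrom": chrom,
                "pos": np.arange(1, L + 1),
                "ref": [DNA_BASES[c] for c in self.ref[chrom]],
                "depth": self.depth[chrom],
                "nA": self.counts[chrom][:, 0],
                "nC": self.counts[chrom][:, 1],
                "nG": self.counts[chrom][:, 2],
                "nT": self.counts[chrom][:, 3],
            }))
        return pd.concat(frames, ignore_index=True)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Pileups":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        ref, depth, counts = {}, {}, {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("pos")
            if not np.array_equal(sub["pos"].to_numpy(),
                                  np.arange(1, len(sub) + 1)):
                raise ValueError(f"{chrom}: pileup positions must be 1..L")
            ref[chrom] = np.array([_BASE_INDEX[b] for b in sub["ref"]],
                                  dtype=np.uint8)
            depth[chrom] = sub["depth"].to_numpy(np.int32)
            counts[chrom] = sub[["nA", "nC", "nG", "nT"]].to_numpy(np.int32)
        return cls(ref, depth, counts)


@dataclass(frozen=True)
class CallerProfile:
    """Threshold profile for the paired de novo caller."""

    name: str
    min_depth: int = 10
    min_alt_depth: int = 3
    min_af: float = 0.10
    max_control_alt: int = 0

    def __post_init__(self):
        if min(self.min_depth, self.min_alt_depth, self.max_control_alt) < 0 \
                or self.min_af < 0:
            raise ValueError("caller thresholds must be nonnegative")


#: the three caller emulations whose intersection forms the consensus
CALLER_PROFILES = {
    "strict": CallerProfile("strict", min_depth=10, min_alt_depth=5,
                            min_af=0.15, max_control_alt=0),
    "default": CallerProfile("default", min_depth=10, min_alt_depth=3,
                             min_af=0.10, max_control_alt=0),
    "sensitive": CallerProfile("sensitive", min_depth=10, min_alt_depth=2,
                               min_af=0.05, max_control_alt=1),
}


@dataclass(frozen=True)
class SNVCall:
    chrom: str
    pos: int          # 1-based
    ref: str
    alt: str
    alt_depth: int
    depth: int
    af: float
    control_alt_depth: int

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)


class SNVCallSet:
    """A named collection of SNV calls keyed by (chrom, pos, alt)."""

    def __init__(self, calls: Iterable[SNVCall] = (), name: str = ""):
        self.name = name
        self._calls: dict[tuple, SNVCall] = {}
        for c in calls:
            self._calls[c.key] = c

    def __len__(self) -> int:
        return len(self._calls)

    def __iter__(self):
        return iter(self._calls.values())

    def __contains__(self, key) -> bool:
        return key in self._calls

    @property
    def keys(self) -> set[tuple]:
        return set(self._calls)

    def get(self, key) -> SNVCall:
        return self._calls[key]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(c.chrom, c.pos, c.ref, c.alt, c.alt_depth, c.depth, c.af,
                 c.control_alt_depth) for c in self]
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                           "alt_depth", "depth", "af",
                                           "control_alt_depth"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, name: str = "") -> "SNVCallSet":
        calls = [SNVCall(str(r.chrom), int(r.pos), str(r.ref), str(r.alt),
                         int(getattr(r, "alt_depth", 0)),
                         int(getattr(r, "depth", 0)),
                         float(getattr(r, "af", np.nan)),
                         int(getattr(r, "control_alt_depth", 0)))
                 for r in df.itertuples(index=False)]
        return cls(calls, name=name)

    @classmethod
    def from_tsv(cls, path: str | Path, name: str = "") -> "SNVCallSet":
        return cls.from_dataframe(pd.read_csv(path, sep="\t",
                                              dtype={"chrom": str}), name=name)


def call_denovo_snvs(edited: Pileups, control: Pileups,
                     profile: CallerProfile) -> SNVCallSet:
    """Call SNVs present in the edited sample and absent from the control.

    A site/alt is called iff depth >= ``min_depth`` in both samples, the
    edited sample has >= ``min_alt_depth`` alt reads at allele fraction
    >= ``min_af``, and the control carries <= ``max_control_alt`` alt reads
    (germline exclusion).  Reference bases must agree between the samples.
    """
    calls: list[SNVCall] = []
    for chrom in edited.chroms:
        if chrom not in control.ref:
            raise ValueError(f"control lacks contig {chrom}")
        ref = edited.ref[chrom]
        if not np.array_equal(ref, control.ref[chrom]):
            raise ValueError(f"{chrom}: reference mismatch between samples")
        de, dc = edited.depth[chrom], control.depth[chrom]
        ce, cc = edited.counts[chrom], control.counts[chrom]
        depth_ok = (de >= profile.min_depth) & (dc >= profile.min_depth)
        with np.errstate(divide="ignore", invalid="ignore"):
            af = np.where(de[:, None] > 0, ce / np.maximum(de, 1)[:, None], 0.0)
        for b in range(4):
            mask = (ref != b) & depth_ok \
                & (ce[:, b] >= profile.min_alt_depth) \
                & (af[:, b] >= profile.min_af) \
                & (cc[:, b] <= profile.max_control_alt)
            for i in np.flatnonzero(mask):
                calls.append(SNVCall(
                    chrom=chrom, pos=int(i) + 1, ref=DNA_BASES[ref[i]],
                    alt=DNA_BASES[b], alt_depth=int(ce[i, b]),
                    depth=int(de[i]), af=float(af[i, b]),
                    control_alt_depth=int(cc[i, b])))
    return SNVCallSet(calls, name=profile.name)


def consensus_intersection(callsets: Sequence[SNVCallSet],
                           mode: str = "intersection") -> SNVCallSet:
    """Consensus of exactly three call sets over the same sample pair.

    ``intersection`` (the GOTI convention) keeps calls present in all three
    sets; ``union`` keeps calls present in any.  Call records (af, depths)
    are taken from the first set that contains the call.
    """
    if len(callsets) != 3:
        raise ValueError("consensus requires exactly three call sets")
    if mode == "intersection":
        keys = set.intersection(*(s.keys for s in callsets))
    elif mode == "union":
        keys = set.union(*(s.keys for s in callsets))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    calls = []
    for key in sorted(keys):  # stable across processes (set order is not)
        for s in callsets:
            if key in s:
                calls.append(s.get(key))
                break
    return SNVCallSet(calls, name="consensus")


@dataclass
class OverlapResult:
    """Venn-style overlap of replicate SNV sets."""

    labels: tuple[str, ...]
    exclusive_counts: dict[frozenset, int]   # membership pattern -> count
    pairwise: pd.DataFrame                   # shared counts, labels x labels
    all_shared: int

    def shared(self, *labels: str) -> int:
        """Count of calls present in at least the given sets."""
        want = set(labels)
        return sum(n for pattern, n in self.exclusive_counts.items()
                   if want <= pattern)


def replicate_overlap(snv_sets: Sequence[SNVCallSet],
                      labels: Sequence[str] | None = None) -> OverlapResult:
    """Full overlap table for 2-4 replicate SNV sets keyed by (chrom,pos,alt)."""
    if not 2 <= len(snv_sets) <= 4:
        raise ValueError("replicate_overlap supports 2 to 4 sets")
    if labels is None:
        labels = [s.name or f"set{i+1}" for i, s in enumerate(snv_sets)]
    labels = tuple(labels)
    key_sets = {lab: s.keys for lab, s in zip(labels, snv_sets)}
    all_keys = set.union(*key_sets.values())
    exclusive: dict[frozenset, int] = {}
    for key in all_keys:
        pattern = frozenset(lab for lab in labels if key in key_sets[lab])
        exclusive[pattern] = exclusive.get(pattern, 0) + 1
    pair = pd.DataFrame(0, index=list(labels), columns=list(labels))
    for a, b in combinations(labels, 2):
        n = len(key_sets[a] & key_sets[b])
        pair.loc[a, b] = pair.loc[b, a] = n
    for lab in labels:
        pair.loc[lab, lab] = len(key_sets[lab])
    all_shared = len(set.intersection(*key_sets.values()))
    return OverlapResult(labels, exclusive, pair, all_shared)


def group_statistics(counts_by_group: Mapping[str, Sequence[float]],
                     control: str) -> pd.DataFrame:
    """Per-group mean, SEM, fold over control and Welch t-test p-values.

    The p-value for each non-control group is a two-sided unpaired t-test
    against the control with Welch's unequal-variance correction; it is NaN
    where either group has fewer than two values.  Fold is the ratio of group
    mean to control mean (NaN, with a warning, if the control mean is zero).
    """
    if control not in counts_by_group:
        raise ValueError(f"control group {control!r} missing")
    ctrl = np.asarray(counts_by_group[control], dtype=float)
    ctrl_mean = ctrl.mean()
    if ctrl_mean == 0:
        warnings.warn("control mean is zero; fold changes are undefined")
    rows = []
    for group, values in counts_by_group.items():
        v = np.asarray(values, dtype=float)
        mean = v.mean()
        sem = stats.sem(v) if len(v) >= 2 else np.nan
        fold = mean / ctrl_mean if ctrl_mean != 0 else np.nan
        if group == control or len(v) < 2 or len(ctrl) < 2:
            t_stat, p = np.nan, np.nan
        else:
            t_stat, p = stats.ttest_ind(v, ctrl, equal_var=False)
        rows.append((group, len(v), mean, sem, fold, t_stat, p))
    return pd.DataFrame(rows, columns=["group", "n", "mean", "sem",
                                       "fold_vs_control", "t_stat", "p_value"]
                        ).set_index("group")
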