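"""Protospacer site geometry on amplicons.

A :class:`ProtospacerSite` anchors the protospacer/PAM coordinate system on an
amplicon reference.  Protospacer positions are numbered 1..proto_len from the
PAM-distal (5') end of the protospacer, with the PAM immediately 3'-adjacent,
so "A5" is the fifth base of the protospacer counting away from the PAM.  All
per-position bases are reported on the protospacer strand; for sites on the
amplicon minus strand this means reverse-complementing observed bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd

DNA_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC nucleotide codes -> set of concrete bases they match.
IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def matches_iupac(seq: str, pattern: str) -> bool:
    """True if ``seq`` matches the IUPAC ``pattern`` base-by-base."""
    if len(seq) != len(pattern):
        return False
    return all(b in IUPAC[p.upper()] for b, p in zip(seq.upper(), pattern))


class SiteConfigError(ValueError):
    """Raised when a site definition is internally inconsistent."""


@dataclass(frozen=True)
class ProtospacerSite:
    """An amplicon together with the protospacer/PAM geometry on it.

    Parameters
    ----------
    site_id : str
        Unique identifier.
    amplicon_seq : str
        Forward-strand amplicon reference (ACGT only).
    proto_start : int
        0-based offset of the protospacer footprint on the amplicon forward
        strand (leftmost base of the footprint regardless of strand).
    strand : {"+", "-"}
        Orientation of the protospacer relative to the amplicon forward
        strand.
    proto_len : int
        Protospacer length (20 for SpCas9).
    pam : str
        IUPAC PAM pattern expected 3' of the protospacer (e.g. ``NGG``).
    intended_positions : tuple of int
        1-based protospacer positions carrying the intended A-to-G edit.
    """

    site_id: str
    amplicon_seq: str
    proto_start: int
    strand: str = "+"
    proto_len: int = 20
    pam: str = "NGG"
    intended_positions: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        amp = self.amplicon_seq.upper()
        object.__setattr__(self, "amplicon_seq", amp)
        object.__setattr__(self, "intended_positions",
                           tuple(int(p) for p in self.intended_positions))
        if set(amp) - set(DNA_BASES):
            raise SiteConfigError(
                f"{self.site_id}: amplicon contains non-ACGT characters")
        if self.strand not in "+-":
            raise SiteConfigError(f"{self.site_id}: strand must be + or -")
        if self.proto_len < 1:
            raise SiteConfigError(f"{self.site_id}: proto_len must be >= 1")
        if not (0 <= self.proto_start and
                self.proto_start + self.proto_len <= len(amp)):
            raise SiteConfigError(
                f"{self.site_id}: protospacer footprint outside amplicon")
        pam_len = len(self.pam)
        if self.strand == "+":
            pam_obs = amp[self.proto_start + self.proto_len:
                          self.proto_start + self.proto_len + pam_len]
        else:
            lo = self.proto_start - pam_len
            pam_obs = revcomp(amp[max(lo, 0):self.proto_start]) if lo >= 0 else ""
        if not matches_iupac(pam_obs, self.pam):
            raise SiteConfigError(
                f"{self.site_id}: PAM {pam_obs!r} does not match {self.pam!r}")
        for p in self.intended_positions:
            if not 1 <= p <= self.proto_len:
                raise SiteConfigError(
                    f"{self.site_id}: intended position {p} outside protospacer")
            if self.proto_base(p) != "A":
                raise SiteConfigError(
                    f"{self.site_id}: intended position {p} is not an A "
                    f"on the protospacer strand")

    # -- coordinate helpers -------------------------------------------------

    @property
    def protospacer(self) -> str:
        """Protospacer sequence on the protospacer strand, 5'->3'."""
        footprint = self.amplicon_seq[self.proto_start:
                                      self.proto_start + self.proto_len]
        return footprint if self.strand == "+" else revcomp(footprint)

    @property
    def footprint(self) -> tuple[int, int]:
        """0-based half-open interval of the protospacer on the forward strand."""
        return self.proto_start, self.proto_start + self.proto_len

    @property
    def pam_observed(self) -> str:
        pam_len = len(self.pam)
        if self.strand == "+":
            s = self.proto_start + self.proto_len
            return self.amplicon_seq[s:s + pam_len]
        return revcomp(self.amplicon_seq[self.proto_start - pam_len:
                                         self.proto_start])

    def amplicon_index(self, position: int) -> int:
        """Forward-strand amplicon index of protospacer ``position`` (1-based)."""
        if not 1 <= position <= self.proto_len:
            raise IndexError(f"protospacer position {position} out of range")
        if self.strand == "+":
            return self.proto_start + position - 1
        return self.proto_start + self.proto_len - position

    def proto_base(self, position: int) -> str:
        """Reference base at a protospacer position, on the protospacer strand."""
        b = self.amplicon_seq[self.amplicon_index(position)]
        return b if self.strand == "+" else b.translate(_COMPLEMENT)

    @property
    def proto_ref_bases(self) -> str:
        """Reference protospacer bases positions 1..proto_len (= protospacer)."""
        return self.protospacer

    def mirrored(self) -> "ProtospacerSite":
        """The same site expressed on the reverse-complemented amplicon.

        Useful for strand-invariance checks: quantification of a site and of
        its mirrored counterpart must agree base-for-base.
        """
        L = len(self.amplicon_seq)
        new_start = L - (self.proto_start + self.proto_len)
        return ProtospacerSite(
            site_id=self.site_id,
            amplicon_seq=revcomp(self.amplicon_seq),
            proto_start=new_start,
            strand="+" if self.strand == "-" else "-",
            proto_len=self.proto_len,
            pam=self.pam,
            intended_positions=self.intended_positions,
        )


def load_sites(sites_tsv: str | Path, amplicons: dict[str, str]) -> list[ProtospacerSite]:
    """Load site definitions from a TSV plus an amplicon FASTA dict.

    Expected TSV columns: ``site_id``, ``amplicon_id``, ``proto_start``,
    ``strand``, ``pam``, ``intended_positions`` (comma-separated 1-based
    positions, may be empty).
    """
    table = pd.read_csv(sites_tsv, sep="\t", dtype=str)
    required = {"site_id", "amplicon_id", "proto_start", "strand", "pam"}
    missing = required - set(table.columns)
    if missing:
        raise SiteConfigError(f"sites table missing columns: {sorted(missing)}")
    sites = []
    for row in table.itertuples(index=False):
        amp_id = row.amplicon_id
        if amp_id not in amplicons:
            raise SiteConfigError(f"amplicon {amp_id!r} not in FASTA")
        raw = getattr(row, "intended_positions", "") or ""
        intended = tuple(int(x) for x in str(raw).split(",") if x.strip()) \
            if str(raw) not in ("", "nan") else ()
        sites.append(ProtospacerSite(
            site_id=row.site_id,
            amplicon_seq=amplicons[amp_id],
            proto_start=int(row.proto_start),
            strand=row.strand,
            pam=row.pam,
            intended_positions=intended,
        ))
    return sites
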