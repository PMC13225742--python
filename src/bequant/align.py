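"""Read-to-amplicon alignment for targeted amplicon sequencing.

Reads are aligned to the amplicon reference with an end-gap-free ("overlap")
global alignment under affine gap penalties: match +2, mismatch -3, a gap of
length k costs 8 + (k - 1) (the opening penalty covers the first gapped
base).  End gaps on either sequence are free, so a read that covers only part
of the amplicon, or overhangs it, is not penalised for the unaligned flanks.
Ties between co-optimal alignments are broken deterministically by taking the
first traceback of Biopython's aligner, which places gaps leftmost on the
target.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

import numpy as np
from Bio import Align

from .sites import ProtospacerSite, _COMPLEMENT

#: window (bp) around the protospacer footprint inside which a gap marks the
#: read as indel-containing
INDEL_FLANK = 10


@dataclass(frozen=True)
class AlignmentScheme:
    """Scoring parameters for the overlap alignment."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -8.0   # cost of the first base of a gap
    gap_extend: float = -1.0


DEFAULT_SCHEME = AlignmentScheme()


class InvalidReadError(ValueError):
    """Read rejected before alignment (bad characters or too short)."""


@lru_cache(maxsize=8)
def _make_aligner(scheme: AlignmentScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scheme.match
    aligner.mismatch_score = scheme.mismatch
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend
    # free end gaps on both sequences -> overlap alignment
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


@dataclass
class AlignedRead:
    """One read aligned to an amplicon, projected onto protospacer coordinates.

    Attributes
    ----------
    read_id : str
    score : float
        Alignment score under the scheme used.
    has_indel : bool
        True if any internal gap overlaps the protospacer +/- INDEL_FLANK bp.
    bases : numpy array of single characters, length proto_len
        Observed base at each protospacer position on the protospacer strand;
        ``''`` where the read does not cover the position (or a gap removes
        it), ``'N'`` where the read base is ambiguous.
    """

    read_id: str
    score: float
    has_indel: bool
    bases: np.ndarray

    def base_at(self, position: int) -> str:
        """Observed base at 1-based protospacer ``position`` ('' if uncovered)."""
        return str(self.bases[position - 1])


def align_read(read: str, site: ProtospacerSite,
               scheme: AlignmentScheme = DEFAULT_SCHEME,
               read_id: str = "") -> AlignedRead:
    """Align one read to the site's amplicon and project it onto the protospacer.

    Raises
    ------
    InvalidReadError
        If the read contains characters outside ACGTN or is shorter than
        30 bases.  Callers are expected to count rejected reads rather than
        abort (see :func:`align_reads`).
    """
    read = read.upper()
    if set(read) - set("ACGTN"):
        raise InvalidReadError(f"{read_id or 'read'}: non-ACGTN characters")
    if len(read) < 30:
        raise InvalidReadError(f"{read_id or 'read'}: shorter than 30 bases")

    amplicon = site.amplicon_seq
    aligner = _make_aligner(scheme)
    alignments = aligner.align(amplicon, read)
    best = alignments[0]
    coords = best.coordinates  # shape (2, n_points): target row, query row

    read_base_at = np.full(len(amplicon), "", dtype="<U1")
    window_lo = max(0, site.proto_start - INDEL_FLANK)
    window_hi = min(len(amplicon), site.proto_start + site.proto_len + INDEL_FLANK)
    has_indel = False

    n_seg = coords.shape[1] - 1
    for k in range(n_seg):
        t0, t1 = int(coords[0, k]), int(coords[0, k + 1])
        q0, q1 = int(coords[1, k]), int(coords[1, k + 1])
        if t1 > t0 and q1 > q0:                      # aligned block
            read_base_at[t0:t1] = list(read[q0:q1])
        elif t1 > t0:                                # gap in read over target
            if q0 == 0 or q0 == len(read):
                continue                             # uncovered amplicon flank
            if t0 < window_hi and t1 > window_lo:    # internal deletion
                has_indel = True
        elif q1 > q0:                                # inserted read bases
            if t0 == 0 or t0 == len(amplicon):
                continue                             # read overhang
            if window_lo <= t0 <= window_hi:         # internal insertion
                has_indel = True

    bases = np.full(site.proto_len, "", dtype="<U1")
    for pos in range(1, site.proto_len + 1):
        b = read_base_at[site.amplicon_index(pos)]
        if b and site.strand == "-":
            b = b.translate(_COMPLEMENT)
        bases[pos - 1] = b

    return AlignedRead(read_id=read_id, score=float(best.score),
                       has_indel=has_indel, bases=bases)


def align_reads(reads: Iterable[tuple[str, str]], site: ProtospacerSite,
                scheme: AlignmentScheme = DEFAULT_SCHEME,
                ) -> tuple[list[AlignedRead], int]:
    """Align (read_id, sequence) pairs; returns (aligned reads, n_rejected)."""
    aligned: list[AlignedRead] = []
    n_rejected = 0
    for read_id, seq in reads:
        try:
            aligned.append(align_read(seq, site, scheme=scheme, read_id=read_id))
        except InvalidReadError:
            n_rejected += 1
    return aligned, n_rejected
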