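"""Synthetic-data generators with known ground truth.

Every pipeline stage can be exercised without external data: random genomes,
deaminase-style genome-wide off-target SNVs with TA-context bias, paired
edited/control pileups with mosaic allele fractions and sequencing error,
amplicon reads with configurable per-position editing profiles, and planted
predicted-off-target decoys.  All generators are deterministic for a fixed
seed and emit :class:`TruthSet` sidecars for oracle comparisons.

Default parameters emulate the study conditions this package targets: 50x
whole-genome coverage, ~350 deaminase off-targets against a ~13-event
spontaneous background per embryo, mosaic allele fractions centred at 0.5
(single-blastomere editing followed by sorting), and amplicon editing
profiles peaking at protospacer position A5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .goti import Pileups, encode_seq
from .predicted import PredictedSite
from .sites import DNA_BASES, IUPAC, ProtospacerSite, revcomp

_BASE_INDEX = {b: i for i, b in enumerate(DNA_BASES)}
# the 3 non-reference base codes for each reference code
_ALT_CODES = np.array([[c for c in range(4) if c != r] for r in range(4)])


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

def make_genome(length: int, gc: float = 0.42, seed=0,
                name: str = "chr1") -> dict[str, str]:
    """Random i.i.d. genome at the stated GC content; byte-deterministic.

    The default GC of 0.42 matches the mouse genome.  Lengths below 10 kb
    are rejected: context statistics are meaningless on smaller sequences.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be strictly between 0 and 1")
    if length < 10_000:
        raise ValueError("genome length must be >= 10 kb")
    rng = _as_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    seq = "".join(DNA_BASES[c] for c in codes)
    return {name: seq}


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthEvent:
    chrom: str
    pos: int        # 1-based
    ref: str
    alt: str
    strand: str     # deaminated strand for deaminase events; '+' otherwise
    origin: str     # deaminase | background | germline
    af: float

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)


@dataclass
class TruthSet:
    """Ground truth emitted by the simulators.

    ``events`` hold SNV-level truth; ``site_profiles`` the per-site true and
    realised amplicon editing profiles; ``planted_sites`` the decoy
    protospacer loci written into a genome.
    """

    events: list[TruthEvent] = field(default_factory=list)
    site_profiles: dict = field(default_factory=dict)
    planted_sites: list[PredictedSite] = field(default_factory=list)

    def events_by_origin(self, origin: str) -> list[TruthEvent]:
        return [e for e in self.events if e.origin == origin]

    @property
    def keys(self) -> set[tuple]:
        return {e.key for e in self.events}

    def events_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.events],
                            columns=["chrom", "pos", "ref", "alt", "strand",
                                     "origin", "af"])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "events": [asdict(e) for e in self.events],
            "site_profiles": self.site_profiles,
            "planted_sites": [asdict(s) for s in self.planted_sites],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            events=[TruthEvent(**e) for e in payload["events"]],
            site_profiles=payload["site_profiles"],
            planted_sites=[PredictedSite(**s)
                           for s in payload["planted_sites"]],
        )


# ---------------------------------------------------------------------------
# deaminase off-target SNVs
# ---------------------------------------------------------------------------

@dataclass
class OfftargetSimConfig:
    """Conditions for one simulated GOTI embryo.

    Defaults emulate an efficient adenine base editor: ~350 deaminase
    off-targets over a ~13-event spontaneous background at 50x coverage,
    with mosaic allele fractions ~ N(0.5, 0.1) truncated to (0, 1).
    """

    seed: int = 0
    genome_len: int = 2_500_000
    gc: float = 0.42
    n_deaminase: int = 350
    ta_weight: float = 1.0
    n_background: int = 13
    n_germline: int = 0
    af_mean: float = 0.5
    af_sd: float = 0.1
    depth: int = 50
    err_rate: float = 0.001

    def __post_init__(self):
        if min(self.n_deaminase, self.n_background, self.n_germline) < 0:
            raise ValueError("event counts must be nonnegative")
        if not 0 < self.af_mean < 1:
            raise ValueError("af_mean must be in (0, 1)")
        if self.ta_weight < 1:
            raise ValueError("ta_weight must be >= 1")
        if self.genome_len < 10_000:
            raise ValueError("genome_len must be >= 10 kb")


def adenine_context_counts(genome: dict[str, str]) -> tuple[int, int]:
    """(n_TA, n_other): adenines on both strands with/without a 5' T.

    An adenine's context is read on its own (deaminated) strand; edge
    adenines with no 5' neighbour count as non-TA.
    """
    n_ta = n_other = 0
    for seq in genome.values():
        codes = encode_seq(seq)
        fwd_a = codes == _BASE_INDEX["A"]
        fwd_ta = np.zeros_like(fwd_a)
        fwd_ta[1:] = fwd_a[1:] & (codes[:-1] == _BASE_INDEX["T"])
        rev_a = codes == _BASE_INDEX["T"]       # A on the reverse strand
        rev_ta = np.zeros_like(rev_a)
        rev_ta[:-1] = rev_a[:-1] & (codes[1:] == _BASE_INDEX["A"])
        n_ta += int(fwd_ta.sum() + rev_ta.sum())
        n_other += int((fwd_a & ~fwd_ta).sum() + (rev_a & ~rev_ta).sum())
    return n_ta, n_other


def expected_ta_fraction(genome: dict[str, str], ta_weight: float) -> float:
    """Expected TA-context fraction of deaminase events under ``ta_weight``."""
    n_ta, n_other = adenine_context_counts(genome)
    return ta_weight * n_ta / (ta_weight * n_ta + n_other)


def ta_weight_for_fraction(genome: dict[str, str], target: float) -> float:
    """The ta_weight that makes the expected TA-context fraction ``target``."""
    if not 0 < target < 1:
        raise ValueError("target fraction must be in (0, 1)")
    n_ta, n_other = adenine_context_counts(genome)
    w = target * n_other / ((1 - target) * n_ta)
    if w < 1:
        raise ValueError(f"target {target} below the genomic TA proportion; "
                         "would need ta_weight < 1")
    return w


def _truncnorm_af(n: int, mean: float, sd: float,
                  rng: np.random.Generator) -> np.ndarray:
    a, b = (0 - mean) / sd, (1 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                               random_state=rng)


def simulate_deaminase_snvs(genome: dict[str, str], config: OfftargetSimConfig,
                            rng: np.random.Generator | None = None) -> TruthSet:
    """Sample deaminase, background and germline SNVs over a genome.

    Deaminase events are drawn without replacement over the adenines of both
    strands, each weighted ``ta_weight`` when its 5' neighbour on the
    deaminated strand is T; they read out as A>G (forward-strand adenine) or
    T>C (reverse-strand adenine).  Background and germline events are
    uniform over the remaining positions with a uniform alternative base.
    No position is used twice.
    """
    rng = _as_rng(config.seed if rng is None else rng)
    if len(genome) != 1:
        raise ValueError("single-contig genomes only")
    (chrom, seq), = genome.items()
    codes = encode_seq(seq)
    L = len(codes)

    # candidate adenines: forward (A>G) then reverse (T>C)
    fwd_pos = np.flatnonzero(codes == _BASE_INDEX["A"])
    rev_pos = np.flatnonzero(codes == _BASE_INDEX["T"])
    n_cand = len(fwd_pos) + len(rev_pos)
    if n_cand < config.n_deaminase:
        raise ValueError("not enough adenines for n_deaminase events")

    weights = np.ones(n_cand)
    fwd_ta = (fwd_pos > 0) & (codes[np.maximum(fwd_pos - 1, 0)] == _BASE_INDEX["T"])
    rev_ta = (rev_pos < L - 1) & (codes[np.minimum(rev_pos + 1, L - 1)] == _BASE_INDEX["A"])
    weights[:len(fwd_pos)][fwd_ta] = config.ta_weight
    weights[len(fwd_pos):][rev_ta] = config.ta_weight

    events: list[TruthEvent] = []
    used = np.zeros(L, dtype=bool)

    if config.n_deaminase > 0:
        # Gumbel top-k == weighted sampling without replacement
        keys = np.log(weights) + rng.gumbel(size=n_cand)
        chosen = np.argpartition(-keys, config.n_deaminase - 1)[:config.n_deaminase]
        afs = _truncnorm_af(config.n_deaminase, config.af_mean, config.af_sd, rng)
        for j, af in zip(chosen, afs):
            if j < len(fwd_pos):
                pos0 = int(fwd_pos[j])
                ref, alt, strand = "A", "G", "+"
            else:
                pos0 = int(rev_pos[j - len(fwd_pos)])
                ref, alt, strand = "T", "C", "-"
            used[pos0] = True
            events.append(TruthEvent(chrom, pos0 + 1, ref, alt, strand,
                                     "deaminase", float(af)))

    for origin, n in (("background", config.n_background),
                      ("germline", config.n_germline)):
        if n == 0:
            continue
        pool = np.flatnonzero(~used)
        if len(pool) < n:
            raise ValueError(f"not enough free positions for {origin} events")
        picked = pool[rng.choice(len(pool), size=n, replace=False)]
        alt_shift = rng.integers(1, 4, size=n)
        afs = (np.full(n, 0.5) if origin == "germline"
               else _truncnorm_af(n, config.af_mean, config.af_sd, rng))
        for pos0, shift, af in zip(picked, alt_shift, afs):
            used[pos0] = True
            ref_c = int(codes[pos0])
            alt_c = (ref_c + int(shift)) % 4
            events.append(TruthEvent(chrom, int(pos0) + 1, DNA_BASES[ref_c],
                                     DNA_BASES[alt_c], "+", origin, float(af)))

    events.sort(key=lambda e: (e.chrom, e.pos))
    return TruthSet(events=events)


# ---------------------------------------------------------------------------
# paired pileups
# ---------------------------------------------------------------------------

def _sample_pileup(ref_codes: np.ndarray, events: Sequence[TruthEvent],
                   depth_mean: int, err_rate: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    L = len(ref_codes)
    depth = rng.poisson(depth_mean, size=L).astype(np.int32)
    counts = np.zeros((L, 4), dtype=np.int32)
    rows = np.arange(L)
    counts[rows, ref_codes] = depth
    if err_rate > 0:
        n_err = rng.binomial(depth, err_rate)
        split = rng.multinomial(n_err, [1 / 3] * 3)          # (L, 3)
        alts = _ALT_CODES[ref_codes]                         # (L, 3)
        counts[rows[:, None], alts] += split.astype(np.int32)
        counts[rows, ref_codes] -= n_err.astype(np.int32)
    for ev in events:
        pos0 = ev.pos - 1
        ref_c, alt_c = _BASE_INDEX[ev.ref], _BASE_INDEX[ev.alt]
        n_alt = int(rng.binomial(depth[pos0], ev.af))
        n_alt = min(n_alt, int(counts[pos0, ref_c]))
        counts[pos0, alt_c] += n_alt
        counts[pos0, ref_c] -= n_alt
    return depth, counts


def simulate_paired_pileups(genome: dict[str, str], truth: TruthSet,
                            config: OfftargetSimConfig,
                            rng: np.random.Generator | None = None,
                            ) -> tuple[Pileups, Pileups]:
    """Edited and control pileups for one embryo.

    Per position, depth ~ Poisson(``depth``); truth-site alternative reads
    ~ Binomial(depth, af) in the edited sample only, except germline events
    which appear in both; sequencing errors move Binomial(depth, err_rate)
    reads to uniformly chosen other bases in both samples.
    """
    rng = _as_rng(config.seed if rng is None else rng)
    ref, e_depth, e_counts, c_depth, c_counts = {}, {}, {}, {}, {}
    for chrom, seq in genome.items():
        codes = encode_seq(seq)
        ev_all = [e for e in truth.events if e.chrom == chrom]
        ev_germ = [e for e in ev_all if e.origin == "germline"]
        ref[chrom] = codes
        e_depth[chrom], e_counts[chrom] = _sample_pileup(
            codes, ev_all, config.depth, config.err_rate, rng)
        c_depth[chrom], c_counts[chrom] = _sample_pileup(
            codes, ev_germ, config.depth, config.err_rate, rng)
    edited = Pileups(ref, e_depth, e_counts)
    control = Pileups(dict(ref), c_depth, c_counts)
    return edited, control


def run_offtarget_sim(config: OfftargetSimConfig,
                      genome: dict[str, str] | None = None,
                      ) -> tuple[dict[str, str], TruthSet, Pileups, Pileups]:
    """Genome + truth + paired pileups from one seed, end to end."""
    rng = np.random.default_rng(config.seed)
    if genome is None:
        genome = make_genome(config.genome_len, config.gc, rng)
    truth = simulate_deaminase_snvs(genome, config, rng)
    edited, control = simulate_paired_pileups(genome, truth, config, rng)
    return genome, truth, edited, control


# ---------------------------------------------------------------------------
# amplicon reads
# ---------------------------------------------------------------------------

def gaussian_profile(proto_len: int, peak: float, center: int = 5,
                     sigma: float | tuple[float, float] = (2.3, 3.6),
                     ) -> np.ndarray:
    """Bell-shaped per-position editing probabilities, possibly asymmetric.

    ``sigma`` may be a scalar or a (left, right) pair; editing windows of
    real base editors are wider on the PAM-proximal side of the peak, which
    a symmetric falloff cannot represent.
    """
    s_left, s_right = (sigma, sigma) if np.isscalar(sigma) else sigma
    pos = np.arange(1, proto_len + 1, dtype=float)
    d = pos - center
    s = np.where(d < 0, s_left, s_right)
    return peak * np.exp(-(d ** 2) / (2 * s ** 2))


@dataclass
class AmpliconSimConfig:
    """Conditions for one simulated amplicon deep-sequencing library."""

    seed: int = 0
    n_reads: int = 5000
    p_profile: Sequence[float] | None = None  # default: gaussian_profile
    c_edit_rate: float = 0.0
    indel_rate: float = 0.0
    err_rate: float = 0.0
    engagement_frac: float = 1.0  # fraction of reads exposed to the editor

    def __post_init__(self):
        if self.n_reads < 100:
            raise ValueError("n_reads must be >= 100")
        for r in (self.c_edit_rate, self.indel_rate, self.err_rate,
                  self.engagement_frac):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        if self.p_profile is not None:
            p = np.asarray(self.p_profile, dtype=float)
            if np.any((p < 0) | (p > 1)):
                raise ValueError("p_profile values must be in [0, 1]")
            object.__setattr__(self, "p_profile", p)


def simulate_amplicon_reads(site: ProtospacerSite, config: AmpliconSimConfig,
                            rng: np.random.Generator | None = None,
                            ) -> tuple[list[tuple[str, str]], TruthSet]:
    """Amplicon reads under a per-position editing model.

    Each read independently acquires an A>G edit at protospacer position i
    with probability ``p_profile[i-1]`` (per-position independence; set
    ``engagement_frac`` < 1 for a read-level editor-exposure mixture), a
    C edit (to T/G/A uniformly) at each protospacer C with ``c_edit_rate``,
    a 1-3 bp indel inside the protospacer with ``indel_rate``, and uniform
    per-base sequencing errors at ``err_rate``.  Reads are emitted on the
    amplicon forward strand, full length.

    Returns the reads and a :class:`TruthSet` whose ``site_profiles`` entry
    records the configured probabilities and the realised per-position edit
    counts among indel-free reads.
    """
    rng = _as_rng(config.seed if rng is None else rng)
    if config.p_profile is None:
        p_profile = gaussian_profile(site.proto_len, peak=0.44)
    else:
        p_profile = np.asarray(config.p_profile, dtype=float)
    if len(p_profile) != site.proto_len:
        raise ValueError("p_profile length must equal proto_len")

    # simulate in protospacer-strand space; flip back at the end if needed
    sim_site = site if site.strand == "+" else site.mirrored()
    amp = sim_site.amplicon_seq
    fp_lo, fp_hi = sim_site.footprint
    a_pos = [i for i in range(1, sim_site.proto_len + 1)
             if sim_site.proto_base(i) == "A"]
    c_pos = [i for i in range(1, sim_site.proto_len + 1)
             if sim_site.proto_base(i) == "C"]
    a_idx = np.array([sim_site.amplicon_index(i) for i in a_pos], dtype=int)
    c_idx = np.array([sim_site.amplicon_index(i) for i in c_pos], dtype=int)
    a_p = p_profile[np.array(a_pos) - 1]

    reads: list[tuple[str, str]] = []
    edited_counts = np.zeros(site.proto_len, dtype=int)
    n_indel = 0
    n_clean = 0
    other = {b: [c for c in DNA_BASES if c != b] for b in DNA_BASES}

    for r in range(config.n_reads):
        chars = list(amp)
        engaged = rng.random() < config.engagement_frac
        edited_here: list[int] = []
        if engaged and len(a_idx):
            hits = rng.random(len(a_idx)) < a_p
            for idx, pos in zip(a_idx[hits], np.array(a_pos)[hits]):
                chars[idx] = "G"
                edited_here.append(pos)
        if engaged and len(c_idx) and config.c_edit_rate > 0:
            hits = rng.random(len(c_idx)) < config.c_edit_rate
            for idx in c_idx[hits]:
                chars[idx] = other["C"][rng.integers(3)]
        has_indel = rng.random() < config.indel_rate
        if has_indel:
            n_indel += 1
            k = int(rng.integers(1, 4))
            at = int(rng.integers(fp_lo, fp_hi))
            if rng.random() < 0.5:
                del chars[at:at + k]
            else:
                ins = [DNA_BASES[rng.integers(4)] for _ in range(k)]
                chars[at:at] = ins
        else:
            n_clean += 1
            for pos in edited_here:
                edited_counts[pos - 1] += 1
        if config.err_rate > 0:
            err_at = np.flatnonzero(rng.random(len(chars)) < config.err_rate)
            for j in err_at:
                chars[j] = other[chars[j]][rng.integers(3)]
        seq = "".join(chars)
        if site.strand == "-":
            seq = revcomp(seq)
        reads.append((f"read{r:06d}", seq))

    realized = np.full(site.proto_len, np.nan)
    if n_clean:
        realized = edited_counts / n_clean
    realized[[sim_site.proto_base(i) != "A"
              for i in range(1, site.proto_len + 1)]] = np.nan
    truth = TruthSet(site_profiles={site.site_id: {
        "p_profile": [float(x) for x in p_profile],
        "realized_a2g": [None if np.isnan(x) else float(x) for x in realized],
        "n_reads": config.n_reads,
        "n_indel_reads": n_indel,
    }})
    return reads, truth


# ---------------------------------------------------------------------------
# planted predicted sites
# ---------------------------------------------------------------------------

def plant_predicted_sites(genome: dict[str, str], spacer: str,
                          pam: str = "NGG",
                          mismatch_list: Sequence[int] = (0, 1, 2, 3),
                          rng: np.random.Generator | int | None = 0,
                          margin: int = 30,
                          ) -> tuple[dict[str, str], list[PredictedSite]]:
    """Write protospacer+PAM decoys with exact mismatch counts into a genome.

    For each requested mismatch count a 23-mer (20-nt spacer variant with
    exactly that many mismatches, plus a concrete PAM instance) is written at
    a random locus on a random strand, keeping ``margin`` bp between
    placements.  Returns the modified genome and the planted truth.
    """
    if len(spacer) != 20:
        raise ValueError("spacer must be a 20-mer")
    rng = _as_rng(rng)
    if len(genome) != 1:
        raise ValueError("single-contig genomes only")
    (chrom, seq), = genome.items()
    chars = list(seq.upper())
    L = len(chars)
    cassette_len = 20 + len(pam)
    occupied: list[tuple[int, int]] = []
    planted: list[PredictedSite] = []

    for m in mismatch_list:
        if not 0 <= m <= 20:
            raise ValueError("mismatch counts must be in [0, 20]")
        variant = list(spacer.upper())
        if m:
            for j in rng.choice(20, size=m, replace=False):
                variant[j] = [b for b in DNA_BASES if b != variant[j]][
                    rng.integers(3)]
        variant = "".join(variant)
        pam_concrete = "".join(sorted(IUPAC[ch.upper()])[rng.integers(
            len(IUPAC[ch.upper()]))] for ch in pam)
        strand = "+" if rng.random() < 0.5 else "-"
        cassette = variant + pam_concrete
        if strand == "-":
            cassette = revcomp(cassette)
        placed = False
        for _ in range(1000):
            s = int(rng.integers(margin, L - cassette_len - margin))
            if all(s + cassette_len + margin <= lo or s >= hi + margin
                   for lo, hi in occupied):
                placed = True
                break
        if not placed:
            raise ValueError("could not place site without overlap")
        chars[s:s + cassette_len] = list(cassette)
        occupied.append((s, s + cassette_len))
        if strand == "+":
            fp = (s, s + 20)
        else:
            fp = (s + len(pam), s + cassette_len)
        planted.append(PredictedSite(chrom, fp[0], fp[1], strand, int(m),
                                     variant))
    return {chrom: "".join(chars)}, planted
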