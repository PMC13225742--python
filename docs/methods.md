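# Methods

## Coordinate conventions

Protospacer positions are 1-based, A1…A20 counted from the PAM-distal (5′)
end of the protospacer with the PAM immediately 3′-adjacent; this matches
the A1–A20 axis used throughout base-editor characterisation. All
per-position bases are reported on the protospacer strand: for sites on the
amplicon minus strand, observed bases are reverse-complemented and position
*i* maps to forward-strand offset `proto_start + proto_len − i`. Pileup and
SNV coordinates are 1-based; BED-style intervals are 0-based half-open.
Quantifying a site and its mirrored (reverse-complemented) counterpart
yields identical count matrices; this is enforced by test.

## Read alignment

Reads are assumed pre-merged, pre-oriented single sequences (demultiplexing,
UMI handling and paired-end merging are out of scope). Alignment is global
with free end gaps ("overlap" alignment) under affine penalties: match +2,
mismatch −3, gap of length *k* costs 8 + (*k* − 1) — the opening penalty
covers the first gapped base. These values favour a single short indel over
scattered mismatches at amplicon scale; they are exposed via
`AlignmentScheme`. Biopython's `PairwiseAligner` provides the dynamic
programming; the first traceback is taken, which places gaps leftmost and
makes tie-breaking deterministic. A read is *indel-containing* when an
internal gap overlaps the protospacer ± 10 bp; gaps further away (and
uncovered flanks from partial reads) do not disqualify substitution calls.
Reads with non-ACGTN characters or shorter than 30 bases are rejected and
counted, never fatal.

## Efficiency denominators

Per-position frequencies are computed over substitution-only reads with an
unambiguous (non-N) base at the position. Indel-containing reads are
excluded from these denominators and reported as
`indel_fraction = n_indel_reads / n_reads`; the exclusion is a documented
choice, switchable with `include_indel_reads=True`, because published
amplicon pipelines are not unanimous on it. N bases never count as edits or
as coverage.

"Undesired C editing" at a position is the frequency of C→(T/G/A) among
covering reads; the site-level scalar is the maximum over protospacer C
positions (a per-read alternative would count reads with any C edit — the
max-over-positions form is used because it is well defined even when C
content differs between sites). For the single-site C5/A5 ratio, a site
whose position 5 is not a C contributes a numerator of 0 (there is no C to
edit); the library-level ratio uses an aggregated mean profile in which the
C5 mean runs over sites with a C at position 5 and the A5 mean over sites
with an A.

## Editing window

The window rule is applied to the across-site unweighted mean profile
(positions with no contributing A site are null): all positions with mean
efficiency ≥ `threshold_frac` (default 0.30) of the peak, ties for the peak
broken toward the smallest position index. The rule alone does not enforce
contiguity, so the window is reported as the threshold-passing set; a
display helper returns the largest contiguous run containing the peak,
which is how windows such as "A2–A10" are conventionally written. The
window is invariant under uniform scaling of the profile. An all-zero
profile yields an empty window.

## Paired de novo calling

The caller scans paired pileups position by position: a site/alt is called
iff depth ≥ `min_depth` (default 10) in both samples, the edited sample has
≥ `min_alt_depth` alt reads at allele fraction ≥ `min_af`, and the control
has ≤ `max_control_alt` alt reads. Reference disagreement between samples
is a hard error. Three profiles emulate the common practice of intersecting
three independent callers:

| profile   | min_alt_depth | min_af | max_control_alt |
|-----------|---------------|--------|-----------------|
| strict    | 5             | 0.15   | 0               |
| default   | 3             | 0.10   | 0               |
| sensitive | 2             | 0.05   | 1               |

Consensus is the intersection of the three call sets (union available by
flag); raising any threshold can only shrink a call set (tested as a
property). At 50× with mosaic allele fractions near 0.5, recall loss is
dominated by the zero-tolerance control filter meeting a sequencing-error
read (≈ 1.6 % of sites at error rate 0.001), which keeps consensus recall
≈ 0.98, false positives at zero genome-wide, and germline variants (present
in both samples at af 0.5) fully excluded.

## Spectrum, orientation and information content

Substitutions are counted in the 12 directed classes; the deamination
signature is summarised as the combined A→G + T→C fraction. For context
analysis, A→G events are read on the forward reference strand and T→C
events reverse-complemented so that offset 0 is always the deaminated A;
other classes are excluded and counted, as are events whose flank
(default ± 3, configurable — published logos do not state their width)
would cross a contig end. Information content per flanking position is
2 − H bits with H the Shannon entropy of base frequencies computed with a
pseudocount of 0.5 per base (reported alongside raw counts; the closed-form
limits 2 bits / 1 bit / 0 bits for conserved, half-half and uniform columns
hold at pseudocount 0). The TA-motif fraction is the share of oriented
events with T at offset −1; RNA mode relabels T as U and expects calls
already resolved to the transcript strand (strand assignment from
annotation is the caller's responsibility, not inferred here).

## Synthetic data: what it emulates, and what it does not

`make_genome` draws i.i.d. bases at a stated GC (default 0.42, mouse-like);
lengths under 10 kb are rejected as meaningless for context statistics.

`simulate_deaminase_snvs` samples adenines on both strands without
replacement (Gumbel top-k weighted sampling), weighting each adenine by
`ta_weight` when its 5′ neighbour on its own strand is T, and records A→G
(forward) or T→C (reverse) — the strand-symmetric readout of adenine
deamination. `ta_weight_for_fraction` calibrates the weight so the expected
TA fraction hits a target (e.g. 0.8) by exhaustive genome context
enumeration. Background and germline events are uniform over free positions
with a uniform alternative base — uniform over directed classes conditional
on base composition, the natural behaviour of a spontaneous background.
Default event counts (350 deaminase, 13 background) mirror the scale of an
efficient ABE against a spontaneous background per embryo; mosaic allele
fractions are truncated-normal(0.5, 0.1) on (0, 1), reflecting
single-blastomere editing followed by sorting — no empirical af
distribution is available, so these defaults are stated, not fitted.
Germline events are implanted at af 0.5 in both samples.

`simulate_paired_pileups` draws per-position depth ~ Poisson(50), alt reads
~ Binomial(depth, af) at truth sites (edited sample only; germline in
both), and sequencing errors ~ Binomial(depth, 0.001) scattered uniformly
over the three non-reference bases in both samples.

`simulate_amplicon_reads` edits each protospacer A independently with its
per-position probability (an optional read-level engagement mixture relaxes
the independence assumption), edits each C with `c_edit_rate` (alt uniform
over T/G/A), inserts a 1–3 bp indel inside the protospacer with
`indel_rate`, and applies uniform per-base errors. The bell-shaped profile
helper accepts separate left/right falloff widths because real editing
windows are asymmetric around the peak — a wide-window editor spanning
A2–A10 with its peak at A5 is wider on the PAM-proximal side, which no
symmetric falloff can represent (A1 at distance 4 would always be included
together with A9). The default (σ_left, σ_right) = (2.3, 3.6) with peak
0.44 at A5 realises exactly the A2–A10 window under the 30 % rule; (1.6,
1.6) with peak 0.424 realises A3–A7.

Not modelled: quality-score-dependent error profiles, PCR duplicates,
processivity correlation between positions beyond the engagement mixture,
structural variants, chromatin/replication models of ssDNA exposure, and
real read alignment for the WGS arm (pileups are generated directly).
Passing tests therefore demonstrate the correctness of the quantification
machinery under a faithful error model, not robustness to artefacts these
simplifications exclude.

## Determinism

Every generator takes a single integer seed (or an explicit
`numpy.random.Generator`) and is byte-deterministic, including gzip FASTQ
output (fixed header mtime and empty stored filename). Consensus and
report outputs are emitted in sorted order, so reruns are byte-identical;
the CLI MANIFEST carries the only timestamp, and its config hash is
computed over timestamp-free content.

## Problem sizes

The test suite and acceptance script run at the sizes the analysis is
designed around: 5,000-read amplicon libraries for profile/window recovery
(binomial SD ≈ 0.7 percentage points at the peak), 20,000 reads with
common random numbers for the between-editor A5 difference (coupling the
per-read draws makes the difference estimator's SD ≈ 0.2 points), a 2.5-Mb
genome at 50× for caller performance, and 1 Mb for the exhaustive-scan
oracle comparison.
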