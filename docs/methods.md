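# Methods

## The measurement

A read that spans two or more occurrences of the same rDNA feature
yields a direct unit-length observation: the distance between the
projected *origins* (feature position 0) of consecutive same-feature,
same-strand anchors. Start-to-start distances cancel anchor-internal
alignment error to first order, and substitution errors cannot move them
at all; only indels jitter the measurement, with expected measured
length `L·(1 + p_ins − p_del)` for true length `L`.

Anchors are feature hits with ≥80% feature coverage whose feature start
is actually observed (hits missing more than 25 bp of the feature's
start are excluded: their origin would be an extrapolation whose error
grows with the truncation — this matters for reads that begin or end
inside a feature copy, where the aligner can absorb the missing prefix
into a degenerate alignment). Observations from plus- and minus-strand
anchor pairs are pooled; observations come from one anchor feature at a
time (default 18S) to avoid double counting.

## Feature search

Seed-and-extend: exact k-mer seeds (k = 15) of the read, excluding
DUST-masked and soft-masked (lowercase) positions, matched against the
feature sequence on both strands; seeds cluster by diagonal (band =
0.2 × feature length, accommodating ~15–20% indel noise) and gap
(≤2 kb); each cluster is extended by a semi-global edit-distance
alignment (edlib, mode HW) of the feature against the implied read
window. Identity is computed over the interior (aligned) columns;
coverage over the whole feature. Hits below 75% identity or 50% coverage
are dropped; co-linear same-feature fragments are chained (ONT errors
fragment single occurrences), with alignment-length-weighted identity.

DUST masking scores each 64-base window as
`10 · Σ_t c_t(c_t−1)/2 / (n_triplets − 1)` over its overlapping
triplets and masks windows scoring >20 — the classic masker's scaled
score, under which uniform random DNA scores ~5 and homopolymer or
short-motif runs score in the hundreds. (The unscaled triplet sum
averages ~30 on random DNA in a 64-base window, so a raw threshold of 20
would mask everything.)

## Size summaries

Mean and sample SD (n−1); Gaussian KDE evaluated exactly on a 512-point
grid spanning the data range extended by 3 bandwidths; bandwidth by the
rule of thumb `0.9·min(s, IQR/1.34)·n^(−1/5)` (the default of R's
`density()`, against which the implementation is cross-checked in the
test suite via Rscript). When the observations carry no spread at all
the bandwidth is floored at 1 bp so the KDE mode is the observed value
itself rather than an artifact of a huge fallback bandwidth. A secondary
peak is the mode of the same KDE restricted to one side of a stated
bound. Size classes: normal 8–20 kb, large >30 kb, the gap in between
reported as intermediate, below 8 kb as out of range.

## Consensus and annotation

Up to 15 unit copies (deterministically selected: longest anchor support
first, then lexical read id) are cut between consecutive projected 18S
origins and rotated to the forward strand, so every unit begins at the
18S start. The consensus is a star alignment: the medoid copy (minimal
summed edit distance, first on ties) is the centre; every copy is
globally aligned to it; each centre column is called by majority with
the gap as a votable symbol (gap-majority columns deleted, ties to the
alphabetically earliest base, base preferred over gap). Insertions
relative to the centre are independent single-base errors and never
reach a majority, so they are dropped.

Known bias: bases *deleted in the medoid itself* cannot be recovered by
column voting, so the consensus runs short by about the per-read
deletion rate (e.g. ~0.9% at 1% deletions); it is exact on error-free
data. Applications needing polished consensi should iterate or use a
dedicated polisher.

Annotation locates 18S/5.8S/28S by semi-global alignment of reference
features (≥60% identity required, else an error naming the missing
feature); ITS1/ITS2 are the gaps between coding regions and the IGS runs
from the 28S end to the unit end. Because rRNA transcription start
sites cannot be determined from DNA sequence, this IGS definition
*includes both external transcribed spacers*; output headers state this.
The six regions always partition the unit exactly.

## Sub-repeat detection

The unit's k-mer self-match map (k = 12; all off-diagonal exact matches
(i, j), i < j, offsets capped at 1 kb) is the dotplot. Positions covered
by any short-offset match are merged into candidate spans (gap
tolerance 100 bp — small enough that distinct arrays a spacer apart
never fuse). A span's period is the smallest observed offset whose
multiples (±max(2 bp, 2%)) explain ≥80% of its match offsets, which
prevents reporting 2p for a p-periodic array. Because divergence thins
exact matches, the span is then grown outward one period at a time while
the next chunk still aligns to its inner neighbour at ≥60% identity.
Classification: period <10 bp ⇒ microsatellite (excluded from all
sub-repeat totals); mean adjacent-copy identity <0.70 ⇒ degenerate
(the threshold is a configurable knob — the boundary between "tandem
array" and "too diverged to delimit" is inherently soft); otherwise
sub-repeat. Overlapping candidates resolve to the larger span, then the
larger period.

Variance attribution uses residual variance rather than a regression:
with S_i the total sub-repeat length physically inside unit i,
`1 − Var(L−S)/Var(L)` (sample variances, clamped to [0,1]) directly
expresses "length variation caused by copy number" and equals R² when
the residuals are uncorrelated with S. It is exactly 1 when copy number
is the only varying component, 0 when S is constant, undefined (reported
as NA) when Var(L) = 0, and invariant under adding a constant to all
lengths.

## TE orthology

RepeatMasker records <50 bp are discarded. Fragments with the same
repeat name and orientation are rejoined into one logical element when
their consensus coordinates continue co-linearly (tolerance 50 bp;
descending along the query for minus-strand elements) and the query gap
between them is ≥80% covered by other annotated elements, which become
nested children. Matching between two IGSs is the maximum-cardinality
common subsequence over (class/family, orientation) tokens — class/
family rather than repeat name, since cross-species comparison operates
at the family level (a strict by-name mode exists) — computed by
dynamic programming in O(|A|·|B|); among maximum-cardinality matchings
the one maximizing Σ min(len_A, len_B) is selected, making the result
deterministic. Non-TE annotations (simple repeats, pseudogenes such as
the primate cdc27 insertion) are carried through reports but never
matched. The DP is verified against exhaustive enumeration of all
order-preserving matchings on instances with ≤8 elements per side.

## The simulator

`synthetic_data` emulates the statistical structure the analysis
assumes, with complete ground truth:

- One locus = random flank + n tandem units + random flank. All base
  region sequences, sub-repeat masters, TE and microsatellite sequences
  are drawn once per locus (mimicking concerted evolution); only
  sub-repeat copy numbers (uniform integer law per unit) and their
  per-copy substitutions vary between units, so in truth
  `Var(L) = period² · Var(cn)` exactly.
- Default architecture: 18S 1,800 bp, ITS1 1,000 bp, 5.8S 150 bp, ITS2
  1,000 bp, 28S 4,500 bp, IGS core 6,550 bp — a 15 kb "normal" unit of
  vertebrate-magnitude coding lengths. Only the relative layout matters
  to the pipeline; every length is configurable (the bimodal analyses
  use IGS cores of 31,550/35,550 bp for 40/44 kb units).
- Reads: start uniform over the genome, truncated at the ends (no
  circularity), strand by fair coin, length fixed or lognormal. Errors
  are per-base independent: substitution to a uniformly random
  *different* base; single-base insertions/deletions with no
  homopolymer bias. This reproduces the length jitter and anchor
  fragmentation that matter to the measurement, not basecaller-specific
  artifacts (no squiggle model, no quality-correlated errors, no PacBio
  CCS profile) — so passing tests demonstrate correctness of the
  measurement machinery under idealized noise, not robustness to every
  real-world basecaller pathology.
- All randomness flows from one explicit integer seed; rerunning any
  stage with the same seed is byte-identical.

## Problem sizes and numerical choices

The bundled analyses run at desk scale: 10-unit loci, 40–60 reads of
40 kb (92 kb for the bimodal 40/44 kb condition), ≤15 consensus units,
200 random TE instances — sizes chosen so every stage completes in
seconds while leaving each statistical check well-powered (e.g. ≥20
unit-length observations per sizing run). Sub-seeds for independent
stages are small fixed offsets from the user seed. Ties are broken
deterministically everywhere (medoid choice, consensus base order,
unit selection, overlap resolution), so identical inputs and seeds give
identical outputs regardless of iteration order.

## Scope limits

External tools (BLAST, MAFFT, RepeatMasker, assemblers) are never
invoked; their standard output formats are consumed instead (BLAST
tabular outfmt 6/7, RepeatMasker `.out`, FASTA MSA import for
consensus). SAM/BAM ingestion, protein-space search, mixture-model
fitting of size distributions, phylogenetics, and chromosome-haplotype
resolution of rDNA arrays are out of scope.
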