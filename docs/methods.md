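# Methods

## Scope and model

The package treats a haploid nuclear genome as an ordered map of chromosome
sequences over {A,C,G,T,N}, where maximal N-runs mark assembly gaps.  All
coordinates are 0-based half-open in memory; the on-disk dialects (GFF3,
VCF, pileup, alignment coords) are 1-based inclusive, and conversion happens
only in the readers/writers of `pipeline_io`.  Three analyses share these
types: assembly correctness scoring, reference improvement, and
two-timepoint strain comparison.  All randomness flows through explicit
integer seeds (one `numpy` generator per operation call, no global state),
so every pipeline product is a pure function of (configuration, seed).

## Assembly evaluation

**Filtering.**  Alignment blocks below 95% identity are discarded, as are
all blocks of scaffolds ≤ 500 bp.  Redundant placements are resolved on
scaffold coordinates: when two blocks of one scaffold overlap by more than
95% of the shorter block, the shorter one is removed (ties broken by higher
identity, then earlier scaffold start).  The greedy order makes the filter
idempotent, which the suite checks property-style.

**Mis-join taxonomy.**  For each pair of adjacent blocks of a scaffold,
precedence is translocation (different chromosomes) > inversion (different
strands) > relocation.  A relocation requires either a reference order that
contradicts the scaffold order or a reference-coordinate gap differing from
the scaffold-coordinate gap by more than a tolerance (default 1000 bp,
configurable) — adjacent blocks split across a true gap should not count as
errors.  A breakpoint is skipped only when *both* flanking blocks intersect
a repeat interval; requiring both keeps the masking conservative.  One event
at most is emitted per adjacent pair.  The classifier is verified against an
exhaustive case analysis of every configuration of up to three blocks on up
to two chromosomes with both strands (~1100 configurations).

**Contiguity.**  N50 is the first length at which the descending cumulative
sum of scaffold lengths reaches half the assembly size.  Covered-percentage
denominators exclude N positions (a gap cannot be covered).  Every non-N
base is either CDS (inside a CDS exon) or intergenic; introns count as
intergenic in the 2×2 Fisher test of CDS vs intergenic representation
(two-sided exact p via the hypergeometric null; a table with a zero margin
is rejected as degenerate).  A gene is a complete start-to-stop CDS when a
single scaffold's blocks cover every CDS base.

**Saturation.**  The placement table is shuffled once per seed and each
target depth takes a prefix of the shuffle, so subsets are nested and the
covered fraction is non-decreasing by construction — an invariant, not just
an expectation.

## Reference improvement

**Recruitment.**  A gap is closed by a donor scaffold when the alignment
evidence reaches ≥ 200 aligned bp at ≥ 95% identity with ≥ 50 bp anchored on
each side of the gap.  Two geometries are accepted: a single block spanning
the gap (flanks measured inside the block), or two blocks of the same
scaffold and strand abutting the gap edges whose scaffold-coordinate
separation matches the gap length within ±20% (the replacement then comes
from the scaffold between the anchors, so a closed gap may change length).
One closure per gap: longest total aligned span, ties by identity.  Raising
any threshold can only shrink the closure set (tested over parameter
grids).  `apply_closures` refuses overlapping closures or non-N targets and
is byte-preserving outside the replaced intervals.

**Read-pair linkage.**  Pairs whose two ends map within 500 bp (default) of
the ends of two different scaffolds are tallied per end pair and orientation
signature.  An end pair with ≥ 10 supporting pairs and a consistent majority
(≥ 80% by default) is a join; a majority signature with equal read
orientations means one scaffold is reversed relative to the other and is
flagged `inversion_fix`.  The local-reassembly and k-mer-profiling stages of
a full resequencing workflow are deliberately abstracted to this pair-count
decision rule operating on placement tables.

**Base and indel correction.**  A site is corrected when, in every provided
library class (DNA mandatory, RNA optional), at least 10 reads disagree with
the reference, and the most frequent alternative exceeds 90% of the DNA
reads — strictly, so an exact 90% tie never fires.  The same counts and
fractions applied to insertion/deletion evidence drive indel corrections.

**Gap spacing.**  Under uniform random gap placement at the observed
density, the spacing between consecutive gaps is geometric.  Observed
spacings (pooled over chromosomes) are binned at the equal-probability
quantiles of the geometric law fitted by its mean; bins with expected counts
below 5 are merged; the Pearson statistic is referred to chi-square with
(bins − 1 − 1) degrees of freedom, the usual reduction for the one parameter
estimated from the same data.  With that correction the test's measured
type-I error under the null is 4.5–5.5% across 200-replicate batches;
without it (df = bins − 1) the test is conservative (2–3.5%).

## Strain comparison

**Depth bounds.**  A site enters the comparison only when both libraries
cover it with ≥ 10 reads and ≤ 125% of that library's mean coverage (mean
over all non-N positions, zeros included; rounding half away from zero, so a
mean of 205 gives a ceiling of 256).  Explicit per-library overrides exist
because printed ceilings in practice do not always equal the rounded
product.

**Fixed differences.**  The caller is symmetric and haploid: each library
must be ≥ 99% unanimous for its own single allele and the two alleles must
differ.  Consensus thresholds are inclusive (≥ 0.99).  Indels use the same
two-sided fractions on indel-evidence counts at the anchor base before the
event; the allele written for a deletion covers the anchor plus the deleted
bases, VCF-style.  Swapping the two tracks returns the same loci with the
allele roles exchanged, and raising a consensus fraction can only remove
calls — both are tested.

**Effect annotation.**  Substitutions in a CDS are classified by rebuilding
the affected codon strand-aware and translating with the standard nuclear
code: synonymous, nonsense (stop gained) or non-synonymous (a change in the
initiator codon is non-synonymous with a `start_lost` note).  CDS indels are
frameshifts unless their length is a multiple of three (in-frame indel).
Everything outside CDS exons — including introns — is non-coding.  The
classifier is cross-checked against an oracle that mutates the chromosome,
rebuilds the entire CDS and compares the translated proteins.

**Copy number.**  Fixed 50 bp windows tile each chromosome (the final
partial window is evaluated with its own mean); a window is flagged when its
mean depth is ≥ 2× the genome-wide mean, and the rounded ratio is the
integer copy estimate.  Two strains are compared by the symmetric difference
of their flagged window sets, so shared amplifications cancel and an empty
difference means no copy-number change between timepoints.

## Synthetic data: what it emulates, and what it does not

The generator scales a compact, GC-rich (58%) algal-style genome down to a
default of 150 kb over three chromosomes: ~60 single- or two-exon genes
(19% carry one intron of 60–160 bp, matching the compact gene models being
emulated), a 2% repeat fraction of 250 bp units, and a dozen N-gaps of
60–400 bp kept ≥ 300 bp from other features so that recruitment flanks are
well defined.  Derived strains default to the event inventory of a
lab-evolution comparison — 8 substitutions, 2 deletions, 1 insertion — plus
a tandem duplication whose extra copies raise pileup depth over the source
interval in proportion to the copy count.  Indels are rejection-sampled away
from exon boundaries so their coding effect is unambiguous.  Sequencing is
emulated at the pileup level: per-site coverage is Poisson at the requested
depth (defaults 175× and 205× for the two libraries, the high-coverage
regime being modeled), each counted base is miscalled with probability
`error_rate` (default 0.2%) uniformly over the other three bases, and
spurious indel evidence occurs at one tenth of that rate, reflecting the
rarity of indel errors relative to substitutions in short-read data.

Not emulated: read sequences or quality strings, error-rate variation along
reads or with GC, alignment ambiguity in repeats, and library-preparation
coverage biases.  Passing tests therefore demonstrate the correctness of the
decision rules and their thresholds under a clean, known error model — not
robustness to alignment artifacts in real data.

A consequence worth stating explicitly: under independent per-base errors,
a ≥ 99% consensus rule cannot be a zero-miss detector at ~100× coverage.
At depth *n*, a site tolerates at most ⌊n/100⌋ erroneous reads; for
Poisson(100) coverage roughly half of all sites have n < 100, where a single
miscalled read (probability 1 − 0.998ⁿ ≈ 18%) already breaks the threshold.
Measured over 20 seeded strain pairs at 100× and 0.2% error, the caller
recovers 86% of injected variants with zero false positives; near-complete
recovery needs either the ~700×+ regime, depths near the 175–205×
defaults with a modest miss probability per variant, or a lower error rate.
The suite records this boundary honestly rather than relaxing the rule.

## Numerical conventions and edge cases

* Rounding in rendered reports is half away from zero (mean mis-joins to 3
  decimals; percentages to 0 or 1 decimal as printed).
* `filter_alignments` and `classify_misjoins` require per-scaffold input
  sorted by scaffold start and raise on violations; unknown scaffold ids,
  malformed placement rows (reported with their row number), mismatched
  coordinate spaces, zero-margin contingency tables, infeasible feature
  packing and over-closing gap accounts all raise validation errors rather
  than degrading silently.
* Problem sizes in the default study (150 kb genome, 175–205× pileups,
  20-seed recovery sweeps, 200-replicate spacing calibration) keep the whole
  test suite and the acceptance script in the tens of seconds on one CPU
  while leaving every statistic comfortably away from small-sample noise.

## Known limitations

* The recruitment two-block geometry requires blocks abutting the gap edges
  exactly, which exact-substring donors produce; real aligner output with
  clipped ends may need pre-trimming.
* The caller reports at most one alternate allele per site (clonal haploid
  model); sites split across two alternates are simply not called.
* Scaffold N-runs inside donors are never written into a closure
  (replacements must be N-free), but no attempt is made to close a gap
  partially.
* The gap-spacing null models gaps as points at the observed density; very
  long gaps relative to chromosome length would distort the geometric
  approximation.
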