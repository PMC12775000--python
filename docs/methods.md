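# Methods

## Model and procedure

The package treats regulatory fine-mapping of one associated locus as
three independent lines of evidence for a candidate SNV, computed by
three stages that can run separately or as one pipeline.

**Prioritization.** The input LD block is a list of variants annotated
with r² to the lead SNP. Variants with r² below a user-chosen threshold
are dropped (the threshold is a required parameter, not a default — how
tight a "block" is depends on the cohort), and the rest are intersected
with accessible-chromatin peaks. Coordinates follow each format's native
convention: variants are 1-based (VCF), peaks 0-based half-open (BED); a
variant at 1-based position p lies in peak [s, e) iff s ≤ p−1 < e, so a
peak's closed start is inside and its exclusive end outside. Coverage
context is computed as mean per-base depth in fixed windows (500 bp for
locus overviews, 50 bp zoomed), optionally counts-per-million scaled by
1e6/library_size.

**Allele-aware motif scoring.** A motif of length L is a 4×L frequency
matrix M; count matrices are converted with a per-cell pseudocount c:
frequency = (count + c)/(column total + 4c). The score of an L-mer s is
Σᵢ log₂(M(sᵢ,i)/b(sᵢ)) with background b (uniform 0.25 by default;
configurable). For a SNV we take the 2f+1-base window centered on it
(f = 25, i.e. 51 bp), build both allele windows, and score every
placement of the motif that covers the variant on the forward sequence
and on its reverse complement — 2·min(L, valid placements) placements,
22 for L = 11 in a 51-bp window with a central variant. The best hit is
chosen independently per allele (best placements may differ in offset or
strand); ties prefer the + strand, then the smaller offset, so output is
deterministic. Binding efficiency is 2^score and the allelic effect is
the efficiency ratio, equal to 2^(score difference); when both alleles'
best placements coincide, the log₂ ratio reduces to the log-odds
difference at the aligned position.

**Exact motif p-values.** The null distribution of the score over
i.i.d. background sequences is computed exactly by convolving the four
per-position log-odds values, each floored to an integer multiple of a
grid step ε (default 0.001 log₂ units). Cost is O(L · span/ε) rather
than 4^L. A query score is floored to the grid and additionally
discounted by (L−1)·ε before the tail sum P(Score ≥ ·): a sequence's
gridded score undershoots its exact score by at most L·ε, so this
discount guarantees the reported p-value is never smaller than the exact
tail probability (conservative), at the price of at most L·ε of score
resolution. The two-allele statistic is the ratio of best-hit p-values,
reported as max/min ≥ 1 together with the favored (smaller-p) allele.

**Allelic imbalance.** At a heterozygous site with k reference reads out
of n, the two-sided exact binomial p-value is computed against a null
proportion p₀ derived from local copy number: ref_copies/total_copies,
i.e. 0.5 for diploid or balanced tetraploid, 1/3 and 2/3 for the two
triploid heterozygotes; homozygous configurations are rejected. The
default two-sided convention is *minlike* — the sum of point
probabilities not exceeding that of the observed k, with 1e-7 relative
slack so float noise cannot flip inclusion at ties — matching common
exact-test implementations; doubling the smaller tail is available
because the literature does not agree on a convention for p₀ ≠ 0.5. All
tail sums use log-space probability mass (logsumexp), so extreme
imbalances yield exact tiny p-values instead of underflowing to zero.
Donors are combined by summing counts into one pooled test; per-donor
heterogeneity is reported as the max pairwise fraction difference but not
tested. Zero-depth samples are dropped with a warning and never count as
evidence.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *shape* of a fine-mapping study: an 11-bp
motif with one strongly constrained position (reference-allele frequency
`consensus_freq` = 0.8, alternate `disrupted_freq` = 0.1, remainder
spread evenly so every cell is strictly positive); a 51-bp window with
the motif consensus planted so the variant sits at the informative
position; a 17-variant LD block over ~14 kb (jittered lattice placement,
r² to lead drawn in [0.9, 1]) with peaks covering exactly 2 variants
plus a decoy peak covering none; and 7 donors whose depths are negative
binomial (mean 60, dispersion 10 — typical het-site depth for
accessibility data; zero depths are redrawn) with reference counts
Binomial(depth, `true_ref_fraction` = 0.95). Every generator is a pure
function of (config, seed), with an independent substream per generator
so call order never matters.

It does **not** emulate reference-mapping bias, overdispersion beyond
the depth distribution (allele counts are exactly binomial given depth),
haplotype structure (r² is an annotation, not simulated from genotypes),
GC-dependent coverage, or read-level error. Passing parameter-recovery
tests therefore demonstrates correctness of the statistics and plumbing,
not robustness to those real-data artifacts; the beta-binomial
overdispersion case in particular is explicitly out of scope.

## Numerical and design choices

- **Pseudocount** defaults to 0.01 per cell for count matrices. The
  synthetic generator emits strictly positive *frequency* matrices, so
  recovery runs use pseudocount 0 and the recovered log₂ fold equals the
  planted log₂(consensus/disrupted) to machine precision. Fold-change
  reproductions from public count matrices are sensitive to this knob
  (and to whether the matrix is taken as counts or frequencies), which is
  why it is surfaced as a parameter everywhere.
- **Grid step** ε = 0.001 log₂ units balances p-value resolution against
  the O(span/ε) distribution size; the conservativeness discount is
  (L−1)·ε as derived above.
- **Ambiguous bases** (N) are a hard error in scoring: silently assigning
  them zero or background odds would bias fold changes.
- **Ties** everywhere break deterministically (+ strand, smaller offset;
  report rows in input order), so reruns are byte-identical.
- **"0.33"/"0.66" nulls** are interpreted as exact 1/3 and 2/3 (triploid
  copy ratios), computed as rationals before conversion to float.
- **Chromosome naming** ("1" vs "chr1") is never silently normalized; the
  pipeline pre-flights consistency across inputs and fails before running
  any stage, with an opt-in `chrom_style` switch.
- **Problem sizes in the test suite** — oracle equivalence up to L = 8
  (4⁸ enumeration), binomial enumeration to n = 12, 10,000-draw
  calibration at n = 50, and 100–200 replicate recovery runs — were
  chosen so the whole suite exercises every guarantee at full strength
  while remaining a desk-scale computation.

## Known limitations

- The exact-test conventions differ across tools for asymmetric nulls;
  only minlike and doubled are implemented.
- The score-distribution p-value assumes an i.i.d. background; no
  dinucleotide or positional background models.
- Peak calling, LD estimation from panels, and read-level extraction of
  allelic counts are upstream of this package: peaks, r² values and count
  tables arrive as inputs.
- Reproducing published fold-change figures from public matrices requires
  matching the original tool's pseudocount and database-release
  conventions; with those unstated, such runs are supported but their
  exact values are documented as convention-sensitive.
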