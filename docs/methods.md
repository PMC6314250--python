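# Methods

## Problem setting

`batchvar` detects single-base variants inside a coding copy-number
repeat that has been "batch sequenced": all copies of the repeat are
amplified and aligned simultaneously onto a single reference repeat
unit. A variant carried by one copy among, say, 80 then appears as a
~1.2% minor allele at one reference position — the same statistical
regime as mitochondrial heteroplasmy or somatic mutation detection. The
motivating locus is the KIV-2 repeat of *LPA* (5.1 kb unit, 1 to >40
copies per allele, ~70% of the gene's coding sequence), but nothing in
the package is specific to that locus: the reference unit, element
annotation, known-variant definitions and exclusion mask are all user
data.

## Pileup model

Aligned reads (SAM/BAM, or in-memory records from the simulator) are
reduced to strand-separated per-position base counts, retaining each
observation's Phred quality. Read-level filters: mapping quality >= 20
and, when the configured SAM tag is present, a Phred-scaled alignment
quality >= 30; per-observation filter: base quality >= 20. All
thresholds are inclusive minima ("Q20" is the minimum acceptable
quality) and configurable. Indels are ignored entirely (the caller is
SNV-only); N bases are skipped; overlapping mates are both counted (no
de-duplication — amplicon data is expected); reads lacking the
alignment-quality tag pass that filter, since no standard tag exists
across aligners.

Base-alignment-quality (BAQ) recalibration is refused by contract
(`FilterConfig.apply_baq` must be false). Superimposing repeat subtypes
onto one unit produces runs of 2–5 adjacent low-level differences;
BAQ-style realignment treats exactly these patterns as alignment noise
and silently prunes them, so it must never run in this context.

## Variant-level likelihood

At a site, let f be the fraction of reads carrying the variant base and
e_i the error probability of read i (from its Phred quality). Each
retained observation contributes

- P(b_i = minor) = f(1−e_i) + (1−f)·e_i/3
- P(b_i = major) = (1−f)(1−e_i) + f·e_i/3
- P(other base) = e_i/3

i.e. errors are uniform over the three alternative bases. f is
estimated per strand by bounded scalar maximisation of the
log-likelihood on [0, 1] (tolerance 1e-6, endpoints checked); the
evidence against f = 0 is the likelihood-ratio statistic
D = 2(ll(f̂) − ll(0)), compared per strand to the χ²(df=1) quantile at
α = 0.01. Observations are grouped by (base, quality) so deep sites
cost O(#distinct qualities), not O(depth). A site's reported level is
the depth-weighted mean of the per-strand estimates. The major allele
is the reference base of the candidate pair; levels above 0.5 are
legitimate (a variant can dominate the superimposed copies).

## Filters and call emission

A candidate (site, alt allele) is emitted only if all of:

1. >= 2 supporting reads on *each* strand (both-direction confirmation);
2. D >= χ²₁(0.99) on each strand;
3. combined level >= 1% — a **hard floor**: below it the candidate is
   pruned regardless of significance. One variant copy among 80
   repeats sits at 1.2%, so nothing real is expected below 1%, and
   specificity is deliberately preferred over sensitivity there;
4. no strand bias: two-sided Fisher exact p < 1e-3 on the strand×allele
   2×2 table **and** a >5-fold ratio between per-strand levels flags
   bias (the ratio guard keeps pure depth imbalance from tripping the
   filter). Biased candidates are dropped by default, or emitted with
   a STRAND_BIAS flag under `keep_strand_biased`.

PASS additionally requires >= 780× total filtered coverage; otherwise
the call carries LOW_COVERAGE but is still reported (dual reporting:
observed vs confirmed-at-depth). The 780× constant is the published
minimum for differentiating a 1% variant from noise with both-strand
confirmation; the binomial-CI derivation behind it is not reproduced
here — the constant is exposed as configuration, and the boundary is
verified exactly (PASS at 780, LOW_COVERAGE at 779) by the tests.
Multiallelic sites (two or more emitted alt alleles) are supported and
flagged. Output ordering is deterministic (position, then alt base).
Ties for the major allele break toward the reference base, then
lexicographically.

## Annotation

Exon records carry a frame offset (leading bases completing a codon
begun upstream) and a concatenation order. Translation starts at the
first codon fully encoded within the unit's first coding exon, so
residue numbering is shifted by −1 relative to conventions that count
the upstream-spanning codon. The trailing partial codon is completed by
wrap-around with the unit's own leading coding bases — the repeat-
periodicity assumption, valid because the next copy begins with the
same sequence; such calls are flagged boundary-spanning. Consequences
are rendered `p.(Arg20Ter)`-style, or "synonymous". Splice distance is
signed (negative upstream of an exon start, positive past an exon end,
0 inside); |d| <= 25 bp marks near-splice, |d| in {1, 2} the canonical
splice sites. Known-variant matching is allele-exact: a different alt
at a known position is still "novel" (triallelic sites routinely pair
one known with one novel allele).

## Repeat-subtype analytics

Carrier status for the B subtype requires calls at **all three**
canonical exonic positions, with no grouping by level. Variant dosage
in repeat copies is level × total repeat count (e.g. a qPCR estimate of
summed copies). Because the first two canonical positions are shared
with the C subtype while the third is B-specific, the C-type excess is
estimated as max(0, mean(level₁, level₂) − level₃) × total repeats,
flagged above 0.8 copies. The mean (rather than min) of the shared
positions is a design choice — the two shared levels are exchangeable
estimates of the same quantity — and both the estimator and the 0.8
threshold are parameters.

## Mixture simulator

The synthetic benchmark reproduces the plasmid-calibration design in
silico: haplotype A is the reference; haplotype B differs at K = 60
positions (the published count of subtype-specific differences),
sampled outside the exclusion mask and always including one run of 2–5
consecutive differences. Mixing ratios follow the benchmark series
50:50, 90:10, 95:5, 97.5:2.5, 98.5:1.5, 99:1, with B always the minor
component. Each read is drawn from B with probability
x′ = βx/(βx + 1 − x), where β is a single effective amplification-bias
factor (β = 1 unbiased; β < 1 underamplifies the minor haplotype —
modelling the observed polymerase effect as a fraction transform rather
than a mechanistic per-cycle PCR simulation). Reads are 150 bp,
single-end, balanced across strands, clipped at the unit boundaries so
depth is flat across every position, and emitted pre-aligned (true
coordinates, CIGAR all-match), so no external aligner enters the loop.
Substitution errors are applied per base at the Phred-implied rate,
uniformly over the three alternatives — matching the caller's error
partition; per-cycle quality profiles are supported. Identical spec +
seed gives byte-identical SAM.

What the simulator does **not** emulate: indels, PCR chimeras/
recombination, polymerase-specific error spectra, paired-end overlap,
alignment ambiguity between diverged copies, and coverage waviness of
real amplicon data. Passing benchmarks therefore demonstrate the
statistical behaviour of the caller under its own error model, not
robustness to alignment artefacts.

Evaluation is allele-exact. Precision = 100·TP/(TP+FP); sensitivity =
100·TP/K; specificity = 100·TN/(N−K) where N is the unmasked callable
positions and negatives are counted per position (the published
benchmark does not state its negative denominator; this one is
documented and fixed). The bias factor is recoverable from data:
β̂ = x̄′(1−x)/(x(1−x̄′)) with x̄′ the mean called level over truth
positions; tests require recovery within 10% at 10,000× coverage.

## Statistics utilities

- Two-sample proportion test: pooled 2×2 chi-square with Yates
  continuity correction capped at the observed–expected difference,
  matching the standard R implementation; two-sided p from χ²(df=1).
  Correction is on by default.
- Inverse-normal transform: Φ⁻¹((rank − c)/(n − 2c + 1)) with the Blom
  offset c = 3/8 (exposed as a parameter); ties take average ranks.
- GC content: N excluded from numerator and denominator.
- Degenerate-site scan: IUPAC motifs matched on both strands with
  overlaps; palindromic double-matches deduplicated. A variant is
  classified as creating/destroying sites by diffing hit sets before
  and after the substitution. The DraIII recognition site CACNNNGTG
  ships in the enzyme table.

## Problem sizes and numerical choices

Benchmark runs in the tests and the acceptance script use scaled
synthetic units — 1,500 bp for the 50:50 condition (500× per strand)
and 600 bp for the 5% (20,000× total) and 1.5% (40,000× total)
conditions, K = 60 planted differences throughout, 10 seeds per
condition — sizes chosen so the full benchmark battery runs in a few
minutes while keeping >500 negative positions per run for the
specificity denominator. Boundary experiments construct synthetic
pileups directly: the coverage boundary is searched over total depths
770–790 at a ~1% level (Q40 observations, so the error-corrected level
estimate stays above the floor), and the floor sweep plants fractions
0.5–2.0% in 0.1% steps at depth 50,000, representing each fraction by
the smallest integer alt count whose ML level reaches it (plain
rounding can land an exact-boundary fraction epsilon below itself).

Known limitations: single-contig references only; no indel calling or
phasing; no BAQ (by contract); per-position rather than per-molecule
evaluation; the shipped default annotation's second-exon start is
provisional and should be overridden by curated data.
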