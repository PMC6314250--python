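# batchvar

Low-level single-base variant detection in **batch-sequenced copy-number
repeat regions**, with an in-silico mixture benchmark.

Some genes carry large coding repeats present in widely varying copy
number — the canonical example being the KIV-2 repeat of *LPA* (a 5.1 kb
unit, 1 to >40 copies per allele, ~70% of the coding sequence), where
variants modulate lipoprotein(a) and cardiovascular risk. Short reads
cannot be assigned to an individual copy, so the practical approach is
*batch sequencing*: amplify all copies at once and align everything to a
single reference unit. A variant carried by one copy among ~80 then
shows up as a ~1.2% minor allele at one position — the detection problem
of mitochondrial heteroplasmy, transplanted into a nuclear repeat.
`batchvar` is a toolkit for exactly this regime: for geneticists
analysing hypervariable repeat loci, and for method developers who need
a controlled benchmark for low-level variant callers.

## What it does

- **Pileup engine** — strand-separated, quality-filtered base counts
  (base/mapping/alignment quality >= 20/20/30, inclusive) from SAM/BAM
  over a single repeat unit. BAQ-style recalibration is *refused by
  contract*: repeat subtypes superimpose as runs of adjacent low-level
  differences that BAQ silently prunes.
- **Maximum-likelihood caller** — per strand, each read contributes
  P(minor) = f(1−e) + (1−f)e/3, P(major) = (1−f)(1−e) + fe/3,
  P(other) = e/3 with e its Phred error probability; f̂ maximises the
  likelihood on [0,1] and D = 2(ll(f̂) − ll(0)) is tested against
  χ²₁(0.99) *on each strand*. A call needs >=2 supporting reads per
  strand, a combined level >= **1% (hard floor)**, and no strand bias
  (Fisher p < 1e-3 plus >5× level ratio); PASS further requires
  **>= 780× total coverage**, else LOW_COVERAGE. Multiallelic sites are
  supported.
- **Annotator** — element context, amino-acid consequences under the
  repeat's −1 residue-numbering convention (first fully-encoded codon is
  residue 1; the terminal codon wraps around by repeat periodicity),
  signed splice distances (±25 bp near-splice window), and allele-exact
  known-variant labels so superposition artefacts are not mistaken for
  novel variants.
- **Subtype analytics** — carrier status from three canonical exonic
  positions, variant dosage (level × total repeat count), C-subtype
  excess from the shared-position levels, per-population summaries.
- **Mixture simulator + evaluator** — two haplotypes differing at K=60
  positions (with runs of adjacent differences), mixed at 50:50 … 99:1,
  Phred-calibrated substitution errors, optional amplification-bias
  factor β (observed fraction x′ = βx/(βx+1−x)), reads emitted
  pre-aligned; precision/sensitivity/specificity scoring against the
  planted truth.
- **Statistics** — R-compatible two-sample proportion test (Yates),
  rank-based inverse-normal transform (Blom), GC content, and IUPAC
  degenerate restriction-site scanning (DraIII: CACNNNGTG) with
  creates/destroys classification for variants.

## Worked example

Simulate a 95:5 two-haplotype mixture over a 1,000 bp synthetic unit
(12 planted differences, 2,000× per strand), call it, and score it:

```bash
batchvar simulate --length 1000 --k 12 --mix-fraction 0.05 \
    --coverage-per-strand 2000 --seed 11 \
    --out-sam mix.sam --out-truth truth.tsv --out-reference unit.fa
batchvar call --reference unit.fa --reads mix.sam --out calls.tsv
batchvar evaluate --reference unit.fa --reads mix.sam --truth truth.tsv
```

The caller reports 12 variants (`calls.tsv`, first rows):

```
pos  ref alt level    level_fwd level_rev depth_total filter
29   T   C   0.052422 0.050606  0.054230  4100        PASS
129  C   A   0.051890 0.049144  0.054531  4045        PASS
130  C   G   0.050754 0.048615  0.052821  4038        PASS
150  A   G   0.049861 0.050282  0.049455  4029        PASS
```

Every planted 5% variant is recovered at its expected level (129/130 is
one of the adjacent-difference runs that BAQ-style filtering would have
destroyed), and the evaluator prints:

```
tp 12   fp 0   fn 0   tn 988
precision 100.00   sensitivity 100.00   specificity 100.00
```

Library use mirrors the CLI: `synthetic_reference` / `make_haplotypes` /
`MixtureSpec` / `run_benchmark` for simulation, and `build_pileup` /
`call_sample` / `annotate_calls` for the calling path.

## Layout

```
src/batchvar/
  reference.py   repeat unit, annotation, known variants, exclusion mask
  pileup.py      strand-separated quality-filtered pileup (no BAQ)
  caller.py      ML low-level caller, strand bias, coverage gates
  annotate.py    consequences, splice distances, known-variant labels
  haplotypes.py  carrier status, dosage, subtype-excess analytics
  simulate.py    mixture simulator, truth sets, benchmark metrics
  stats.py       proportion test, inverse-normal, GC, motif scanning
  cli.py         `batchvar` subcommands: call / simulate / evaluate /
                 haplotype / scan-sites
  data/          default annotation + known-variant tables (provisional)
docs/methods.md  model, assumptions, parameters, limitations
```
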