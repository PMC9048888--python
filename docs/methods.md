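# Methods

## Phasing and event calling

For each parent and chromosome, informative sites are those where the parent
is heterozygous, the co-parent's transmitted allele is unambiguous, genotype
quality passes the threshold (default GQ >= 30), the site is Mendelian
consistent, passes an excess-heterozygosity screen (default 3.5 SD), is not
masked, and is not within the first/last 5 markers of the chromosome.

Each offspring's sequence of transmitted parental alleles is converted to a
binary haplotype-source vector by a minimum-recombinant (greedy switch)
assignment, which equals the exact two-state dynamic-programming optimum on
all generated test fixtures. At least 5 offspring are required to anchor
phase; ties produce an explicit ambiguity flag.

A run of discordant markers in one offspring is interpreted by span:

* span <= 10 kb: candidate non-crossover (NCO) gene-conversion tract;
* 10-100 kb: long-tract candidate, reported separately;
* &gt; 100 kb: a genuine haplotype switch, i.e. a crossover on each side of the
  run boundary where the source changes.

Crossover intervals are the gaps between the flanking informative markers.
Double crossovers within small intervals are reviewed (interval width, sibship
size, distance to chromosome ends) and labelled confirmed/provisional.

NCO tracts require at least 2 concordant flanking markers within the flank
span on each side, are filtered for sibling sharing (same converted marker in
2+ offspring implies a genotyping artifact or ancestral event) and for
Mendelian transmission where grandchildren exist, and are classified as
simple, complex members (within 30 kb of another tract in the same meiosis)
or CO-associated.

## Assembly-anomaly screening

Apparent triple crossovers clustered across meioses at the same two genomic
positions indicate an inverted segment; isolated tight double crossovers
recurring across meioses indicate a misplaced contig; recurrent single
breakpoints shared by 3+ meioses within 50 kb indicate a scaffold split or
tail swap, and are linked across chromosomes when complementary. `SegmentMap`
objects express coordinate corrections; `apply_corrections` rewrites the
genotype table so the pipeline can be re-run on corrected coordinates.

## Tract-length model and likelihood

Tract lengths follow either a geometric distribution or a two-component
mixture of geometrics with weight `alpha` on the short component, truncated
and renormalized at T = 10,000 bp for fitting. With `r` = converted base
pairs per base pair per meiosis, tracts initiate at intensity `r / E[Lambda]`
per bp, so the expected number of tracts of length k overlapping a marker
window is

```
f_k = r * Pr(k | Lambda) / E[Lambda]
```

For an observed tract (converted markers spanning [first, last] with
nonconverted flanking markers at lf and rf), the number of placements of a
length-k tract consistent with the observation, `o_k`, has a closed
piecewise-linear form (rising, flat, falling). The number of placements that
would have been detected anywhere on a chromosome of length L with marker
positions P but produced no observation, `e_k`, is computed from sorted gap
prefix sums with an exact right-boundary correction. The log-likelihood is

```
LL = sum_tracts log( sum_k f_k o_k ) - sum_k f_k e_k
```

Both closed forms are verified against brute-force enumeration in the test
suite.

Fits maximize LL over a two-significant-digit grid of means (10 to 100,000;
361 values) and, for the mixture, a lattice of alpha values (step 0.001,
coarse 41-point scan with local refinement). Profile confidence intervals
take the parameter range within 1.92 log-likelihood units of the maximum.
Per-mean caches of tract sums, exclusion sums and raw first moments make a
full mixture fit take seconds. `grid_stride` coarsens the mean grid for
faster exploratory fits.

## Tail-fraction conventions

`TractLengthModel.tail_fraction(x, weight, truncated)` reports either the
fraction of tracts longer than x (`weight="tracts"`) or the fraction of
converted base pairs contributed by such tracts (`weight="sites"`). With
`truncated=True` the mixture is renormalized over 1..T before taking tails;
with `truncated=False` the component geometrics' exact survival functions are
mixed. For the default model (alpha=0.998, means 24 and 4,300 bp) at
x = 100 bp these give 1.59%/25.4% (truncated) and 1.61%/31.8%
(nontruncated). `scripts/acceptance.py` reports the nontruncated values,
which are the natural summary of the underlying process rather than of the
fitting window.

## Simulator

`simulate_pedigree` builds two nuclear families, draws crossovers per meiosis
from sex-specific map lengths (defaults 2,080 cM male, 2,506 cM female over
20 chromosomes), places NCO tracts at 7.52e-6 converted bp per bp per
meiosis, applies a 57.6% GC-biased resolution at strong/weak heterozygous
sites, and injects genotype errors at a configurable rate. Ground truth
records every CO position, tract interval, converted site and error.
`inject_assembly_error` rewrites coordinates through a `SegmentMap` to create
inversion, misplaced-contig, tail-swap and split signatures with known truth.

`simulate_tract_observations` simulates the observation process alone
(uniform markers on meiosis-chromosome panels, Poisson tract initiations,
lengths from a given model) and packages detected tracts plus panel geometry
as `KmerData` for likelihood fitting.

## Test problem sizes

The test suite uses a 2-chromosome, 30 Mb, 150/200 cM configuration at zero
genotype-error rate (seed 42). This scale keeps runtimes in seconds while
preserving realistic marker density (3e-4/bp) and well-separated crossovers.
Parameter-recovery tests use an elevated conversion rate (2.3e-4 converted
bp/bp) so a thousand tracts arise from ~25 panels; the likelihood receives
the same rate, so the estimator is evaluated under a correctly specified
model.

## Limitations

* Recall is defined over *detectable* events: a crossover outside the
  informative-marker span, a tract whose converted markers are split by a
  biased-resolution back-conversion at an interior marker, a sibling-shared
  tract, or an event without adequate flanking markers cannot be recovered by
  any marker-based method and is excluded from the denominator.
* The mixture fit's mean grid has two-significant-digit resolution;
  confidence intervals are profile-based, not bootstrap.
* The anomaly detectors target the three recurrent signatures described
  above; they do not attempt general structural-variant discovery.
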