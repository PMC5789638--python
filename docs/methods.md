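# Methods

## Problem

Runs of homozygosity (ROH) — contiguous stretches where an individual is
homozygous at every assayed site — are routinely called with PLINK's
observational sliding-window scan. The same cohort genotyped on a SNP array
and sequenced at low coverage (~4x) yields different ROH estimates: the WGS
channel assays far more sites (about one het per 1.1 kb of genome versus one
per 7.1 kb for the array) but miscalls a fraction of homozygous sites as
heterozygous, and each false het threatens to break a true run.
`rohcompare` implements the machinery needed to study and correct for this:
the windowed caller with a tunable per-window het tolerance *h*, the site QC
applied beforehand, the concordance decomposition that measures the error
structure, the ep leakage statistic, the population-level comparison
statistics, and a paired-channel simulator with known truth.

## ROH calling model

For each individual and chromosome, a window of `window_snp` = 50
consecutive sites slides one site at a time. A window is *homozygous* when
it contains at most `window_het` = *h* heterozygous calls and at most
`window_missing` = 5 missing calls. A site enters the candidate state when
the fraction of homozygous windows among those covering it is at least
`window_threshold` = 0.05; sites near chromosome ends are covered by fewer
than 50 windows and use the actual covering count as denominator, and sites
covered by no window are never in-state. Maximal runs of candidate sites are
split between consecutive sites more than `max_gap_kb` = 1000 kb apart,
trimmed so both ends are non-het and non-missing, and retained when they
have at least `min_snp_final` = 50 sites, span at least `min_kb_final` =
300 kb, and have at least one SNP per `density_kb_per_snp` = 50 kb
(density computed on the final segment, not per window). There is no
segment-level cap on total het content beyond what the window tolerance
admits. The defaults are the standard PLINK 1.9 parameterization for
cross-technology comparison; `min_kb_final` is the *minimum final segment
length* (PLINK `--homozyg-kb` semantics), not a window length.

Coordinates are 1-based with inclusive segment ends
(`length = end - start + 1`, the PLINK `.hom` convention). Heterozygosity is
genotype-level; phase is ignored. Half-missing genotypes are missing.
The caller contains no randomness and no ties to break: identical input and
parameters produce byte-identical `.hom` output.

Numerical detail: the in-state rule is the rational comparison
`hom_windows / covering_windows >= threshold` evaluated in floats; an
epsilon of 1e-9 on the threshold side keeps exact fractions such as 1/20
on the correct side of 0.05 despite binary rounding.

## Site QC

Per population and per channel, sites are removed when the sample minor
allele frequency is strictly below 0.05 (a site exactly at 0.05 is kept) or
when the two-sided Hardy-Weinberg exact test conditional on the observed
allele counts gives p < 0.001. The exact test sums the conditional
probabilities of all heterozygote counts no more probable than the observed
one; the conditional weights are computed in exact integer arithmetic, so
the only floating-point step is the final division, and the tie comparison
(`<=` on weights) is exact. A chi-square variant is available behind a flag
for comparison. Monomorphic sites return p = 1. QC is idempotent.

## Concordance decomposition

The comparison universe for a pair of channels is the intersection of sites
by chromosome and position with both calls non-missing — percentages are
only meaningful on jointly called sites. Each shared site is classified
exactly once: concordant, het-array/hom-WGS, hom-array/het-WGS, or hom/hom
allele mismatch. The two het components sum with the hom/hom mismatches to
the total discordance (identity holds to 1e-9 by construction); the hom/hom
mismatches are reported separately rather than folded into either named
component. Percentages are computed per individual and averaged within
populations (pooling across individuals instead is a near-equivalent
alternative the interface does not expose). Per-Mb false-het rates divide
per-individual counts by a configurable autosomal span, default 2800 Mb
(~2.8e9 assayable autosomal bases); rates measured on shared sites must be
rescaled by the shared-site density when a genome-wide rate is wanted.

The packaged 20-population KGP/AGVP reference table (Infinium Omni 2.5-8
array versus ~4x WGS) ships as plain TSV and feeds the same summary
arithmetic.

## The ep statistic

Let R(P, h, x, y) be the called segments for population P at tolerance h
with length in [x, y) Mb, over the bins [1, 1.5), [1.5, 5), [5, 10),
[10, inf). Each bin contributes the arithmetic mean over its segments of the
per-segment het *fraction* (observed hets / SNPs in the segment); bins are
combined weighted by segment count and scaled by 100:

    ep(P, h) = 100 * (sum_xy |R| * ep_xy) / (sum_xy |R|)

With contiguous bins covering [1, inf) this equals the unbinned mean
per-segment het fraction, which the test suite asserts. The fraction rather
than the raw het count is the adopted definition: it is scale-free across
platforms whose segments contain very different SNP numbers (a single
tolerated het in a 368-SNP segment gives 0.27%, matching the magnitudes
this statistic is reported at); the raw-count variant is available via
`mode="count"`. Segments are pooled across individuals within a population.
Segments under 1 Mb never contribute. ep rises with h in tendency but not
strictly pointwise: a higher tolerance can extend a segment's boundary with
clean homozygous SNPs, growing the fraction's denominator and lowering ep
marginally; tests allow that boundary-drift wobble (0.05 percentage points).

## Population comparison

Per individual, over segments longer than 1 Mb (above which runs
predominantly reflect identity by descent rather than LD): NROH (count),
mean size (Mb) and SROH (total Mb). Population "mean size" is the mean over
individuals of per-individual means, matching the per-individual violin
construction. Channels are compared per statistic and per WGS tolerance h
against the array baseline (h = 1) by a two-sided Mann-Whitney-Wilcoxon
rank-sum test on the per-individual distributions and Pearson correlation of
the paired values. The MWW uses exact enumeration when both samples have at
most 12 observations and no ties, otherwise the normal approximation with
tie and continuity corrections; two identical constant samples give p = 1.
Pearson p-values come from the t-distribution with n - 2 df; zero-variance
vectors make r undefined (reported absent). Significance is read at 0.05,
two-sided, with no multiple-testing correction. Length-class summaries use
short [0.3, 1), medium [1, 8) and long [8, inf) Mb; the three class sums
partition each individual's total called length at or above 0.3 Mb.

## Synthetic data generator

The generator draws the study conditions the comparison machinery assumes:

* **Genome**: 4 chromosomes of 50 Mb (200 Mb — about a fifteenth of the
  autosomal genome, enough for tens of ROH per individual at desk-scale
  runtimes); 20 individuals.
* **Sites**: WGS sites at jittered ~1.1 kb spacing (uniform gaps in
  [0.5, 1.5) x spacing), array sites an independent ~15.5% positional
  subset giving ~7.1 kb spacing. The two channels therefore share a site
  universe by construction.
* **Genotypes**: per-site alternate-allele frequencies uniform on
  [0.05, 0.5]; background genotypes drawn independently per site under HWE.
  LD is not modelled — the analysis concerns runs above 1 Mb and a 50-SNP
  minimum, where chance homozygous runs under independence are negligible.
* **Autozygosity**: per individual, tract counts are Poisson per length
  class with means 4, 2, 2, 1 and 0.3 for [0.3, 1), [1, 1.5), [1.5, 5),
  [5, 10) and [10, 16] Mb (lengths uniform within class, placed uniformly
  without overlap, longest first). This plants on average ~9 tracts above
  0.3 Mb and ~23 Mb of autozygosity per individual — a strongly autozygous
  cohort, chosen so that per-individual NROH/SROH distributions carry
  enough signal for rank tests at n = 20. Inside a tract a single allele is
  drawn at the site frequency and doubled; the truth layer contains no het
  inside any tract.
* **Observation error**: false heterozygotes are placed uniformly over truly
  homozygous sites at a genome-averaged rate per Mb — default 2.4/Mb for
  WGS (presets: 0.3 ZUL-like, 4.5 JPT-like), 0 for the array. Because the
  process acts on homozygous *sites*, the realized per-Mb density inside
  tracts (where every site is homozygous) exceeds the genome average by the
  inverse homozygous fraction; the total count per genome matches the
  configured rate. False homozygotes (allele dropout) hit truly het sites
  at rate 0.02 for WGS (either homozygote equally likely) and 0 for the
  array; missingness is 0.002 per call in both channels. Every observed het
  inside a tract is attributable to the recorded error list.
* **Determinism**: all randomness flows from the single config seed;
  identical seed and config give byte-identical VCFs and truth BED.

Truth evaluation is base-pair-level: per length class, sensitivity
(overlapped tract bp / tract bp), precision (overlapped called bp / called
bp, absent when nothing is called), tract recovery at >= 50% reciprocal
overlap, and calls-per-tract as a fragmentation measure.

## What the simulator does and does not show

Passing tests on these simulations demonstrate that the pipeline's
machinery is correct (caller matches an exhaustive reference, rates are
recovered, identities hold) and that planted autozygosity is recovered
essentially completely at h = 3. They do *not* demonstrate that uniform,
independent false hets reproduce the strong tolerance-sensitivity of ROH
calling reported for real low-coverage data. Indeed the window rule is
provably robust to unclustered errors: with a 5% window threshold a site
leaves the candidate state only when nearly all of its ~50 covering windows
exceed the tolerance, which at h = 1 requires two false hets within a
couple of sites of each other. At 2.4/Mb that coincidence is rare, so
fragmentation at h = 1 is mild and 20-vs-20 rank tests on NROH remain
non-significant at every h. Real low-coverage miscalls cluster — coverage
dips and misalignment produce bursts of errors — and that clustering, not
the marginal rate, is what makes h = 1 calling fragile on real data. The
generator deliberately keeps the uniform (autozygosity-blind, unclustered)
error process as its documented condition; an error-burst model is the
natural extension and is listed under limitations.

## Known limitations

* No LD, so the simulator cannot study false-positive short ROH arising
  from haplotype structure, nor array ascertainment of tag SNPs.
* Uniform error placement understates ROH fragmentation relative to real
  low-coverage data (see above); per-population error heterogeneity is a
  single rate dial.
* PLINK 1.9's undocumented boundary extension/trimming details may differ
  from this implementation at single-SNP scale on real data.
* PED/MAP input carries no reference allele; hom-ref/hom-alt labels from
  that reader are conventional unless reference alleles are supplied
  (het/hom status, which is all the caller consumes, is unaffected).
* The violin/heatmap helpers are conveniences; no numerical output depends
  on plotting.
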