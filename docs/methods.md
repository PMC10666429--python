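# Methods

This note documents the models, conventions and numerical choices behind
`faroh`, and what the synthetic cohorts do and do not establish about real
data.

## Genotype model and filtering

Genotypes are diploid codes {0 hom-ref, 1 het, 2 hom-alt, −1 missing} over
autosomal (chr 1–22) biallelic single-nucleotide sites, 1-based inclusive
coordinates throughout. Two site-filter profiles are supported at import:

* **basic** — `QUAL > 30`;
* **advanced** — additionally `FILTER == PASS` at the site and per-genotype
  used-read depth `FMT/DPU > 10`. The depth bound is applied per genotype
  (failing calls become missing, sites with no surviving call are dropped)
  because DPU is a FORMAT field; for single-sample inputs the distinction
  is moot, for merged inputs it is the only consistent rule. A missing
  depth field in advanced mode counts as failing and is logged.

Multiallelic records and indels are dropped, not split: the pipeline
targets per-sample variant-caller output in which biallelic SNP records are
selected upstream. `DPU` is treated as an opaque per-genotype integer; no
attempt is made to distinguish "depth used" from total depth.

**Merging** takes the union of sites keyed by (chrom, pos, ref, alt) and
marks a sample missing at every site its own input lacks. This reproduces
the characteristic behaviour of merged single-genome VCFs: missing rates
near 0.5, and a heterozygote deficit after complete-case filtering, because
private variants (called in one sample) are strongly enriched for
heterozygotes. Conflicting REF alleles at one position are fatal.

**QC** applies, in order: sample missingness (`mind_max`, default 0.1) →
site missingness (`geno_max`, 0.1) → Hardy–Weinberg (`hwe_p_min`, 1e-7).
The order is fixed and conventional; each stage logs counts. In the
orchestrated pipeline the sample-missingness ceiling is judged on each
input's *own* call set before merging, since post-merge missing rates
reflect sharing, not sample quality; site missingness and HWE run on the
merged matrix. With n = 8 and `geno_max = 0.1`, any site missing even one
call (rate 0.125) is removed, so all surviving sites have call rate 1.

The HWE test is the two-sided exact test: conditional on the allele
counts, the probabilities of all heterozygote configurations no more
probable than the observed one are summed (computed by log-gamma, with a
1e-12 relative tolerance on the inclusion comparison; the test suite
checks it against exact rational enumeration). Monomorphic sites return
p = 1. The test is skipped, with a log line, for single-sample matrices
where it is degenerate.

## Heterozygosity conventions

H is *SNP heterozygosity*: heterozygous / non-missing genotypes over the
variant sites present in the filtered matrix, with no monomorphic-genome
denominator. On this definition deep-sequenced single genomes sit near
H ≈ 0.6; it is sensitive to how the site set was ascertained, which is why
the call-rate decomposition (`het_by_call_rate`) is provided: overall H of
a merged matrix equals the call-weighted mean of the per-bin heterozygote
fractions exactly, and the drop of H after complete-case filtering is
attributable bin by bin.

maf uses minor-allele count / (2 × called samples at the site), so the
denominator shrinks with missingness. Summaries follow a
median/iqr/mean/sd convention: quantiles with linear interpolation
(type 7), sd with the n−1 denominator, a single value reporting sd = 0
with a degeneracy flag.

## Kinship

Both KING-style estimators are implemented from the four concordance
counts over pairwise-complete markers; relatedness is R = 2φ̂ exactly, and
negative estimates are reported untruncated (a flagging column marks
errors, not sign). The robust estimator relabels so that the individual
with the lower heterozygosity rate takes the normalising role; at equal
heterozygote counts it reduces algebraically to the within-family form,
which is used as the deterministic tie-break. Two marker-set modes exist:
`pairwise-shared` (markers non-missing in the two samples — estimates are
then invariant to adding cohort members) and `complete-case` (markers
called in every sample — the headline post-filter convention, default).
The two differ systematically on cohorts with private variation; both are
exposed and tested. No maf filtering and no LD pruning are applied
anywhere.

## ROH calling

The caller follows the PLINK `--homozyg` sliding-window dialect; see the
module docstring for the four steps. Numerical choices that PLINK leaves
implicit are fixed and documented:

* run length = inclusive bp span / 1000 (kb);
* missing genotypes count toward the per-window missing allowance but do
  not break runs; run boundaries are the outermost *supported homozygous*
  SNPs;
* only windows fully inside a chromosome are counted, so calls within
  ~50 SNPs of a chromosome end can differ marginally from PLINK's;
* no run-level heterozygote cap — het tolerance emerges from window
  support only.

Two presets: `plink-default` (gap 1000 kb, ≥100 SNPs) and `ref20` (gap
100 kb, ≥25 SNPs). The minimum-length sweep calls once at the smallest
grid value and filters emitted runs by length; this is exactly equivalent
to independent re-calls because window support does not depend on
`min_kb` (asserted against re-calls in the tests). NROH and SROH are
non-increasing and AVROH non-decreasing along the grid by construction.

## Inbreeding and founder dating

F_ROH>x divides per-sample SROH above x by L_aut = 2,881,033.286 kb (the
summed GRCh37 autosome lengths, stored per chromosome and summed at import
of the module); synthetic genomes pass their own length. R_ROH>x = 2
F_ROH>x rests on parental relatedness being twice the offspring's
inbreeding when common ancestors are themselves non-inbred. Aggregation
doubles per sample and then takes medians; since doubling is linear this
only matters at the rounding digit.

The bottleneck detector works on the NROH-versus-SROH plane with SROH in
Mb, diagonal NROH = SROH_Mb. The deviation is the signed *vertical* gap
d = SROH_Mb − NROH; whether the source convention is vertical, horizontal
or perpendicular is not determinable from the material available, so
vertical was chosen and the table of per-sample d values is exposed for
any other normalisation. L_min is the smallest grid length with d > 0 for
every sample; L_max maximises the median of d across samples (per-sample
argmaxima are also reported). Both are reported as undefined, with
diagnostics, when the sign condition never holds.

Dating inverts the exponential segment-length model, ĝ = 100 cM / (2L),
with 1 cM/Mb (configurable), generation time 26.9 y, and reference year
1960 (average birth year of a sampled cohort); the 2012 sampling-year
alternative shifts calendar years up by exactly 52. Start-bound years are
reported unrounded (0.7 Mb → year ≈ 38.6).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, at
a scale that runs in seconds:

* **allele frequencies** — alt frequency Beta(3, 3) by default, which
  makes the heterozygote fraction at a single genome's variant sites
  exactly 0.6, mixed with a rare-variant stratum (default 30% of sites,
  maf uniform on [0.001, 0.05]) to produce a rare-heavy maf spectrum;
* **pedigrees** — gene-drop with recombination on a 1 cM/Mb linear map,
  Haldane (Poisson, no-interference) crossovers; founder-haplotype labels
  are tracked so realised IBD kinship is recorded exactly alongside the
  pedigree expectation (the oracle for the kinship module);
* **founder autozygosity** — per sample, a Poisson number of
  non-overlapping homozygous tracts with exponential lengths of mean
  100/(2 g₀) cM, each copying one ancestral haplotype. Placement is
  longest-first rejection sampling (which preserves the iid length
  distribution) and fails loudly when the requested tract mass cannot fit;
  the defaults (200 tracts × 1 cM on an 800 Mb genome) put ~25% of the
  genome in ROH, the level seen in strongly bottlenecked isolates;
* **noise** — per-genotype miscalls (uniform flip to another code),
  missingness, QUAL (5% of sites below the 30 threshold by default),
  FILTER failures, and Poisson(37) per-genotype depth;
* **emission** — per-sample variant-only VCFs (the form single-genome
  callers produce, which drives the merge/missingness behaviour) or one
  multi-sample VCF with all genotypes; plus a JSON truth sidecar. Output
  is byte-identical for identical specs; all randomness derives from one
  master seed through named substreams.

A second generator plants explicit private/shared site strata (private
sites 80% heterozygous, shared 30% by default) to exercise the call-rate
decomposition with exact bookkeeping.

What the cohorts do **not** emulate: linkage disequilibrium outside
planted tracts and pedigree descent (sites are exchangeable given the
frequency model — deliberate, to keep oracles analytic), realistic
frequency spectra or LD of any particular population, sequencing-read
noise structure, sex chromosomes, or indels. Passing tests therefore
establish correctness of the estimators under their stated assumptions,
not calibration to any real cohort.

## Problem sizes and statistical design of the checks

Recovery checks run at sizes chosen for statistical resolution: gene-drop
kinship uses 40 replicate families on a 10-Morgan genome (realised
sib-pair kinship has SD ≈ 0.05 per pair, so the mean's standard error is
≈ 0.007, comfortably inside the ±0.02 acceptance band); founder-generation
recovery pools ≥480 planted segments so the exponential mean is estimated
to a few percent; the deviation-profile check uses the default cohort
(8 × 200 tracts), where the median-deviation peak at 1 Mb is sharp.

## Known limitations

* The ROH caller is a faithful but independent implementation of the
  window dialect; edge handling within one window of chromosome ends is
  documented above and may differ marginally from PLINK.
* `match_r_to_roh` is a nearest-neighbour lookup on a median table; it
  deliberately does not interpolate between grid lengths.
* Dating assumes a constant 1 cM/Mb map and a single-parameter exponential
  length model; segment-length censoring by the caller's minimum SNP count
  biases ĝ slightly upward if estimated from *called* rather than true
  segments.
* The subsampling extrapolation of merged-cohort H to larger n is not
  hard-coded; the machinery (merge + qc + stats) is exposed instead.
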