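# Methods

## The analysis

The pipeline consumes four tabular inputs — a gene-level raw count matrix,
a BED-like gene annotation carrying effective transcript lengths, a
per-SNP allele-depth table derived from RNA-seq variant calls, and a UCSC
cytoBand file — plus sample metadata mapping each sample to a study, a
pluripotency-state label (primed / naive / naive_high / naive_low /
male_primed) and a sex. It runs six stages in order; stages whose inputs
are absent are skipped with a logged notice.

1. **TPM.** Counts are divided by effective length, each column is
   normalized to sum to 10⁶. A sample with all-zero counts is an error.
2. **XIST status.** XIST⁺ iff TPM(XIST) > 1, strictly: a sample at
   exactly 1 TPM is XIST⁻. The strict call is the conservative resolution
   of an expressed/not-expressed threshold quoted from both sides.
3. **Allele-specific expression.** SNPs with total depth < 10 are
   dropped. The minor/major ratio min(ref,alt)/max(ref,alt) classifies a
   SNP as biallelic strictly above 0.2; at or below it is *uninformative*
   — never "monoallelic", since low ratios can reflect coverage or a
   missing polymorphism rather than silencing. NS for a chromosome is the
   biallelic-SNP count over the count of *all annotated genes* on that
   chromosome (an expressed-only denominator and a per-gene-collapsed
   numerator are exposed as options). The X:autosome ratio divides
   NS(chrX) by the unweighted mean of the autosomal NS values (a pooled
   autosomal mode is exposed); a zero autosomal mean flags the summary
   undefined instead of raising. XIST biallelism uses the median ratio
   across XIST SNPs with the same 0.2 threshold; values within ±0.02 of
   the threshold are logged as near-threshold, and no "borderline"
   category is returned.
4. **Geography.** For the moving-average analysis only, genes are first
   filtered to those expressed (TPM > 1 in at least one sample) and the
   top ceil(0.1·n) most variable (variance of log₂(TPM+1), ties broken by
   gene id) are removed. Each test sample's TPM is divided by the
   per-gene median of its study's baseline group with pseudocount
   ε = 0.01, restricted to genes whose baseline median TPM exceeds 1;
   log₂ fold changes are ordered by gene start (ties by gene id) and
   smoothed with a 50-gene window sliding by one gene, no partial windows.
   Group curves take the per-gene median within each study, then the
   median of study medians within the XIST⁺ or XIST⁻ group, then the
   window. The window applies an arithmetic mean — the median belongs to
   the cross-sample aggregation step — with a windowed-median mode
   exposed for sensitivity analysis. Region membership (e.g. Xq22,
   resolved from the cytoband file as the union of all bands matching the
   name prefix) is by gene midpoint, so each gene belongs to exactly one
   region.
5. **Epiblast score.** Selected single cells are summed into one
   pseudo-bulk column, TPM-normalized through the same code path, and
   each sample is scored by Pearson r on log₂(TPM+1) over the marker
   panel (raw-TPM mode exposed; fewer than 3 shared markers is an
   error). The log transform keeps one or two high-abundance markers from
   dominating r. The marker list and cell selection are inputs, never
   bundled claims.
6. **Comparisons.** Paired/unpaired t-tests and Mann–Whitney, always
   two-sided, delegated to scipy. Boxplot summaries use type-7 (linear
   interpolation) quartiles and the ggplot whisker rule — upper whisker
   min(max(x), Q3 + 1.5·IQR), lower max(min(x), Q1 − 1.5·IQR) — applied
   literally, so a whisker can sit at the fence itself.

A note on filter scope: the variable-gene filter exists to stabilize the
windowed profiles and is applied only there. The per-sample X-linked
expression summary (mean TPM over chromosome-X genes) uses the expressed
filter only; computed cohort-wide, the variance filter would
preferentially remove exactly the dosage-responsive genes that carry the
naive/primed contrast.

## The synthetic cohort generator

The generator emulates the data structure the analysis assumes under an
explicit latent truth, so each stage has a parameter-recovery test.

**Genome.** A synthetic chromosome X of 156.04 Mb with XIST at 73.8 Mb
and an Xq22 band union at 99.1–103.6 Mb (synthetic cytobands ship with
the cohort), plus 5 autosomes of 150 Mb. Default 300 genes on X and 300
per autosome, positions uniform, effective lengths log-normal around
1.5 kb. FGF4 and FGF2 are placed on autosomes for the high/low-naive
expression-ratio check.

**X-state maps.** Each female sample carries a segmentwise state of the
second X: `active` (dosage 2), `eroded_inactive` (dosage d_e, default
1.15), `inactive` (dosage 1). Presets:

- `primed_XaXe` — uniformly eroded, XIST level 0;
- `naive_xist_pos` — edges (0–50 Mb, 120–156 Mb) active, center
  (50–120 Mb, containing Xq22) inactive, XIST TPM drawn from 1.3–23;
- `naive_xist_neg` — uniformly eroded, XIST 0 (indistinguishable from
  primed along the chromosome);
- male samples carry a single X (dosage 1 everywhere, no heterozygous X
  SNPs).

This geometry jointly reproduces the target phenomenology relative to the
primed baseline: XIST⁺ naive profiles show elevated edges and a central
dip containing Xq22; XIST⁻ profiles are flat; XIST⁺ naive samples have
higher total X output and more biallelic X SNPs; primed-vs-male profiles
sit uniformly at log₂(d_e) > 0, confirming partial double-X dosage.

**Why d_e = 1.15.** The minor-allele read fraction at a heterozygous SNP
is tied to dosage: the partially active copy contributes (d−1)/d of the
reads, blended with a sequencing-error leak of 0.02 so a fully silenced
locus still shows 2% minor reads and a biallelic locus sits at exactly
0.5. A ratio threshold of 0.2 corresponds to a minor fraction of 1/6;
an eroded dosage must therefore stay below ≈1.17 for eroded loci to read
as mostly uninformative — the defining property of the eroded primed X,
whose reactivation is detectable in expression but largely sub-threshold
allelically. At 1.15 eroded loci are called biallelic ≈40% of the time
(beta-binomial spread around a mean fraction of 0.145), a genuinely
intermediate state between active (≈100%) and silenced (≪1%).

**Counts.** Per-copy baselines μ_g are log-normal (median 2, σ = 1 on the
natural-log scale). Sample expression is μ_g × dosage, times optional
per-gene multipliers (e.g. FGF4 ×8 in high-naive samples), times
mean-corrected log-normal noise (σ = 0.15). XIST's expression is solved
so its expected TPM equals the map's XIST level exactly. Reads are
negative-binomial around the library-scaled expected count (library mean
2×10⁷, dispersion 0.05, variance μ + 0.05μ²).

**Allele depths.** Each gene carries at most one usable heterozygous SNP
with probability 0.3 (multi-SNP genes via config); males have none on X.
Depth is Poisson with mean 30·d/2; the minor-allele count is
beta-binomial with the dosage-determined mean fraction and concentration
50; which physical allele (ref or alt) is the minor one is a fair coin,
recorded in the truth. Autosomes are all biallelic, giving the X:autosome
ratio its baseline. XIST itself receives biallelic SNPs only when
expressed.

**Epiblast signature.** A per-marker log-normal signature (median 4,
σ = 0.8 in log) defines the epiblast reference pattern; a sample with
epiblast weight w applies signature^w, rescaled so the marker set's total
library share is unchanged — the signature is a *pattern* among markers,
not a global up-regulation, and would otherwise distort TPM composition.
Naive XIST⁺ samples carry w = 1, XIST⁻ naive 0.6, primed 0.15. The
35 reference cells are naive-like with the full signature, 2×10⁵ reads
each, negative-binomial with dispersion 0.1. A uniform marker boost would
cancel in Pearson r on the log scale; the per-marker signature is what
makes the naive > primed ordering recoverable.

**Ground truth.** The cohort records μ, per-gene/sample dosage, expected
counts and TPM, every SNP's latent minor fraction and minor-allele
identity, per-sample state maps and XIST levels — sufficient to recompute
every expectation without re-simulation. Fixed seed ⇒ byte-identical
output files.

**What the simulation does not capture.** Real cohorts have batch and
protocol effects between studies, GC/length biases, genotype sharing
between samples from one line, multi-SNP phasing structure, partial
erosion that varies gene-by-gene rather than segment-by-segment, and an
epiblast reference measured with a different chemistry. Passing recovery
tests certifies the statistics and their implementation, not performance
on such confounders.

## Numerical choices

- Coordinates 0-based half-open internally; GTF-derived input converted
  on load; SNP positions 1-based on disk (as in VCF), 0-based in memory.
- Pseudocounts: 0.01 in fold changes and the FGF4/FGF2 ratio.
- All rankings and orderings carry deterministic tie-breaks (gene id).
- Degenerate inputs prefer flagged results over exceptions where a value
  is legitimately undefined (zero autosomal NS mean, non-positive primed
  correlation mean) and exceptions where the input is malformed.
- Reports serialize with sorted keys and 6-significant-digit rounding so
  identical inputs give byte-identical files.

## Problem sizes

The test suite and the acceptance script run entirely on simulated
cohorts: the standard cohort is 3 studies × (10 naïve + 10 primed +
2 male) over 1,800 genes; profile-localization replicates use 20 cohorts
of 1 study × (4 + 4); allele-fraction laws and the misclassification
bound use single-sample cohorts with 7,600 X genes (≥ 2,000 depth-passing
SNPs). These sizes give comfortable statistical margins for every
directional claim while keeping a full run to a few minutes.

## Known limitations

- No between-sample normalization beyond TPM (no TMM/quantile) and no
  differential-expression framework; contrasts are means and rank tests.
- No phasing: the pipeline never identifies *which* X is eroded.
- Region membership by midpoint makes boundary genes' assignment depend
  on annotation coordinates.
- The NS denominator counts annotated genes, so annotations of very
  different completeness are not directly comparable without the
  expressed-only option.
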