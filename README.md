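# xeprof

X-chromosome inactivation (XCI) and erosion profiling from bulk RNA-seq.

Female human embryonic stem cells in the conventional *primed* state
typically carry an eroded inactive X (XaXe): *XIST* is silenced and the
inactive X has partially regained activity. Resetting cells to the
*naïve* state can reactivate *XIST* and remodel the chromosome — but not
uniformly: distal regions reactivate while a central region downstream of
*XIST*, most clearly the Xq22 band, is silenced again. `xeprof` implements
the complete downstream analysis that detects and localizes this
remodelling from gene-level count matrices and heterozygous-SNP allele
depths, for anyone comparing pluripotent-state cohorts across studies.

## What it computes

- **TPM** per gene and sample: `TPM_g = (c_g / L_g) / Σ_g (c_g / L_g) × 10⁶`
  with `L_g` the effective transcript length; columns sum to 10⁶ exactly.
- **XIST status**: a sample is XIST⁺ iff TPM(XIST) > 1 (strict).
- **Allelic ratio** at a heterozygous SNP: `min(ref, alt) / max(ref, alt)`
  of the read depths; a SNP is *biallelic* if the ratio exceeds 0.2,
  otherwise *uninformative*. SNPs under 10 reads are discarded.
- **NS (normalized SNPs)** per chromosome: biallelic-SNP count divided by
  the chromosome's gene count; the **X:autosome allelic ratio** is
  `NS(chrX) / mean_autosomes(NS)` — higher means more biallelic X output.
- **Erosion geography**: per gene, `log₂((TPM_test + ε) / (median
  TPM_baseline + ε))`, ordered along chromosome X and smoothed with a
  50-gene sliding window; cross-sample aggregation is the median within
  each study, then the median of study medians per XIST group.
- **Region contrasts** (e.g. Xq22 vs. the whole chromosome) via paired
  t-tests or Mann–Whitney, plus ggplot-convention boxplot summaries.
- **Epiblast score**: Pearson r of log₂(TPM+1) against a pseudo-bulk
  pre-implantation-epiblast reference over a 47-gene marker panel.

A fully parameterized synthetic-cohort generator (negative-binomial
counts, beta-binomial allele depths, explicit per-sample X-state maps)
provides ground truth for every stage; see `docs/methods.md`.

## Worked example

```sh
xeprof simulate --preset multi_study --seed 7 --studies 2 --naive 3 --primed 3 --out demo
xeprof report --config demo/config.yaml --out demo/report.json
```

The first command writes a two-study cohort (study A XIST⁺, study B
XIST⁻, each 3 naïve + 3 primed + 2 male samples) with its ground truth;
the second runs every stage and writes one JSON report. From that report:

| sample      | XIST TPM | status | mean X TPM | X:autosome ratio |
|-------------|---------:|--------|-----------:|-----------------:|
| A_primed_00 |     0.00 | XIST⁻  |      358.2 |             0.32 |
| A_naive_00  |     8.53 | XIST⁺  |      496.1 |             0.60 |
| A_naive_01  |    16.12 | XIST⁺  |      469.7 |             0.62 |
| B_naive_00  |     0.00 | XIST⁻  |      358.2 |             0.40 |

The XIST⁺ naïve samples show both higher X-linked expression and more
biallelic X SNPs than their primed counterparts, while the XIST⁻ study is
indistinguishable from primed — the expected erosion biology. The group
profiles localize the change: the XIST⁺ moving-average minimum sits at
64.5 Mb (inside the simulated re-inactivated center, value −0.36), the
XIST⁻ profile is flat (minimum −0.04), and the Xq22 contrast reports a
region mean log₂ fold change of −0.18 against a chromosome mean of +0.12
(paired t, p = 0.040). Per-study epiblast naïve/primed correlation ratios
are 1.14 (A) and 1.10 (B).

Every subcommand (`simulate`, `tpm`, `xist`, `allelic`, `geography`,
`epiblast`, `report`) is a thin wrapper over the library functions in
`xeprof.*`; use the library directly for anything programmatic.

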