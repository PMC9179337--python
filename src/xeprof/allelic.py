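"""Allele-specific expression: SNP filtering, allelic ratios, biallelic calls,
the normalized-SNP (NS) statistic and the X:autosome allelic ratio.

At a heterozygous site the minor/major allelic ratio is
min(ref, alt) / max(ref, alt) of the read depths; a SNP with ratio strictly
above 0.2 is biallelic, at or below it is uninformative (never called
monoallelic — a low ratio can equally reflect coverage or a missing
polymorphism).  NS for a chromosome is the biallelic-SNP count divided by
that chromosome's annotated gene count; the X:autosome allelic ratio is
NS(chrX) / mean over autosomes of NS, with an unweighted mean across the
autosomes present in the annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GeneAnnotation, RegionSpec, X_CHROM, genes_in_region

logger = logging.getLogger(__name__)

MIN_SNP_DEPTH = 10
BIALLELIC_RATIO_THRESHOLD = 0.2
NEAR_THRESHOLD_MARGIN = 0.02

SNP_COLUMNS = ["chrom", "pos", "sample_id", "gene_id", "ref_depth", "alt_depth"]


@dataclass
class AllelicSummary:
    """Per-chromosome NS values and the X:autosome ratio for one sample."""

    sample_id: str
    ns_per_chrom: dict[str, float] = field(default_factory=dict)
    x_autosome_ratio: float = float("nan")
    undefined: bool = False  # autosomal NS mean was 0


def load_snp_table(path: str | Path) -> pd.DataFrame:
    """Read the SNP TSV (chrom, pos, sample_id, gene_id, ref_depth, alt_depth).

    Positions are 1-based in the file, as in VCF, and converted to 0-based
    on load.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    missing = set(SNP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing SNP table columns {sorted(missing)}")
    df = df[SNP_COLUMNS].copy()
    df["pos"] = df["pos"].astype(int) - 1
    df[["ref_depth", "alt_depth"]] = df[["ref_depth", "alt_depth"]].astype(int)
    if (df[["ref_depth", "alt_depth"]] < 0).any().any():
        raise ValueError(f"{path}: negative allele depths")
    return df


def write_snp_table(snps: pd.DataFrame, path: str | Path) -> None:
    out = snps[SNP_COLUMNS].copy()
    out["pos"] = out["pos"].astype(int) + 1  # back to 1-based on disk
    out.to_csv(path, sep="\t", index=False)


def load_snp_vcf(path: str | Path, gene_tag: str = "GENE") -> pd.DataFrame:
    """Read a minimal VCF with per-sample AD depths and a gene INFO tag.

    Accepts the dialect GATK-derived variant tables arrive in (one ALT
    allele per record, AD = ref,alt).  Positions become 0-based.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    rows = []
    vcf = VCF(str(path))
    samples = vcf.samples
    for variant in vcf:
        gene = variant.INFO.get(gene_tag)
        if gene is None:
            continue
        ad = variant.format("AD")
        if ad is None:
            continue
        for i, sample in enumerate(samples):
            ref_d, alt_d = int(ad[i][0]), int(ad[i][1])
            if ref_d < 0 or alt_d < 0:  # missing genotype encoded as -1
                continue
            rows.append((variant.CHROM, variant.POS - 1, sample, gene, ref_d, alt_d))
    return pd.DataFrame(rows, columns=SNP_COLUMNS)


def filter_snps(snps: pd.DataFrame, min_depth: int = MIN_SNP_DEPTH) -> pd.DataFrame:
    """Retain records whose total depth (ref + alt) is >= min_depth."""
    total = snps["ref_depth"] + snps["alt_depth"]
    kept = snps[total >= min_depth].copy()
    logger.info("depth filter: kept %d / %d SNP records (min_depth=%d)",
                len(kept), len(snps), min_depth)
    return kept


def allelic_ratio(ref_depth, alt_depth):
    """Minor/major ratio: min(ref, alt) / max(ref, alt), in [0, 1].

    Vectorized over array-likes; zero when one depth is zero; both zero is
    an error (such records should have been depth-filtered away).
    """
    ref = np.asarray(ref_depth, dtype=float)
    alt = np.asarray(alt_depth, dtype=float)
    total = ref + alt
    if np.any(total < 1):
        raise ValueError("allelic_ratio on a record with zero total depth")
    ratio = np.minimum(ref, alt) / np.maximum(ref, alt)
    return float(ratio) if ratio.ndim == 0 else ratio


def classify_biallelic(ref_depth, alt_depth,
                       threshold: float = BIALLELIC_RATIO_THRESHOLD):
    """True where the allelic ratio is strictly above the threshold.

    Exactly at the threshold the SNP is uninformative.  Ratios within
    ±0.02 of the threshold are counted and logged as near-threshold.
    """
    ratio = np.atleast_1d(allelic_ratio(ref_depth, alt_depth))
    near = int(np.sum(np.abs(ratio - threshold) <= NEAR_THRESHOLD_MARGIN))
    if near:
        logger.info("%d SNP(s) within %.2f of the biallelic threshold",
                    near, NEAR_THRESHOLD_MARGIN)
    calls = ratio > threshold
    return bool(calls[0]) if np.isscalar(ref_depth) else calls


def ns_per_chromosome(snps: pd.DataFrame, genes: GeneAnnotation,
                      sample_id: str,
                      threshold: float = BIALLELIC_RATIO_THRESHOLD,
                      per_gene: bool = False) -> dict[str, float]:
    """NS = biallelic SNP count / annotated gene count, per chromosome.

    Biallelic SNPs are counted per SNP record; ``per_gene=True`` instead
    counts genes carrying at least one biallelic SNP (sensitivity mode).
    The denominator is all annotated genes of the chromosome, regardless
    of expression.
    """
    sub = snps[snps["sample_id"] == sample_id]
    ns: dict[str, float] = {}
    for chrom in genes.chromosomes:
        n_genes = genes.n_genes(chrom)
        if n_genes == 0:
            continue
        chrom_snps = sub[sub["chrom"] == chrom]
        if len(chrom_snps) == 0:
            ns[chrom] = 0.0
            continue
        calls = classify_biallelic(chrom_snps["ref_depth"].to_numpy(),
                                   chrom_snps["alt_depth"].to_numpy(), threshold)
        if per_gene:
            n_biallelic = chrom_snps.loc[calls, "gene_id"].nunique()
        else:
            n_biallelic = int(np.sum(calls))
        ns[chrom] = n_biallelic / n_genes
    return ns


def x_autosome_ratio(snps: pd.DataFrame, genes: GeneAnnotation, sample_id: str,
                     threshold: float = BIALLELIC_RATIO_THRESHOLD,
                     pooled_autosomes: bool = False,
                     per_gene: bool = False) -> AllelicSummary:
    """X:autosome allelic ratio: NS(chrX) / mean over autosomes of NS.

    The default autosomal mean is unweighted across chromosomes; the
    pooled mode instead pools all autosomal SNPs and genes into a single
    NS value.  A zero autosomal mean flags the summary undefined rather
    than raising.
    """
    ns = ns_per_chromosome(snps, genes, sample_id, threshold, per_gene=per_gene)
    autosomes = [c for c in genes.autosomes if c in ns]
    if not autosomes:
        raise ValueError("no autosomal genes in the annotation")
    if pooled_autosomes:
        sub = snps[(snps["sample_id"] == sample_id) & snps["chrom"].isin(autosomes)]
        n_genes = sum(genes.n_genes(c) for c in autosomes)
        if len(sub):
            calls = classify_biallelic(sub["ref_depth"].to_numpy(),
                                       sub["alt_depth"].to_numpy(), threshold)
            n_bi = sub.loc[calls, "gene_id"].nunique() if per_gene else int(np.sum(calls))
        else:
            n_bi = 0
        autosome_mean = n_bi / n_genes
    else:
        autosome_mean = float(np.mean([ns[c] for c in autosomes]))
    summary = AllelicSummary(sample_id=sample_id, ns_per_chrom=ns)
    ns_x = ns.get(X_CHROM, 0.0)
    if autosome_mean == 0:
        summary.undefined = True
        logger.warning("sample %s: autosomal NS mean is 0; ratio undefined", sample_id)
    else:
        summary.x_autosome_ratio = ns_x / autosome_mean
    return summary


def xist_biallelism(snps: pd.DataFrame, xist_gene_id: str = "XIST",
                    min_depth: int = MIN_SNP_DEPTH,
                    threshold: float = BIALLELIC_RATIO_THRESHOLD) -> str:
    """Classify XIST allelic expression for one sample's SNP records.

    Returns ``insufficient_coverage`` when no XIST SNP passes the depth
    filter, ``biallelic`` when the median allelic ratio across passing
    XIST SNPs is strictly above the threshold, else
    ``monoallelic_or_uninformative``.
    """
    xist = snps[snps["gene_id"] == xist_gene_id]
    xist = filter_snps(xist, min_depth) if len(xist) else xist
    if len(xist) == 0:
        return "insufficient_coverage"
    ratios = allelic_ratio(xist["ref_depth"].to_numpy(), xist["alt_depth"].to_numpy())
    med = float(np.median(np.atleast_1d(ratios)))
    if abs(med - threshold) <= NEAR_THRESHOLD_MARGIN:
        logger.info("XIST median allelic ratio %.3f is near the %.2f threshold",
                    med, threshold)
    return "biallelic" if med > threshold else "monoallelic_or_uninformative"


def biallelic_fraction(snps: pd.DataFrame, genes: GeneAnnotation, sample_id: str,
                       region: RegionSpec | None = None,
                       chrom: str = X_CHROM,
                       threshold: float = BIALLELIC_RATIO_THRESHOLD) -> float:
    """Fraction of (depth-passing) SNPs called biallelic on a chromosome,
    optionally restricted to genes whose midpoint falls in ``region``.

    NaN when no SNPs qualify.
    """
    sub = snps[(snps["sample_id"] == sample_id) & (snps["chrom"] == chrom)]
    if region is not None:
        region_ids = {g.gene_id for g in genes_in_region(genes, region)}
        sub = sub[sub["gene_id"].isin(region_ids)]
    if len(sub) == 0:
        return float("nan")
    calls = classify_biallelic(sub["ref_depth"].to_numpy(),
                               sub["alt_depth"].to_numpy(), threshold)
    return float(np.mean(calls))
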