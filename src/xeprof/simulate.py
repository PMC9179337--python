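"""Synthetic cohort generator with known X-inactivation ground truth.

Emulates the data the analysis consumes — gene-level RNA-seq counts,
heterozygous-SNP allele depths, annotation, cytobands, marker panel and an
epiblast-like single-cell matrix — under explicit per-sample X-state maps,
so every downstream stage has a parameter-recovery test against recorded
latent truth.

The generative model: each gene g has a per-copy baseline expression
mu_g ~ log-normal; a sample's expression is mu_g * dosage(g) where dosage
is 2 at biallelically active loci (and autosomes), 1 where the second copy
is silenced, and an intermediate value (default 1.5) where the inactive X
is eroded.  Counts are negative-binomial around the library-scaled
expected read count; allele depths at heterozygous SNPs are beta-binomial
with minor-allele mean 0.5 at biallelic loci, the sequencing-error leak
(default 0.02) at monoallelic loci, and (d-1)/d blended with the leak at
eroded loci.  Male samples carry a single X (dosage 1, no heterozygous X
SNPs).  Fixing the seed makes every output byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .allelic import SNP_COLUMNS
from .epiblast import MarkerPanel, write_marker_panel
from .expression import SampleTable, write_table
from .genome import (Cytoband, CytobandMap, GeneAnnotation, GeneModel,
                     X_CHROM, write_annotation)

logger = logging.getLogger(__name__)

# synthetic genome layout (loosely modeled on GRCh38 scale)
CHRX_LENGTH = 156_040_000
AUTOSOME_LENGTH = 150_000_000
XIST_START, XIST_END = 73_820_000, 73_852_000
XIST_LENGTH = 19_280  # mature transcript scale
#: central segment silenced/eroded in the presets; contains Xq22
CENTER_START, CENTER_END = 50_000_000, 120_000_000
XQ22_START, XQ22_END = 99_100_000, 103_600_000

STATE_DOSAGE_EXPONENTS = ("active", "eroded_inactive", "inactive")

#: synthetic chrX cytobands; only the q22 sub-bands matter downstream
SYNTHETIC_CHRX_BANDS = [
    ("p22", 0, 10_000_000, "gneg"),
    ("p21", 10_000_000, 37_000_000, "gpos50"),
    ("p11", 37_000_000, 58_000_000, "gneg"),
    ("q11", 58_000_000, 63_000_000, "acen"),
    ("q13", 63_000_000, 76_000_000, "gneg"),
    ("q21", 76_000_000, XQ22_START, "gpos75"),
    ("q22.1", XQ22_START, 100_300_000, "gneg"),
    ("q22.2", 100_300_000, 101_400_000, "gpos25"),
    ("q22.3", 101_400_000, XQ22_END, "gneg"),
    ("q23", XQ22_END, 110_000_000, "gpos50"),
    ("q24", 110_000_000, 118_000_000, "gneg"),
    ("q25", 118_000_000, 130_000_000, "gpos100"),
    ("q26", 130_000_000, 139_000_000, "gneg"),
    ("q27", 139_000_000, 148_000_000, "gpos50"),
    ("q28", 148_000_000, CHRX_LENGTH, "gneg"),
]


@dataclass(frozen=True)
class XStateMap:
    """Segmentwise X-inactivation state of the second X chromosome.

    ``segments`` is a list of (start, end, state) tiling [0, chrx_length)
    without gaps or overlap; states are active / eroded_inactive /
    inactive.  ``xist_level`` is the expected XIST TPM.
    """

    segments: tuple[tuple[int, int, str], ...]
    xist_level: float
    chrx_length: int = CHRX_LENGTH

    def __post_init__(self) -> None:
        if self.xist_level < 0:
            raise ValueError("xist_level must be >= 0")
        segs = sorted(self.segments)
        if not segs or segs[0][0] != 0 or segs[-1][1] != self.chrx_length:
            raise ValueError("segments must tile [0, chrx_length)")
        for (s0, e0, st), (s1, _, _) in zip(segs, segs[1:]):
            if e0 != s1:
                raise ValueError("segments must tile without gaps or overlap")
        for _, _, st in segs:
            if st not in STATE_DOSAGE_EXPONENTS:
                raise ValueError(f"unknown segment state {st!r}")

    def state_at(self, position: float) -> str:
        for start, end, state in self.segments:
            if start <= position < end:
                return state
        raise ValueError(f"position {position} outside chromosome X")


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    study: str
    state: str  # primed | naive | naive_high | naive_low | male_primed
    x_state: XStateMap
    sex: str = "female"
    gene_multipliers: dict = field(default_factory=dict)
    epiblast_weight: float = 0.0  # 0..1 strength of the marker-gene signature


@dataclass
class SimConfig:
    """All knobs of the generator; the defaults define the study conditions."""

    samples: list[SampleSpec]
    n_genes_X: int = 300
    n_genes_autosome: int = 300  # per autosome
    n_autosomes: int = 5
    nb_dispersion: float = 0.05
    libsize_mean: float = 2e7
    het_snp_rate: float = 0.3
    mono_allele_leak: float = 0.02
    bb_concentration: float = 50.0
    eroded_dosage: float = 1.15
    snp_depth_mean: float = 30.0
    expr_noise_sd: float = 0.15  # natural-log-scale, mean-corrected
    marker_boost: float = 4.0
    n_markers: int = 47
    n_epiblast_cells: int = 35
    cell_libsize_mean: float = 2e5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("config has no samples")
        if self.n_genes_X <= 0 or self.n_genes_autosome <= 0:
            raise ValueError("gene counts must be positive")
        for rate in (self.het_snp_rate, self.mono_allele_leak):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.nb_dispersion <= 0 or self.bb_concentration <= 0:
            raise ValueError("dispersions must be positive")
        if not 1.0 <= self.eroded_dosage <= 2.0:
            raise ValueError("eroded_dosage must lie in [1, 2]")


@dataclass
class Cohort:
    """An in-memory simulated cohort plus its latent ground truth."""

    annotation: GeneAnnotation
    counts: SampleTable
    snps: pd.DataFrame
    cytobands: CytobandMap
    marker_panel: MarkerPanel
    epiblast_cells: pd.DataFrame  # genes x cells raw counts
    truth: dict


# ---------------------------------------------------------------------------
# presets

def synthetic_cytobands() -> CytobandMap:
    return CytobandMap([Cytoband(X_CHROM, s, e, name, stain)
                        for name, s, e, stain in SYNTHETIC_CHRX_BANDS])


def preset_state_map(kind: str, chrx_length: int = CHRX_LENGTH,
                           xist_level: float | None = None) -> XStateMap:
    """The three study-condition X-state maps.

    ``primed_XaXe``: uniformly eroded (the second X partially active
    everywhere), XIST silent.  ``naive_xist_pos``: distal edges fully
    reactivated, the central region including Xq22 re-inactivated, XIST
    expressed.  ``naive_xist_neg``: uniformly eroded with XIST silent —
    indistinguishable from primed along the chromosome.

    Relative to the primed baseline this geometry yields the observed
    naive XIST+ pattern: elevated distal edges, a clear dip in the middle
    downstream of XIST, overall higher X output and more biallelic SNPs;
    XIST- naive samples show no regional pattern.
    """
    edges_mid = lambda mid_state: (
        (0, CENTER_START, "active"),
        (CENTER_START, CENTER_END, mid_state),
        (CENTER_END, chrx_length, "active"),
    )
    if kind == "primed_XaXe":
        return XStateMap(((0, chrx_length, "eroded_inactive"),),
                         xist_level=0.0 if xist_level is None else xist_level,
                         chrx_length=chrx_length)
    if kind == "naive_xist_pos":
        return XStateMap(edges_mid("inactive"),
                         xist_level=10.0 if xist_level is None else xist_level,
                         chrx_length=chrx_length)
    if kind == "naive_xist_neg":
        return XStateMap(((0, chrx_length, "eroded_inactive"),),
                         xist_level=0.0 if xist_level is None else xist_level,
                         chrx_length=chrx_length)
    raise ValueError(f"unknown preset kind {kind!r}")


def male_state_map(chrx_length: int = CHRX_LENGTH) -> XStateMap:
    """Single-X male: modeled as a uniformly 'inactive' second X (dosage 1)."""
    return XStateMap(((0, chrx_length, "inactive"),), xist_level=0.0,
                     chrx_length=chrx_length)


def multi_study_config(seed: int, n_studies: int = 3, n_naive: int = 10,
                        n_primed: int = 10, n_male: int = 2,
                        n_xist_neg_studies: int = 1, **overrides) -> SimConfig:
    """The default multi-study cohort: per study, primed XaXe + naive samples.

    The last ``n_xist_neg_studies`` studies are XIST- (uniformly eroded,
    weaker epiblast signature); the rest are XIST+ with XIST TPM drawn
    uniformly from the 1.3-23 range.  Each study also carries a few male
    primed samples as the single-X baseline.
    """
    rng = np.random.default_rng(seed)
    primed_map = preset_state_map("primed_XaXe")
    samples: list[SampleSpec] = []
    for i in range(n_studies):
        study = chr(ord("A") + i)
        xist_pos = i < n_studies - n_xist_neg_studies
        for j in range(n_primed):
            samples.append(SampleSpec(f"{study}_primed_{j:02d}", study, "primed",
                                      primed_map, epiblast_weight=0.15))
        for j in range(n_naive):
            if xist_pos:
                level = float(rng.uniform(1.3, 23.0))
                x_map = preset_state_map("naive_xist_pos", xist_level=level)
                weight = 1.0
            else:
                x_map = preset_state_map("naive_xist_neg")
                weight = 0.6
            samples.append(SampleSpec(f"{study}_naive_{j:02d}", study, "naive",
                                      x_map, epiblast_weight=weight))
        for j in range(n_male):
            samples.append(SampleSpec(f"{study}_male_{j:02d}", study, "male_primed",
                                      male_state_map(), sex="male",
                                      epiblast_weight=0.15))
    overrides.setdefault("seed", int(rng.integers(2**31)))
    return SimConfig(samples=samples, **overrides)


def high_low_naive_config(seed: int, n_lines: int = 4, n_each: int = 2,
                          fgf4_boost: float = 8.0, **overrides) -> SimConfig:
    """High- vs low-naive samples: high-naive have boosted FGF4 and higher XIST."""
    samples: list[SampleSpec] = []
    rng = np.random.default_rng(seed)
    for i in range(n_lines):
        line = f"line{i + 1}"
        for j in range(n_each):
            high_map = preset_state_map(
                "naive_xist_pos", xist_level=float(rng.uniform(12, 23)))
            low_map = preset_state_map(
                "naive_xist_pos", xist_level=float(rng.uniform(1.3, 8)))
            samples.append(SampleSpec(f"{line}_high_{j}", line, "naive_high",
                                      high_map, gene_multipliers={"FGF4": fgf4_boost},
                                      epiblast_weight=1.0))
            samples.append(SampleSpec(f"{line}_low_{j}", line, "naive_low",
                                      low_map, epiblast_weight=0.5))
    overrides.setdefault("seed", int(rng.integers(2**31)))
    return SimConfig(samples=samples, **overrides)


# ---------------------------------------------------------------------------
# core generator

def _dosage(state: str, eroded_dosage: float) -> float:
    return {"active": 2.0, "eroded_inactive": eroded_dosage, "inactive": 1.0}[state]


def _make_annotation(config: SimConfig, rng: np.random.Generator) -> GeneAnnotation:
    genes: list[GeneModel] = []

    def draw_genes(chrom: str, chrom_len: int, n: int, prefix: str,
                   named: dict[str, tuple[int, int, int]] | None = None):
        if named:
            for gid, (start, end, length) in named.items():
                genes.append(GeneModel(gid, chrom, start, end, length))
        n_random = n - (len(named) if named else 0)
        spans = rng.integers(5_000, 200_000, size=n_random)
        starts = rng.integers(0, chrom_len - 200_000, size=n_random)
        lengths = np.maximum(200, rng.lognormal(np.log(1500), 0.6, size=n_random)
                             ).astype(int)
        for i in range(n_random):
            genes.append(GeneModel(f"{prefix}{i:04d}", chrom, int(starts[i]),
                                   int(starts[i] + spans[i]), int(lengths[i])))

    draw_genes(X_CHROM, CHRX_LENGTH, config.n_genes_X, "gX_",
               named={"XIST": (XIST_START, XIST_END, XIST_LENGTH)})
    for a in range(1, config.n_autosomes + 1):
        named = {}
        if a == 1:
            named["FGF4"] = (60_000_000, 60_002_000, 1_200)
        if a == 2:
            named["FGF2"] = (80_000_000, 80_070_000, 1_800)
        draw_genes(f"chr{a}", AUTOSOME_LENGTH, config.n_genes_autosome,
                   f"g{a}_", named=named)
    return GeneAnnotation(genes)


def _expression_matrix(config: SimConfig, annotation: GeneAnnotation,
                       mu: pd.Series, signature: pd.Series,
                       rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expected expression e_gs (transcript units) and dosage per gene/sample.

    ``signature`` holds per-marker epiblast multipliers; a sample with
    epiblast weight w applies signature**w, so the marker-gene *pattern*
    (not just its level) is shared with the epiblast reference in
    proportion to w.
    """
    gene_ids = list(mu.index)
    chrom_of = annotation.chrom_of()
    midpoints = {g.gene_id: g.midpoint for g in annotation}
    e = pd.DataFrame(index=gene_ids, columns=[s.sample_id for s in config.samples],
                     dtype=float)
    dosage = e.copy()
    for spec in config.samples:
        dos = np.empty(len(gene_ids))
        for i, gid in enumerate(gene_ids):
            if chrom_of[gid] != X_CHROM:
                dos[i] = 2.0
            elif spec.sex == "male":
                dos[i] = 1.0
            else:
                dos[i] = _dosage(spec.x_state.state_at(midpoints[gid]),
                                 config.eroded_dosage)
        expr = mu.to_numpy() * dos
        for gid, mult in spec.gene_multipliers.items():
            expr[gene_ids.index(gid)] *= mult
        if spec.epiblast_weight > 0 and len(signature):
            idx = [gene_ids.index(gid) for gid in signature.index]
            before = expr[idx].sum()
            expr[idx] *= signature.to_numpy() ** spec.epiblast_weight
            # keep the marker set's library share fixed: the signature is a
            # pattern among markers, not a global up-regulation
            expr[idx] *= before / expr[idx].sum()
        # XIST expression set so its expected TPM equals the map's xist_level
        xi = gene_ids.index("XIST")
        expr[xi] = 0.0
        level = spec.x_state.xist_level
        if level > 0:
            expr[xi] = level * expr.sum() / (1e6 - level)
        dos[xi] = float("nan")
        e[spec.sample_id] = expr
        dosage[spec.sample_id] = dos
    return e, dosage


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    r = 1.0 / dispersion
    p = r / (r + mean[pos])
    out[pos] = rng.negative_binomial(r, p, size=int(pos.sum()))
    return out


def _betabin_draw(rng: np.random.Generator, n: np.ndarray, p: np.ndarray,
                  concentration: float) -> np.ndarray:
    alpha = np.maximum(p * concentration, 1e-12)
    beta = np.maximum((1.0 - p) * concentration, 1e-12)
    frac = rng.beta(alpha, beta)
    return rng.binomial(n.astype(np.int64), frac)


def minor_allele_fraction(dosage: float, leak: float) -> float:
    """Expected minor-allele read fraction at a het SNP with copy dosage d.

    The silenced/partial copy contributes (d-1)/d of the reads; the
    sequencing-error leak blends in so a fully monoallelic locus still
    shows ``leak`` and a biallelic locus stays at exactly 0.5.
    """
    raw = (dosage - 1.0) / dosage
    return leak + (1.0 - 2.0 * leak) * raw


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate the full cohort; same config (incl. seed) => identical output."""
    rng = np.random.default_rng(config.seed)
    annotation = _make_annotation(config, rng)
    gene_ids = [g.gene_id for chrom in annotation.chromosomes
                for g in annotation.genes_on(chrom)]
    mu = pd.Series(rng.lognormal(np.log(2.0), 1.0, size=len(gene_ids)),
                   index=gene_ids)
    lengths = pd.Series(annotation.lengths())[gene_ids].astype(float)

    autosomal_ids = [g for g in gene_ids
                     if annotation[g].chrom != X_CHROM and g not in ("FGF4", "FGF2")]
    markers = sorted(rng.choice(autosomal_ids, size=config.n_markers, replace=False))
    panel = MarkerPanel(tuple(markers), source="synthetic epiblast markers")
    # per-marker epiblast signature, median marker_boost, spread on log scale
    signature = pd.Series(
        rng.lognormal(np.log(config.marker_boost), 0.8, size=len(markers)),
        index=markers)

    e, dosage = _expression_matrix(config, annotation, mu, signature, rng)

    # per-sample multiplicative expression noise, mean-corrected on natural scale
    sd = config.expr_noise_sd
    if sd > 0:
        noise = rng.lognormal(-0.5 * sd**2, sd, size=e.shape)
        e_noisy = e * noise
    else:
        e_noisy = e.copy()

    # counts: library-scaled read mass proportional to expression * length
    read_mass = e_noisy.mul(lengths, axis=0)
    expected_counts = read_mass.div(read_mass.sum(axis=0), axis=1) * config.libsize_mean
    counts = pd.DataFrame(
        _nb_draw(rng, expected_counts.to_numpy(), config.nb_dispersion),
        index=e.index, columns=e.columns)
    expected_tpm = e.div(e.sum(axis=0), axis=1) * 1e6

    meta = pd.DataFrame(
        [{"sample_id": s.sample_id, "study": s.study, "state": s.state,
          "sex": s.sex} for s in config.samples]).set_index("sample_id")
    table = SampleTable(counts.astype(float), meta, kind="counts")

    snps, snp_truth = _simulate_snps(config, annotation, dosage, rng)
    cells = _simulate_epiblast_cells(config, annotation, mu, signature, lengths, rng)

    truth = {
        "mu": mu,
        "dosage": dosage,
        "expected_counts": expected_counts,
        "expected_tpm": expected_tpm,
        "snp_truth": snp_truth,
        "xist_level": {s.sample_id: s.x_state.xist_level for s in config.samples},
        "x_state": {s.sample_id: s.x_state for s in config.samples},
        "markers": markers,
        "marker_signature": signature,
        "config": config,
    }
    return Cohort(annotation=annotation, counts=table, snps=snps,
                  cytobands=synthetic_cytobands(), marker_panel=panel,
                  epiblast_cells=cells, truth=truth)


def _simulate_snps(config: SimConfig, annotation: GeneAnnotation,
                   dosage: pd.DataFrame, rng: np.random.Generator):
    """One heterozygous SNP per gene at most (default), beta-binomial depths."""
    rows, truth_rows = [], []
    chrom_of = annotation.chrom_of()
    spans = {g.gene_id: (g.start, g.end) for g in annotation}
    for spec in config.samples:
        dcol = dosage[spec.sample_id]
        for gid in dosage.index:
            chrom = chrom_of[gid]
            if gid == "XIST":
                # XIST itself: het SNP only when expressed; biallelic in XIST+
                if spec.x_state.xist_level <= 0 or spec.sex == "male":
                    continue
                if rng.random() >= config.het_snp_rate:
                    continue
                p_minor, dos = 0.5, 2.0
            else:
                if chrom == X_CHROM and spec.sex == "male":
                    continue  # hemizygous: no het X sites
                if rng.random() >= config.het_snp_rate:
                    continue
                dos = float(dcol[gid])
                p_minor = minor_allele_fraction(dos, config.mono_allele_leak)
            depth = int(rng.poisson(config.snp_depth_mean * dos / 2.0))
            if depth == 0:
                continue
            minor = int(_betabin_draw(rng, np.array([depth]),
                                      np.array([p_minor]),
                                      config.bb_concentration)[0])
            minor_is_alt = bool(rng.random() < 0.5)
            ref_d, alt_d = (depth - minor, minor) if minor_is_alt else (minor, depth - minor)
            pos = int(rng.integers(spans[gid][0], spans[gid][1]))
            rows.append((chrom, pos, spec.sample_id, gid, ref_d, alt_d))
            truth_rows.append((chrom, pos, spec.sample_id, gid, p_minor,
                               minor_is_alt, dos))
    snps = pd.DataFrame(rows, columns=SNP_COLUMNS)
    snp_truth = pd.DataFrame(truth_rows, columns=[
        "chrom", "pos", "sample_id", "gene_id", "p_minor", "minor_is_alt", "dosage"])
    return snps, snp_truth


def _simulate_epiblast_cells(config: SimConfig, annotation: GeneAnnotation,
                             mu: pd.Series, signature: pd.Series,
                             lengths: pd.Series, rng: np.random.Generator) -> pd.DataFrame:
    """Pre-implantation-epiblast-like cells: naive-like dosage, full signature."""
    naive_map = preset_state_map("naive_xist_pos")
    midpoints = {g.gene_id: g.midpoint for g in annotation}
    chrom_of = annotation.chrom_of()
    dos = np.array([
        2.0 if chrom_of[g] != X_CHROM
        else _dosage(naive_map.state_at(midpoints[g]), config.eroded_dosage)
        for g in mu.index])
    expr = mu.to_numpy() * dos
    gene_list = list(mu.index)
    idx = [gene_list.index(gid) for gid in signature.index]
    before = expr[idx].sum()
    expr[idx] *= signature.to_numpy()
    expr[idx] *= before / expr[idx].sum()
    expr[list(mu.index).index("XIST")] = 0.0
    mass = expr * lengths.to_numpy()
    n_cells = config.n_epiblast_cells
    cols = {}
    for c in range(n_cells):
        noise = rng.lognormal(-0.5 * 0.3**2, 0.3, size=len(expr))
        cell_mass = mass * noise
        mean = cell_mass / cell_mass.sum() * config.cell_libsize_mean
        cols[f"epi_cell_{c:02d}"] = _nb_draw(rng, mean, 0.1)
    return pd.DataFrame(cols, index=mu.index).astype(float)


# ---------------------------------------------------------------------------
# analytic oracles

def analytic_biallelic_rate(depths, p_minor: float, concentration: float,
                            threshold: float = 0.2) -> float:
    """Exact probability a beta-binomial het SNP is called biallelic.

    The minor/major ratio exceeds ``threshold`` iff the minor count x
    satisfies x/(n-x) > t and (n-x)/x > t, i.e. n*t/(1+t) < x < n/(1+t).
    Averaged over the supplied depths.
    """
    a = p_minor * concentration
    b = (1.0 - p_minor) * concentration
    probs = []
    for n in np.asarray(depths, dtype=int):
        x = np.arange(n + 1)
        lo, hi = n * threshold / (1 + threshold), n / (1 + threshold)
        mask = (x > lo) & (x < hi)
        probs.append(stats.betabinom.pmf(x[mask], n, a, b).sum())
    return float(np.mean(probs))


# ---------------------------------------------------------------------------
# serialization

def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write every table in the TSV/VCF dialects the loaders read.

    Returns a name -> path map.  Output is byte-identical for identical
    cohorts (fixed column order and float formatting).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": outdir / "annotation.tsv",
        "counts": outdir / "counts.tsv",
        "snps": outdir / "snps.tsv",
        "snps_vcf": outdir / "snps.vcf",
        "metadata": outdir / "metadata.tsv",
        "cytobands": outdir / "cytoBand.txt",
        "markers": outdir / "markers.txt",
        "epiblast_cells": outdir / "epiblast_cells.tsv",
        "truth": outdir / "truth.json",
    }
    write_annotation(cohort.annotation, paths["annotation"])
    write_table(cohort.counts, paths["counts"], float_format="%.0f")
    from .allelic import write_snp_table
    write_snp_table(cohort.snps, paths["snps"])
    _write_snp_vcf(cohort.snps, paths["snps_vcf"])
    with open(paths["metadata"], "w") as fh:
        fh.write("sample_id\tstudy\tstate\tsex\n")
        for sid, row in cohort.counts.meta.iterrows():
            fh.write(f"{sid}\t{row['study']}\t{row['state']}\t{row['sex']}\n")
    with open(paths["cytobands"], "w") as fh:
        for b in cohort.cytobands.bands:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.name}\t{b.stain}\n")
    write_marker_panel(cohort.marker_panel, paths["markers"])
    with open(paths["epiblast_cells"], "w") as fh:
        fh.write("#gene_id\t" + "\t".join(cohort.epiblast_cells.columns) + "\n")
        cohort.epiblast_cells.to_csv(fh, sep="\t", header=False, float_format="%.0f")
    _write_truth(cohort, paths["truth"])
    return paths


def _write_snp_vcf(snps: pd.DataFrame, path: Path) -> None:
    """Minimal VCF (one ALT, AD depths, GENE info tag) for format tests."""
    samples = sorted(snps["sample_id"].unique())
    sites = snps.groupby(["chrom", "pos", "gene_id"], sort=True)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        for chrom in sorted(snps["chrom"].unique()):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for (chrom, pos, gene), grp in sites:
            per_sample = {r.sample_id: (r.ref_depth, r.alt_depth)
                          for r in grp.itertuples()}
            cells = []
            for s in samples:
                if s in per_sample:
                    rd, ad = per_sample[s]
                    cells.append(f"0/1:{rd},{ad}")
                else:
                    cells.append("./.:.")
            fh.write(f"{chrom}\t{pos + 1}\t.\tA\tG\t.\tPASS\tGENE={gene}\t"
                     f"GT:AD\t" + "\t".join(cells) + "\n")


def _write_truth(cohort: Cohort, path: Path) -> None:
    truth = cohort.truth
    config = truth["config"]
    record = {
        "seed": config.seed,
        "eroded_dosage": config.eroded_dosage,
        "mono_allele_leak": config.mono_allele_leak,
        "bb_concentration": config.bb_concentration,
        "nb_dispersion": config.nb_dispersion,
        "markers": list(truth["markers"]),
        "xist_level": truth["xist_level"],
        "x_state": {
            sid: {"segments": [list(seg) for seg in m.segments],
                  "xist_level": m.xist_level}
            for sid, m in truth["x_state"].items()},
        "mu": {g: float(v) for g, v in truth["mu"].items()},
        "samples": [
            {"sample_id": s.sample_id, "study": s.study, "state": s.state,
             "sex": s.sex, "epiblast_weight": s.epiblast_weight,
             "gene_multipliers": s.gene_multipliers}
            for s in config.samples],
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=None, sort_keys=True, separators=(",", ":"))
        fh.write("\n")
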