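"""End-to-end pipeline: expression -> XIST -> allelic -> geography -> epiblast.

``run_pipeline`` consumes the tabular inputs (counts, annotation, SNP
table, cytobands, marker panel, metadata), executes every stage whose
inputs are present, and returns a fully recomputable report.  Stages with
absent inputs are skipped with a logged notice.  The same config and
inputs always produce a byte-identical serialized report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import allelic as al
from . import epiblast as epi
from . import expression as expr
from . import geography as geo
from .compare import compare as compare_groups
from .genome import (GeneAnnotation, RegionSpec, X_CHROM, load_annotation,
                     load_cytobands, resolve_region)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds of one pipeline run.

    Thresholds default to the analysis constants: XIST called expressed
    above 1 TPM, SNPs kept from 10 reads, biallelic above a 0.2
    minor/major ratio, 50-gene windows, top 10% variable genes removed,
    0.01 pseudocount in fold changes.
    """

    annotation: str | Path | None = None
    counts: str | Path | None = None
    snp_table: str | Path | None = None
    cytobands: str | Path | None = None
    marker_panel: str | Path | None = None
    metadata: str | Path | None = None
    epiblast_cells: str | Path | None = None

    xist_tpm: float = 1.0
    biallelic_ratio: float = 0.2
    snp_min_depth: int = 10
    window: int = 50
    variable_gene_fraction: float = 0.1
    pseudocount: float = 0.01
    region: str = "q22"
    xist_gene_id: str = "XIST"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("xist_tpm", "biallelic_ratio", "snp_min_depth", "window",
                     "variable_gene_fraction", "pseudocount"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        paths = raw.pop("paths", {})
        cfg = cls(**{**paths, **raw})
        base = Path(path).parent
        for name in ("annotation", "counts", "snp_table", "cytobands",
                     "marker_panel", "metadata", "epiblast_cells"):
            value = getattr(cfg, name)
            if value is not None:
                p = Path(value)
                setattr(cfg, name, p if p.is_absolute() else base / p)
        return cfg

    def provenance(self) -> dict:
        thresholds = {
            "xist_tpm": self.xist_tpm, "biallelic_ratio": self.biallelic_ratio,
            "snp_min_depth": self.snp_min_depth, "window": self.window,
            "variable_gene_fraction": self.variable_gene_fraction,
            "pseudocount": self.pseudocount, "region": self.region,
        }
        digest = hashlib.sha256(
            json.dumps(thresholds, sort_keys=True).encode()).hexdigest()[:16]
        return {"thresholds": thresholds, "seed": self.seed, "config_hash": digest}


@dataclass
class Report:
    """Consolidated pipeline output; every number recomputable from inputs."""

    provenance: dict = field(default_factory=dict)
    xist_calls: list = field(default_factory=list)
    xlinked_mean_tpm: dict = field(default_factory=dict)
    fgf_ratio: dict = field(default_factory=dict)
    allelic_summaries: dict = field(default_factory=dict)
    xist_biallelism: dict = field(default_factory=dict)
    profiles: dict = field(default_factory=dict)
    region_contrasts: dict = field(default_factory=dict)
    epiblast_scores: dict = field(default_factory=dict)
    naive_primed_ratio: dict = field(default_factory=dict)
    comparisons: dict = field(default_factory=dict)
    stages_run: list = field(default_factory=list)

    def to_json(self) -> str:
        def default(obj):
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            raise TypeError(f"not serializable: {type(obj)}")

        payload = {
            "provenance": self.provenance,
            "stages_run": self.stages_run,
            "xist_calls": self.xist_calls,
            "xlinked_mean_tpm": self.xlinked_mean_tpm,
            "fgf_ratio": self.fgf_ratio,
            "allelic_summaries": self.allelic_summaries,
            "xist_biallelism": self.xist_biallelism,
            "profiles": self.profiles,
            "region_contrasts": self.region_contrasts,
            "epiblast_scores": self.epiblast_scores,
            "naive_primed_ratio": self.naive_primed_ratio,
            "comparisons": self.comparisons,
        }
        return json.dumps(payload, sort_keys=True, indent=1, default=default)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")


def _round6(x: float) -> float:
    return float(f"{x:.6g}")


def paired_by_study_index(values: pd.Series, meta: pd.DataFrame,
                          state_a: str = "naive", state_b: str = "primed"):
    """Pair the i-th naive with the i-th primed sample within each study.

    Returns aligned (a, b, keys) vectors over the studies where both
    groups exist; unmatched trailing samples are dropped.
    """
    a_vals, b_vals, keys = [], [], []
    meta = meta.loc[[s for s in values.index if s in meta.index]]
    for study in sorted(meta["study"].unique()):
        sub = meta[meta["study"] == study]
        a_ids = sorted(sub.index[sub["state"].str.startswith(state_a)])
        b_ids = sorted(sub.index[sub["state"].str.startswith(state_b)])
        for x, y in zip(a_ids, b_ids):
            a_vals.append(values[x])
            b_vals.append(values[y])
            keys.append(f"{study}:{x}|{y}")
    return np.array(a_vals), np.array(b_vals), keys


def run_pipeline(config: RunConfig) -> Report:
    if config.annotation is None or config.counts is None:
        raise ValueError("annotation and counts inputs are required")
    report = Report(provenance=config.provenance())

    annotation = load_annotation(config.annotation)
    meta = (expr.load_metadata(config.metadata)
            if config.metadata is not None else None)
    counts = expr.load_counts(config.counts, meta)
    if meta is not None:
        unknown = [s for s in counts.samples if s not in meta.index]
        if unknown:
            raise ValueError(f"samples missing from metadata: {unknown}")
    tpm = expr.compute_tpm(counts, annotation)
    report.stages_run.append("expression")

    calls = expr.call_xist(tpm, config.xist_gene_id, config.xist_tpm)
    status = {c.sample_id: c.status for c in calls}
    report.xist_calls = [
        {"sample_id": c.sample_id, "xist_tpm": _round6(c.xist_tpm),
         "status": c.status} for c in calls]
    report.stages_run.append("xist")

    # the variable-gene filter is specific to the geographic analysis; the
    # X-linked expression summary averages over expressed genes only
    expressed = expr.filter_genes(tpm, "expressed_only")
    xmeans = expr.xlinked_summary(tpm, annotation, "sample", gene_subset=expressed)
    report.xlinked_mean_tpm = {s: _round6(v) for s, v in xmeans.items()}
    if "FGF4" in tpm.values.index and "FGF2" in tpm.values.index:
        ratios = expr.fgf_ratio(tpm, eps=config.pseudocount)
        report.fgf_ratio = {s: _round6(v) for s, v in ratios.items()}

    if meta is not None:
        naive_x, primed_x, keys = paired_by_study_index(xmeans, meta)
        if len(naive_x) >= 2:
            c = compare_groups(naive_x, primed_x, paired=True, test="paired_t",
                                keys=keys)
            report.comparisons["xlinked_naive_vs_primed"] = c.as_dict()

    snps_all = None
    if config.snp_table is not None and Path(config.snp_table).exists():
        snps_all = al.load_snp_table(config.snp_table)
        snps = al.filter_snps(snps_all, config.snp_min_depth)
        for sample in counts.samples:
            summary = al.x_autosome_ratio(snps, annotation, sample,
                                          config.biallelic_ratio)
            report.allelic_summaries[sample] = {
                "x_autosome_ratio": (None if summary.undefined
                                     else _round6(summary.x_autosome_ratio)),
                "undefined": summary.undefined,
                "ns_chrX": _round6(summary.ns_per_chrom.get(X_CHROM, 0.0)),
            }
            report.xist_biallelism[sample] = al.xist_biallelism(
                snps_all[snps_all["sample_id"] == sample], config.xist_gene_id,
                config.snp_min_depth, config.biallelic_ratio)
        report.stages_run.append("allelic")
        if meta is not None:
            ratios = pd.Series({s: d["x_autosome_ratio"]
                                for s, d in report.allelic_summaries.items()
                                if d["x_autosome_ratio"] is not None})
            a, b, keys = paired_by_study_index(ratios, meta)
            if len(a) >= 2:
                c = compare_groups(a, b, paired=True, test="paired_t", keys=keys)
                report.comparisons["x_autosome_naive_vs_primed"] = c.as_dict()
    else:
        logger.info("no SNP table; skipping the allelic stage")

    if meta is not None:
        _geography_stage(report, config, annotation, tpm, meta, status,
                         snps_filtered=None if snps_all is None
                         else al.filter_snps(snps_all, config.snp_min_depth))

    if (config.marker_panel is not None and Path(config.marker_panel).exists()
            and config.epiblast_cells is not None
            and Path(config.epiblast_cells).exists()):
        panel = epi.load_marker_panel(config.marker_panel)
        cells = expr.load_counts(config.epiblast_cells).values
        reference = epi.pseudo_bulk_tpm(cells, list(cells.columns), annotation)
        scores = epi.score_cohort(tpm, reference, panel)
        report.epiblast_scores = {
            s.sample_id: {"r": _round6(s.r), "n_markers_used": s.n_markers_used}
            for s in scores}
        if meta is not None:
            try:
                ratio = epi.naive_primed_ratio(scores, meta)
                report.naive_primed_ratio = {k: _round6(v) for k, v in ratio.items()}
            except ValueError as exc:
                logger.info("naive/primed epiblast ratio unavailable: %s", exc)
        report.stages_run.append("epiblast")
    else:
        logger.info("no marker panel / epiblast cells; skipping the epiblast stage")

    return report


def _geography_stage(report: Report, config: RunConfig,
                     annotation: GeneAnnotation, tpm, meta: pd.DataFrame,
                     status: dict[str, str], snps_filtered=None) -> None:
    filtered = expr.filter_genes(tpm, "expressed_and_variable",
                                 variable_fraction=config.variable_gene_fraction)
    region = None
    if config.cytobands is not None and Path(config.cytobands).exists():
        region = resolve_region(config.region, load_cytobands(config.cytobands))

    tracks_by_group: dict[str, dict[str, list]] = {"XIST_pos": {}, "XIST_neg": {}}
    fc_columns: dict[str, dict[str, pd.Series]] = {"XIST_pos": {}, "XIST_neg": {}}
    for study in sorted(meta["study"].unique()):
        sub = meta[meta["study"] == study]
        primed_ids = [s for s in sub.index
                      if sub.loc[s, "state"] in ("primed", "naive_low")]
        naive_ids = [s for s in sub.index
                     if sub.loc[s, "state"] in ("naive", "naive_high")]
        if not primed_ids or not naive_ids:
            continue
        baseline = tpm.values[primed_ids]
        for sample in naive_ids:
            try:
                track = geo.fold_change_track(
                    tpm.values[sample], baseline, annotation, X_CHROM,
                    gene_subset=filtered, eps=config.pseudocount)
            except ValueError:
                continue
            group = status.get(sample, "XIST_neg")
            tracks_by_group[group].setdefault(study, []).append(track)
            fc_columns[group][sample] = track.values_by_gene()
    for group, by_study in tracks_by_group.items():
        if not by_study:
            continue
        try:
            profile = geo.group_profile(by_study, window=config.window)
        except ValueError as exc:
            logger.info("%s group profile unavailable: %s", group, exc)
            continue
        min_pos, min_val = profile.minimum()
        report.profiles[group] = {
            "window": profile.window, "n_points": len(profile),
            "min_center_position": _round6(min_pos), "min_value": _round6(min_val),
        }
    if "geography" not in report.stages_run and report.profiles:
        report.stages_run.append("geography")

    if region is None:
        return
    pos_cols = fc_columns["XIST_pos"]
    if len(pos_cols) >= 2:
        values = pd.DataFrame(pos_cols).dropna()
        contrast = geo.region_contrast(values, region, annotation, "paired_t")
        report.region_contrasts["log2fc_xq22_vs_chrX"] = {
            "region_mean": _round6(contrast.region_mean),
            "chrom_mean": _round6(contrast.chrom_mean),
            "statistic": _round6(contrast.statistic),
            "p_value": _round6(contrast.p_value),
            "test": contrast.test_name, "n": contrast.n,
        }
    if snps_filtered is not None and len(pos_cols) >= 2:
        samples = sorted(pos_cols)
        region_fr = [al.biallelic_fraction(snps_filtered, annotation, s, region,
                                           threshold=config.biallelic_ratio)
                     for s in samples]
        chrom_fr = [al.biallelic_fraction(snps_filtered, annotation, s, None,
                                          threshold=config.biallelic_ratio)
                    for s in samples]
        mask = ~(np.isnan(region_fr) | np.isnan(chrom_fr))
        if mask.sum() >= 2:
            c = compare_groups(np.array(region_fr)[mask], np.array(chrom_fr)[mask],
                                paired=True, test="paired_t")
            report.region_contrasts["biallelic_fraction_xq22_vs_chrX"] = c.as_dict()
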