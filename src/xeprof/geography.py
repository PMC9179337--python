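"""Geographic erosion profiles along chromosome X.

Each test sample's TPM per gene is divided by the per-gene median of a
baseline group (primed samples, or male samples for the erosion check),
and the log2 fold changes, ordered by gene start position, are smoothed
with a 50-gene sliding window.  Cross-sample aggregation is by nested
medians — per-gene median within each study, then the per-gene median of
those study medians within an XIST+ or XIST- group — and the window then
applies an arithmetic mean (a windowed-median mode is exposed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneAnnotation, RegionSpec, X_CHROM, genes_in_region

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 50
FC_PSEUDOCOUNT = 0.01
BASELINE_MIN_TPM = 1.0


@dataclass
class FoldChangeTrack:
    """Position-ordered per-gene log2 fold changes on one chromosome."""

    chrom: str
    entries: pd.DataFrame  # columns gene_id, position, log2fc; sorted by position

    def __post_init__(self) -> None:
        pos = self.entries["position"].to_numpy()
        if len(pos) and np.any(np.diff(pos) < 0):
            raise ValueError("track positions must be non-decreasing")
        if not np.all(np.isfinite(self.entries["log2fc"])):
            raise ValueError("non-finite log2 fold changes in track")

    def __len__(self) -> int:
        return len(self.entries)

    def values_by_gene(self) -> pd.Series:
        return self.entries.set_index("gene_id")["log2fc"]


@dataclass
class MovingAverageProfile:
    """Windowed values along a chromosome: (center position, value) points."""

    window: int
    points: pd.DataFrame  # columns center_position, value

    def __len__(self) -> int:
        return len(self.points)

    def minimum(self) -> tuple[float, float]:
        """(center position, value) of the profile minimum (first on ties)."""
        i = int(np.argmin(self.points["value"].to_numpy()))
        row = self.points.iloc[i]
        return float(row["center_position"]), float(row["value"])


@dataclass
class RegionContrast:
    region_name: str
    region_mean: float
    chrom_mean: float
    statistic: float
    p_value: float
    test_name: str
    n: int = 0


def _ordered_genes(genes: GeneAnnotation, chrom: str, keep: set[str]) -> list:
    return [g for g in genes.genes_on(chrom) if g.gene_id in keep]


def fold_change_track(test_tpm: pd.Series, baseline_tpm: pd.DataFrame,
                      genes: GeneAnnotation, chrom: str = X_CHROM,
                      gene_subset: set[str] | None = None,
                      eps: float = FC_PSEUDOCOUNT,
                      baseline_min_tpm: float = BASELINE_MIN_TPM) -> FoldChangeTrack:
    """log2((test + eps) / (baseline median + eps)) per gene, position-ordered.

    Restricted to genes whose baseline median TPM exceeds
    ``baseline_min_tpm``; callers are expected to have applied the
    expressed-and-variable gene filter already and pass it as
    ``gene_subset``.
    """
    if baseline_tpm.shape[1] == 0:
        raise ValueError("baseline group is empty")
    shared = set(test_tpm.index) & set(baseline_tpm.index)
    if gene_subset is not None:
        shared &= set(gene_subset)
    ordered = _ordered_genes(genes, chrom, shared)
    baseline_median = baseline_tpm.median(axis=1)
    ordered = [g for g in ordered if baseline_median[g.gene_id] > baseline_min_tpm]
    if not ordered:
        raise ValueError(f"no genes survive the baseline filter on {chrom}")
    ids = [g.gene_id for g in ordered]
    log2fc = np.log2((test_tpm[ids].to_numpy() + eps)
                     / (baseline_median[ids].to_numpy() + eps))
    entries = pd.DataFrame({
        "gene_id": ids,
        "position": [g.start for g in ordered],
        "log2fc": log2fc,
    })
    return FoldChangeTrack(chrom=chrom, entries=entries)


def moving_average(track: FoldChangeTrack, window: int = DEFAULT_WINDOW,
                   stat: str = "mean") -> MovingAverageProfile:
    """Sliding window over consecutive genes in position order.

    The window slides by one gene with no partial windows at the ends, so
    the profile has n_genes - window + 1 points; each point's center is
    the mean position of its window's genes.
    """
    n = len(track)
    if n < window:
        raise ValueError(
            f"track has {n} genes, fewer than window={window}; use a smaller window")
    values = track.entries["log2fc"].to_numpy()
    positions = track.entries["position"].to_numpy(dtype=float)
    series = pd.Series(values)
    if stat == "mean":
        win_vals = series.rolling(window).mean().to_numpy()[window - 1:]
    elif stat == "median":
        win_vals = series.rolling(window).median().to_numpy()[window - 1:]
    else:
        raise ValueError(f"unknown window statistic {stat!r}")
    centers = pd.Series(positions).rolling(window).mean().to_numpy()[window - 1:]
    points = pd.DataFrame({"center_position": centers, "value": win_vals})
    return MovingAverageProfile(window=window, points=points)


def group_profile(tracks_by_study: dict[str, list[FoldChangeTrack]],
                  window: int = DEFAULT_WINDOW,
                  stat: str = "mean") -> MovingAverageProfile:
    """Median-of-medians group curve, then the sliding window.

    Per study the per-gene median of its samples' log2 fold changes is
    taken; the per-gene median across study medians forms the group
    track.  Studies whose gene sets differ are intersected with a logged
    count.
    """
    if not tracks_by_study:
        raise ValueError("no studies supplied")
    study_medians: dict[str, pd.Series] = {}
    for study, tracks in tracks_by_study.items():
        if not tracks:
            raise ValueError(f"study {study!r} has no tracks")
        frame = pd.concat([t.values_by_gene() for t in tracks], axis=1)
        study_medians[study] = frame.median(axis=1)
    common = None
    for series in study_medians.values():
        idx = set(series.dropna().index)
        common = idx if common is None else common & idx
    union = set().union(*(set(s.index) for s in study_medians.values()))
    if len(common) < len(union):
        logger.info("group profile: intersecting gene sets across studies "
                    "(%d of %d genes shared)", len(common), len(union))
    group_median = pd.concat(
        [s[sorted(common)] for s in study_medians.values()], axis=1).median(axis=1)

    any_track = next(iter(tracks_by_study.values()))[0]
    positions = any_track.entries.set_index("gene_id")["position"]
    ids = [g for g in any_track.entries["gene_id"] if g in common]
    entries = pd.DataFrame({
        "gene_id": ids,
        "position": positions[ids].to_numpy(),
        "log2fc": group_median[ids].to_numpy(),
    }).sort_values(["position", "gene_id"], kind="mergesort").reset_index(drop=True)
    return moving_average(FoldChangeTrack(any_track.chrom, entries), window, stat)


def region_contrast(values: pd.DataFrame | pd.Series, region: RegionSpec,
                    genes: GeneAnnotation, test: str = "paired_t") -> RegionContrast:
    """Contrast a region's per-gene statistic against the whole chromosome.

    ``values`` holds a per-gene statistic (log2fc, TPM, biallelic
    fraction) indexed by gene id — a DataFrame with one column per sample
    gives a paired test of per-sample region means against per-sample
    chromosome means; a Series gives an unpaired gene-level test of
    region genes against the rest of the chromosome.
    """
    region_ids = [g.gene_id for g in genes_in_region(genes, region)
                  if g.gene_id in set(values.index)]
    if not region_ids:
        raise ValueError(f"no genes with values inside region {region.name}")
    from .compare import compare  # local import to avoid a cycle

    if isinstance(values, pd.Series):
        region_vals = values[region_ids].to_numpy()
        rest = values.drop(index=region_ids).to_numpy()
        if len(region_vals) < 2 or len(rest) < 2:
            raise ValueError("need >= 2 genes inside and outside the region")
        cmp = compare(region_vals, rest, paired=False,
                      test="unpaired_t" if test == "paired_t" else test)
        return RegionContrast(region.name, float(np.mean(region_vals)),
                              float(np.mean(values)), cmp.statistic, cmp.p_value,
                              cmp.test_name, n=len(region_vals))

    region_means = values.loc[region_ids].mean(axis=0)
    chrom_means = values.mean(axis=0)
    cmp = compare(region_means.to_numpy(), chrom_means.to_numpy(), paired=True,
                  test=test, keys=list(values.columns))
    return RegionContrast(region.name, float(region_means.mean()),
                          float(chrom_means.mean()), cmp.statistic, cmp.p_value,
                          cmp.test_name, n=values.shape[1])


def primed_vs_male_track(primed_tpm: pd.DataFrame, male_tpm: pd.DataFrame,
                         genes: GeneAnnotation, chrom: str = X_CHROM,
                         gene_subset: set[str] | None = None,
                         window: int = DEFAULT_WINDOW) -> MovingAverageProfile:
    """Erosion check: primed samples against the male single-X baseline.

    Each primed sample is normalized to the per-gene male median; the
    per-gene median across primed samples is smoothed with the standard
    window.  An eroded (XaXe) X shows elevated distal edges (toward
    log2 2) and a depressed middle.
    """
    if male_tpm.shape[1] == 0:
        raise ValueError("no male baseline samples")
    tracks = [
        fold_change_track(primed_tpm[s], male_tpm, genes, chrom, gene_subset)
        for s in primed_tpm.columns
    ]
    return group_profile({"primed": tracks}, window=window)


def write_profile(profile: MovingAverageProfile, path, group: str = "",
                  landmarks: dict[str, float] | None = None) -> None:
    """Profile TSV: center_position, value, window, group (+ landmark comments)."""
    with open(path, "w") as fh:
        if landmarks:
            for name, pos in sorted(landmarks.items()):
                fh.write(f"#landmark\t{name}\t{pos:.0f}\n")
        fh.write("#center_position\tvalue\twindow\tgroup\n")
        for _, row in profile.points.iterrows():
            fh.write(f"{row['center_position']:.1f}\t{row['value']:.6g}"
                     f"\t{profile.window}\t{group}\n")
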