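"""Pseudo-bulk epiblast reference and marker-gene correlation scoring.

Single cells classified as pre-implantation epiblast are merged (raw
counts summed) into one pseudo-bulk column, TPM-normalized, and each bulk
sample is scored by the Pearson correlation of log2(TPM+1) against the
reference over a panel of epiblast marker genes.  Naive-state samples are
expected to correlate more strongly than their primed counterparts; the
per-study naive/primed ratio of mean correlations summarizes that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .expression import SampleTable, compute_tpm
from .genome import GeneAnnotation

logger = logging.getLogger(__name__)

MIN_SHARED_MARKERS = 3


@dataclass(frozen=True)
class MarkerPanel:
    gene_ids: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("marker panel is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate ids in marker panel")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class EpiblastScore:
    sample_id: str
    r: float
    n_markers_used: int


def load_marker_panel(path: str | Path, source: str = "") -> MarkerPanel:
    """One gene id per line; '#' lines are comments."""
    ids = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    return MarkerPanel(tuple(ids), source=source or str(path))


def write_marker_panel(panel: MarkerPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        if panel.source:
            fh.write(f"# source: {panel.source}\n")
        fh.write("\n".join(panel.gene_ids) + "\n")


def pseudo_bulk(cell_counts: pd.DataFrame, cell_ids: list[str]) -> pd.Series:
    """Sum raw counts over the selected cells (columns) into one column."""
    if not cell_ids:
        raise ValueError("empty cell selection for pseudo-bulk")
    missing = [c for c in cell_ids if c not in cell_counts.columns]
    if missing:
        raise KeyError(f"cells absent from the matrix: {missing[:5]}")
    return cell_counts[list(cell_ids)].sum(axis=1)


def pseudo_bulk_tpm(cell_counts: pd.DataFrame, cell_ids: list[str],
                    genes: GeneAnnotation, name: str = "epiblast") -> pd.Series:
    """Pseudo-bulk counts TPM-normalized through the standard pipeline."""
    bulk = pseudo_bulk(cell_counts, cell_ids).to_frame(name)
    tpm = compute_tpm(SampleTable(bulk, kind="counts"), genes)
    return tpm.values[name]


def epiblast_correlation(sample_tpm: pd.Series, reference_tpm: pd.Series,
                         panel: MarkerPanel, log_transform: bool = True,
                         sample_id: str | None = None) -> EpiblastScore:
    """Pearson r between a sample and the reference over the marker panel.

    Computed on log2(TPM+1) by default (raw-TPM mode exposed); markers
    absent from either vector are dropped with a logged count, and fewer
    than three shared markers is an error.
    """
    shared = [g for g in panel.gene_ids
              if g in sample_tpm.index and g in reference_tpm.index]
    n_missing = len(panel) - len(shared)
    if n_missing:
        logger.info("%d of %d panel markers missing from the matrices",
                    n_missing, len(panel))
    if len(shared) < MIN_SHARED_MARKERS:
        raise ValueError(
            f"only {len(shared)} shared markers; need >= {MIN_SHARED_MARKERS}")
    x = sample_tpm[shared].to_numpy(dtype=float)
    y = reference_tpm[shared].to_numpy(dtype=float)
    if log_transform:
        x, y = np.log2(x + 1.0), np.log2(y + 1.0)
    r, _ = stats.pearsonr(x, y)
    sid = sample_id if sample_id is not None else str(sample_tpm.name)
    return EpiblastScore(sample_id=sid, r=float(r), n_markers_used=len(shared))


def score_cohort(tpm: SampleTable, reference_tpm: pd.Series, panel: MarkerPanel,
                 log_transform: bool = True) -> list[EpiblastScore]:
    return [epiblast_correlation(tpm.values[s], reference_tpm, panel,
                                 log_transform, sample_id=s)
            for s in tpm.samples]


def naive_primed_ratio(scores: list[EpiblastScore], meta: pd.DataFrame) -> pd.Series:
    """(mean naive r) / (mean primed r) per study.

    A study missing either group is an error naming it; a non-positive
    primed mean yields NaN (flagged undefined) rather than an exception.
    """
    rows = []
    for s in scores:
        if s.sample_id not in meta.index:
            raise KeyError(f"sample {s.sample_id!r} absent from metadata")
        state = meta.loc[s.sample_id, "state"]
        group = "naive" if str(state).startswith("naive") else "primed"
        rows.append({"study": meta.loc[s.sample_id, "study"], "group": group, "r": s.r})
    df = pd.DataFrame(rows)
    ratios = {}
    for study, sub in df.groupby("study"):
        naive = sub.loc[sub["group"] == "naive", "r"]
        primed = sub.loc[sub["group"] == "primed", "r"]
        if naive.empty or primed.empty:
            missing = "naive" if naive.empty else "primed"
            raise ValueError(f"study {study!r} has no {missing} scores")
        primed_mean = primed.mean()
        if primed_mean <= 0:
            logger.warning("study %s: primed mean r <= 0; ratio undefined", study)
            ratios[study] = float("nan")
        else:
            ratios[study] = float(naive.mean() / primed_mean)
    return pd.Series(ratios).sort_index()
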