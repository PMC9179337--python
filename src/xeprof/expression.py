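"""TPM quantification, gene filtering, XIST status calling and X-linked summaries.

TPM (transcripts per million) is computed per sample by dividing each
gene's reads by its effective length, then dividing by the sum of those
rates and multiplying by 10^6, so every TPM column sums to 10^6 over the
full gene set.  A sample is called XIST+ when its XIST TPM is strictly
above 1 transcript per million; exactly 1 falls to XIST-.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GeneAnnotation, X_CHROM

logger = logging.getLogger(__name__)

XIST_TPM_THRESHOLD = 1.0
EXPRESSED_TPM_THRESHOLD = 1.0
VARIABLE_GENE_FRACTION = 0.1
FGF_PSEUDOCOUNT = 0.01

#: sample state labels understood by the pipeline
STATES = ("primed", "naive", "naive_high", "naive_low", "male_primed")


@dataclass
class SampleTable:
    """A genes x samples matrix (raw counts or TPM) plus per-sample metadata.

    ``meta`` is indexed by sample id with columns ``study``, ``state``
    and ``sex``; ``kind`` records whether ``values`` holds counts or TPM.
    """

    values: pd.DataFrame
    meta: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["study", "state", "sex"]))
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            n = int(self.values.isna().sum().sum())
            logger.warning("filling %d missing cells with 0", n)
            self.values = self.values.fillna(0.0)
        missing = [s for s in self.values.columns if s not in self.meta.index]
        if missing and not self.meta.empty:
            logger.warning("%d samples absent from metadata: %s", len(missing), missing[:5])

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def samples_in_state(self, *states: str) -> list[str]:
        if self.meta.empty:
            return []
        keep = self.meta.index[self.meta["state"].isin(states)]
        return [s for s in self.values.columns if s in set(keep)]

    def subset(self, genes=None, samples=None) -> "SampleTable":
        values = self.values
        if genes is not None:
            values = values.loc[[g for g in values.index if g in set(genes)]]
        if samples is not None:
            values = values[list(samples)]
        return SampleTable(values.copy(), self.meta, self.kind)


@dataclass(frozen=True)
class XistCall:
    sample_id: str
    xist_tpm: float
    status: str  # "XIST_pos" | "XIST_neg"


def load_counts(path: str | Path, meta: pd.DataFrame | None = None,
                kind: str = "counts") -> SampleTable:
    """Read a counts/TPM TSV: first column gene_id, one column per sample,
    optional '#'-prefixed header line."""
    with open(path) as fh:
        first = fh.readline()
    header = 0
    if first.startswith("#"):
        names = first.lstrip("#").rstrip("\n").split("\t")
        df = pd.read_csv(path, sep="\t", skiprows=1, header=None, names=names)
    else:
        df = pd.read_csv(path, sep="\t", header=header)
    df = df.set_index(df.columns[0])
    df.index.name = "gene_id"
    if meta is None:
        meta = pd.DataFrame(columns=["study", "state", "sex"])
    return SampleTable(df.astype(float), meta, kind)


def write_table(table: SampleTable, path: str | Path, float_format: str = "%.6g") -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\t" + "\t".join(table.samples) + "\n")
        table.values.to_csv(fh, sep="\t", header=False, float_format=float_format)


def load_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV: sample_id, study, state, sex ('#' header allowed)."""
    df = pd.read_csv(path, sep="\t", comment=None)
    df.columns = [c.lstrip("#") for c in df.columns]
    bad = set(df["state"]) - set(STATES)
    if bad:
        raise ValueError(f"unknown state labels in metadata: {sorted(bad)}")
    return df.set_index("sample_id")


def compute_tpm(counts: SampleTable, genes: GeneAnnotation) -> SampleTable:
    """Length-normalize then library-normalize raw counts to TPM.

    Per sample s and gene g: rate_gs = count_gs / length_g and
    TPM_gs = rate_gs / sum_g(rate_gs) * 1e6.
    """
    missing = [g for g in counts.genes if g not in genes]
    if missing:
        raise KeyError(f"{len(missing)} genes lack an annotation entry, e.g. {missing[:3]}")
    lengths = pd.Series({g: genes[g].length for g in counts.genes}, dtype=float)
    rate = counts.values.div(lengths, axis=0)
    colsum = rate.sum(axis=0)
    zero = colsum[colsum == 0]
    if len(zero):
        raise ValueError(f"sample(s) with all-zero counts: {list(zero.index)}")
    tpm = rate.div(colsum, axis=1) * 1e6
    return SampleTable(tpm, counts.meta, kind="tpm")


def call_xist(tpm: SampleTable, xist_gene_id: str = "XIST",
              threshold: float = XIST_TPM_THRESHOLD) -> list[XistCall]:
    """Call per-sample XIST status: XIST_pos iff TPM strictly > threshold."""
    if tpm.kind != "tpm":
        raise ValueError("call_xist requires a TPM table")
    if xist_gene_id not in tpm.values.index:
        raise KeyError(f"XIST gene {xist_gene_id!r} absent from the expression matrix")
    row = tpm.values.loc[xist_gene_id]
    return [
        XistCall(sample_id=s, xist_tpm=float(v),
                 status="XIST_pos" if v > threshold else "XIST_neg")
        for s, v in row.items()
    ]


def xist_status_frame(calls: list[XistCall], meta: pd.DataFrame) -> pd.DataFrame:
    """Tabulate XIST calls with study/state metadata for reporting."""
    df = pd.DataFrame([{"sample_id": c.sample_id, "xist_tpm": c.xist_tpm,
                        "status": c.status} for c in calls]).set_index("sample_id")
    return df.join(meta, how="left")


def filter_genes(tpm: SampleTable, mode: str = "expressed_and_variable",
                 expressed_threshold: float = EXPRESSED_TPM_THRESHOLD,
                 variable_fraction: float = VARIABLE_GENE_FRACTION) -> set[str]:
    """Drop non-expressed genes, then (optionally) the top most-variable ones.

    A gene counts as expressed when its TPM exceeds ``expressed_threshold``
    in at least one sample of the table.  Variability is the variance of
    log2(TPM+1) across samples; the top ceil(variable_fraction * n) of the
    expressed genes are removed (variance ties broken by gene id so the
    survivor set is deterministic).
    """
    if mode not in ("expressed_only", "expressed_and_variable"):
        raise ValueError(f"unknown filter mode {mode!r}")
    if len(tpm.genes) < 10:
        raise ValueError("gene filtering requires at least 10 genes")
    expressed_mask = (tpm.values > expressed_threshold).any(axis=1)
    expressed = tpm.values.index[expressed_mask]
    if len(expressed) == 0:
        raise ValueError("all genes filtered: none expressed above threshold")
    if mode == "expressed_only":
        return set(expressed)
    logv = np.log2(tpm.values.loc[expressed] + 1.0)
    variance = logv.var(axis=1, ddof=1).fillna(0.0)
    n_drop = math.ceil(variable_fraction * len(expressed))
    order = sorted(variance.index, key=lambda g: (-variance[g], g))
    survivors = set(order[n_drop:])
    if not survivors:
        raise ValueError("all genes filtered: variable-gene removal left none")
    logger.info("gene filter: %d expressed, %d dropped as most variable",
                len(expressed), n_drop)
    return survivors


def xlinked_summary(tpm: SampleTable, genes: GeneAnnotation,
                    group_by: str = "sample",
                    gene_subset: set[str] | None = None) -> pd.Series:
    """Mean TPM over chromosome-X genes, per sample or per state.

    State-level aggregation is the mean of the per-sample means, so every
    sample weighs equally regardless of gene coverage.
    """
    x_ids = [g.gene_id for g in genes.genes_on(X_CHROM) if g.gene_id in set(tpm.genes)]
    if gene_subset is not None:
        x_ids = [g for g in x_ids if g in gene_subset]
    if not x_ids:
        raise ValueError("no chromosome-X genes left after filtering")
    per_sample = tpm.values.loc[x_ids].mean(axis=0)
    if group_by == "sample":
        return per_sample
    if group_by == "state":
        states = tpm.meta.loc[per_sample.index, "state"]
        return per_sample.groupby(states).mean()
    raise ValueError(f"unknown group_by {group_by!r}")


def fgf_ratio(tpm: SampleTable, fgf4_id: str = "FGF4", fgf2_id: str = "FGF2",
              eps: float = FGF_PSEUDOCOUNT) -> pd.Series:
    """Per-sample (TPM_FGF4 + eps) / (TPM_FGF2 + eps)."""
    for gid in (fgf4_id, fgf2_id):
        if gid not in tpm.values.index:
            raise KeyError(f"gene {gid!r} absent from the expression matrix")
    return (tpm.values.loc[fgf4_id] + eps) / (tpm.values.loc[fgf2_id] + eps)
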