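"""Gene annotation, cytobands and region definitions.

All coordinates are 0-based half-open internally.  BED-like and UCSC
cytoBand inputs are already 0-based half-open; GTF-derived tables are
1-based inclusive and are converted on load.  Gene length is the effective
transcript length used as the TPM denominator and is taken from the
annotation column, never recomputed from exon models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

AUTOSOME_PREFIX = "chr"
X_CHROM = "chrX"


@dataclass(frozen=True)
class GeneModel:
    """One gene: coordinates plus effective transcript length.

    ``start``/``end`` are 0-based half-open.  ``length`` is the effective
    transcript length in bases (> 0), the denominator of the TPM rate.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    length: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start ({self.start}) must be < end ({self.end})"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class RegionSpec:
    """A named genomic interval, e.g. the Xq22 band union."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region {self.name!r}: start must be < end")

    def contains_midpoint(self, gene: GeneModel) -> bool:
        return gene.chrom == self.chrom and self.start <= gene.midpoint < self.end


@dataclass(frozen=True)
class Cytoband:
    chrom: str
    start: int
    end: int
    name: str
    stain: str


@dataclass
class CytobandMap:
    """Cytogenetic bands per chromosome, sorted by start within chromosome."""

    bands: list[Cytoband] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bands = sorted(self.bands, key=lambda b: (b.chrom, b.start))
        prev: dict[str, int] = {}
        for b in self.bands:
            if b.chrom in prev and b.start < prev[b.chrom]:
                raise ValueError(f"overlapping cytobands on {b.chrom} near {b.name}")
            prev[b.chrom] = b.end

    def on(self, chrom: str) -> list[Cytoband]:
        return [b for b in self.bands if b.chrom == chrom]


class GeneAnnotation:
    """A validated, position-ordered set of :class:`GeneModel`.

    Gene ids are unique; per-chromosome ordering is the total order
    ``(start, gene_id)``.
    """

    def __init__(self, genes: Iterable[GeneModel]):
        self._genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise ValueError(f"duplicate gene_id {g.gene_id!r} in annotation")
            self._genes[g.gene_id] = g
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in self._genes.values():
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for chrom in self._by_chrom:
            self._by_chrom[chrom].sort(key=lambda g: (g.start, g.gene_id))

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.chromosomes if c not in (X_CHROM, "chrY", "chrM")]

    def genes_on(self, chrom: str) -> list[GeneModel]:
        """Genes of one chromosome ordered by (start, gene_id)."""
        return list(self._by_chrom.get(chrom, []))

    def n_genes(self, chrom: str) -> int:
        return len(self._by_chrom.get(chrom, []))

    def lengths(self) -> dict[str, int]:
        return {g.gene_id: g.length for g in self._genes.values()}

    def chrom_of(self) -> dict[str, str]:
        return {g.gene_id: g.chrom for g in self._genes.values()}


def load_annotation(path: str | Path, dialect: str = "bed-like") -> GeneAnnotation:
    """Load a gene annotation table.

    ``bed-like``: tab-separated ``chrom start end gene_id length`` with
    0-based half-open coordinates and an optional ``#`` header line.
    ``gtf-derived-tsv``: same columns but 1-based inclusive coordinates,
    converted to 0-based half-open on load.

    Genes with non-positive length are rejected (dropped) with a logged
    count; a start >= end row or a duplicate gene_id is an error naming
    the offending line.
    """
    if dialect not in ("bed-like", "gtf-derived-tsv"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    path = Path(path)
    genes: list[GeneModel] = []
    n_bad_length = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
            chrom, start_s, end_s, gene_id, length_s = fields[:5]
            try:
                start, end, length = int(start_s), int(end_s), int(length_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate field") from exc
            if dialect == "gtf-derived-tsv":
                start -= 1  # 1-based inclusive -> 0-based half-open
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end for gene {gene_id!r}")
            if length <= 0:
                n_bad_length += 1
                continue
            genes.append(GeneModel(gene_id, chrom, start, end, length))
    if n_bad_length:
        logger.warning("%s: rejected %d genes with non-positive length", path, n_bad_length)
    return GeneAnnotation(genes)


def write_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    """Write the BED-like dialect that :func:`load_annotation` reads."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tgene_id\tlength\n")
        for chrom in annotation.chromosomes:
            for g in annotation.genes_on(chrom):
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t{g.length}\n")


def load_cytobands(path: str | Path) -> CytobandMap:
    """Read the UCSC cytoBand.txt dialect (no header, 5 tab-separated columns)."""
    bands = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            chrom, start, end, name, stain = fields[:5]
            bands.append(Cytoband(chrom, int(start), int(end), name, stain))
    return CytobandMap(bands)


def resolve_region(band_prefix: str, cytobands: CytobandMap, chrom: str = X_CHROM) -> RegionSpec:
    """Resolve a band-name prefix (e.g. ``"q22"``) to one spanning region.

    All bands on ``chrom`` whose name starts with ``band_prefix`` (so
    ``"q22"`` matches q22.1, q22.2, q22.3) are unioned into a single
    interval from their minimal start to their maximal end.
    """
    matches = [b for b in cytobands.on(chrom) if b.name.startswith(band_prefix)]
    if not matches:
        available = ", ".join(b.name for b in cytobands.on(chrom)) or "(none)"
        raise ValueError(
            f"no band named {band_prefix}* on {chrom}; available bands: {available}"
        )
    start = min(b.start for b in matches)
    end = max(b.end for b in matches)
    return RegionSpec(name=f"{chrom.removeprefix('chr')}{band_prefix}", chrom=chrom,
                      start=start, end=end)


def genes_in_region(genes: GeneAnnotation | Iterable[GeneModel], region: RegionSpec) -> list[GeneModel]:
    """Genes whose midpoint lies in [region.start, region.end), ordered by (start, gene_id).

    Midpoint membership (rather than overlap) assigns each gene to exactly
    one region even when it spans a region boundary.
    """
    pool = genes.genes_on(region.chrom) if isinstance(genes, GeneAnnotation) else list(genes)
    hits = [g for g in pool if region.contains_midpoint(g)]
    hits.sort(key=lambda g: (g.start, g.gene_id))
    return hits
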