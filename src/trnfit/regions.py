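"""Open-chromatin region calling and promoter / gene-body classification.

Open chromatin is defined as the union of connected assay-positive
intervals (histone-mark ChIP, DNase-seq, ATAC-seq), keeping only unions
supported by at least one accessibility assay (DNase or ATAC).  Regions
containing a gene's TSS become its promoter; open regions inside the
TSS-to-TES span (minus the promoter) become gene-body regions, which the
downstream model treats as repressive binding territory.

All coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

ASSAYS = frozenset({"histone_chip", "dnase", "atac"})
ACCESSIBILITY_ASSAYS = frozenset({"dnase", "atac"})


@dataclass(frozen=True)
class GenomicInterval:
    """A peak interval from one assay, 0-based half-open."""

    chrom: str
    start: int
    end: int
    assay: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} "
                f"({self.assay}): start must be < end"
            )
        if self.assay not in ASSAYS:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end}: unknown assay "
                f"{self.assay!r}; expected one of {sorted(ASSAYS)}"
            )


@dataclass(frozen=True)
class OpenRegion:
    """A maximal connected run of assay-positive bases with accessibility support."""

    chrom: str
    start: int
    end: int

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass(frozen=True)
class GeneModel:
    """Gene coordinates; for + strand tss < tes, for - strand tss > tes."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.tss == self.tes:
            raise ValueError(f"gene {self.gene_id}: tss == tes")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"gene {self.gene_id}: + strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"gene {self.gene_id}: - strand requires tss > tes")

    @property
    def span(self) -> tuple[int, int]:
        """TSS-to-TES span as a half-open interval on the forward axis."""
        lo, hi = sorted((self.tss, self.tes))
        return lo, hi


@dataclass
class RegionAnnotation:
    """Per-gene promoter / gene-body assignment.

    A gene whose TSS falls in no open region has ``promoter is None`` and is
    excluded from the network roster downstream.
    """

    gene_id: str
    promoter: Optional[OpenRegion]
    gene_body_regions: list[OpenRegion] = field(default_factory=list)

    @property
    def excluded(self) -> bool:
        return self.promoter is None


def call_open_regions(peaks: Iterable[GenomicInterval]) -> list[OpenRegion]:
    """Merge connected positive intervals and keep accessibility-supported unions.

    Intervals that overlap or abut (end == start) merge into one connected
    region.  A merged region is retained only if at least one DNase-seq or
    ATAC-seq peak overlaps it; histone-only regions are dropped, which also
    removes heterochromatin-dense territory lacking accessibility signal.

    Returns disjoint regions sorted by (chrom, start).
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        if not isinstance(p, GenomicInterval):
            p = GenomicInterval(*p)  # triggers validation
        by_chrom.setdefault(p.chrom, []).append(p)

    out: list[OpenRegion] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        cur_accessible = ivs[0].assay in ACCESSIBILITY_ASSAYS
        for p in ivs[1:]:
            if p.start <= cur_end:  # overlap or book-ended: same connected run
                cur_end = max(cur_end, p.end)
                cur_accessible = cur_accessible or p.assay in ACCESSIBILITY_ASSAYS
            else:
                if cur_accessible:
                    out.append(OpenRegion(chrom, cur_start, cur_end))
                cur_start, cur_end = p.start, p.end
                cur_accessible = p.assay in ACCESSIBILITY_ASSAYS
        if cur_accessible:
            out.append(OpenRegion(chrom, cur_start, cur_end))
    return out


def classify_regions(
    open_regions: Sequence[OpenRegion], genes: Iterable[GeneModel]
) -> list[RegionAnnotation]:
    """Assign each gene its promoter and gene-body open regions.

    Promoter: the open region containing the TSS (``start <= tss < end``);
    absent when no region contains it.  Gene body: intersections of open
    regions with the TSS-to-TES span, with any promoter overlap removed and
    empty pieces dropped.  Idempotent and deterministic; promoter and
    gene-body regions never overlap.
    """
    by_chrom: dict[str, list[OpenRegion]] = {}
    for r in open_regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda r: r.start)

    annotations: list[RegionAnnotation] = []
    for gene in genes:
        regions = by_chrom.get(gene.chrom, [])
        promoter = next((r for r in regions if r.contains(gene.chrom, gene.tss)), None)
        lo, hi = gene.span
        bodies: list[OpenRegion] = []
        for r in regions:
            s, e = max(r.start, lo), min(r.end, hi)
            if s >= e:
                continue
            pieces = [(s, e)]
            if promoter is not None and promoter.start < e and s < promoter.end:
                pieces = [
                    (a, b)
                    for a, b in ((s, min(e, promoter.start)), (max(s, promoter.end), e))
                    if a < b
                ]
            bodies.extend(OpenRegion(gene.chrom, a, b) for a, b in pieces)
        annotations.append(RegionAnnotation(gene.gene_id, promoter, bodies))
    return annotations
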