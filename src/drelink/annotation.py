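"""Classify DNase I hypersensitive sites and define profile regions.

A DHS falls into exactly one of three categories:

* ``DRE`` — overlaps no gene body and lies more than ``tss_flank`` bp
  (default 2000) from the nearest transcription start site.  These are the
  candidate distal regulatory elements.
* ``intragenic`` — overlaps at least one gene body.  These are the gene-side
  anchors for Hi-C read counting.
* ``promoter_proximal`` — overlaps no gene body but sits within ``tss_flank``
  of a TSS.  Used only for read-density profiling.

Intragenic takes precedence: a DHS inside one gene body but near another
gene's TSS is intragenic.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Sequence

from .genomic_io import BedInterval, GeneModel, GenomicInterval

DRE = "DRE"
INTRAGENIC = "intragenic"
PROMOTER_PROXIMAL = "promoter_proximal"


@dataclass(frozen=True)
class ClassifiedDHS:
    interval: GenomicInterval
    dhs_id: str
    category: str
    host_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in (DRE, INTRAGENIC, PROMOTER_PROXIMAL):
            raise ValueError(f"unknown DHS category {self.category!r}")
        if (self.category == INTRAGENIC) != bool(self.host_genes):
            raise ValueError("host_genes set iff category is intragenic")

    @property
    def host_gene(self) -> str | None:
        """First host gene (genomic input order), or None if not intragenic."""
        return self.host_genes[0] if self.host_genes else None


@dataclass(frozen=True)
class ProfileRegion:
    """The sequence region whose phylogenetic profile represents an owner.

    For a DRE the region is the DHS peak interval itself; for a gene it runs
    from ``upstream`` bp before the TSS (strand-aware) to the gene end.
    """

    owner_id: str
    interval: GenomicInterval


def classify_dhs(
    dhs: Sequence[BedInterval | GenomicInterval],
    genes: Sequence[GeneModel],
    tss_flank: int = 2000,
    dhs_ids: Sequence[str] | None = None,
) -> list[ClassifiedDHS]:
    """Classify every DHS; classification is total.

    TSS distance is the minimum absolute bp distance from any base of the DHS
    interval to the TSS point; "within a gene" means any overlap with a gene
    body.  A DHS on a chromosome with no gene is a DRE (TSS distance is
    treated as infinite).
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    if dhs_ids is None:
        dhs_ids = [
            getattr(iv, "name", None) or f"dhs{i:06d}" for i, iv in enumerate(dhs)
        ]
    if len(dhs_ids) != len(dhs):
        raise ValueError("dhs_ids length mismatch")

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    tss_by_chrom: dict[str, list[int]] = {}
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: (g.body.start, g.body.end, g.gene_id))
        tss_by_chrom[chrom] = sorted(g.tss for g in gs)

    out: list[ClassifiedDHS] = []
    for iv, dhs_id in zip(dhs, dhs_ids):
        chrom_genes = by_chrom.get(iv.chrom, [])
        hosts = tuple(
            g.gene_id for g in chrom_genes if iv.overlaps(g.body)
        )
        if hosts:
            out.append(ClassifiedDHS(iv, dhs_id, INTRAGENIC, hosts))
            continue
        tss_list = tss_by_chrom.get(iv.chrom, [])
        if tss_list and _min_tss_distance(iv, tss_list) <= tss_flank:
            out.append(ClassifiedDHS(iv, dhs_id, PROMOTER_PROXIMAL))
        else:
            out.append(ClassifiedDHS(iv, dhs_id, DRE))
    return out


def _min_tss_distance(iv: GenomicInterval, sorted_tss: list[int]) -> int:
    """Min distance from the interval to any TSS in a sorted position list."""
    i = bisect.bisect_left(sorted_tss, iv.start)
    best = None
    for j in (i - 1, i, bisect.bisect_right(sorted_tss, iv.end - 1)):
        if 0 <= j < len(sorted_tss):
            d = iv.distance_to_point(sorted_tss[j])
            best = d if best is None else min(best, d)
    # any TSS inside the interval gives distance 0
    lo = bisect.bisect_left(sorted_tss, iv.start)
    hi = bisect.bisect_right(sorted_tss, iv.end - 1)
    if hi > lo:
        return 0
    assert best is not None
    return best


def gene_profile_region(gene: GeneModel, upstream: int = 1000) -> ProfileRegion:
    """Region from ``upstream`` bp before the TSS to the gene end, clipped
    at position 0."""
    b = gene.body
    if b.strand == "+":
        start, end = max(0, b.start - upstream), b.end
    else:
        start, end = b.start, b.end + upstream
    return ProfileRegion(gene.gene_id, GenomicInterval(b.chrom, start, end, b.strand))


def dre_profile_region(dre: ClassifiedDHS) -> ProfileRegion:
    """A DRE's profile region is its DHS peak interval, unchanged."""
    if dre.category != DRE:
        raise ValueError(f"{dre.dhs_id} is not a DRE")
    return ProfileRegion(dre.dhs_id, dre.interval)


def intragenic_dhs_of(
    gene: GeneModel, classified: Iterable[ClassifiedDHS]
) -> list[ClassifiedDHS]:
    """Intragenic DHS overlapping this gene's body, in genomic order.

    A DHS spanning two overlapping genes is returned for both.
    """
    hits = [
        c
        for c in classified
        if c.category == INTRAGENIC and c.interval.overlaps(gene.body)
    ]
    hits.sort(key=lambda c: (c.interval.start, c.interval.end, c.dhs_id))
    return hits


def write_classified(classified: Iterable[ClassifiedDHS], path) -> None:
    with open(path, "w") as fh:
        fh.write("dhs_id\tchrom\tstart\tend\tcategory\thost_genes\n")
        for c in classified:
            fh.write(
                f"{c.dhs_id}\t{c.interval.chrom}\t{c.interval.start}\t"
                f"{c.interval.end}\t{c.category}\t{','.join(c.host_genes)}\n"
            )


def load_classified(path) -> list[ClassifiedDHS]:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            dhs_id, chrom, start, end, cat, hosts = line.rstrip("\n").split("\t")
            out.append(
                ClassifiedDHS(
                    GenomicInterval(chrom, int(start), int(end)),
                    dhs_id,
                    cat,
                    tuple(h for h in hosts.split(",") if h),
                )
            )
    return out
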