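"""Hi-C contact counting for DRE-gene pairs, and read-density profiling.

A contact supports a candidate (DRE, gene) pair when one mapped end lies
inside the DRE peak interval and the other inside the capture window of an
intragenic DHS of the gene (DHS center +/- ``flank`` bp, default 1000); both
end orderings are accepted and one contact may support several pairs.

Because longer genes have more intragenic DHS, summing reads over a gene's
DHS would bias pair counts toward long genes.  The per-dataset pair count is
therefore the *maximum* over the gene's intragenic DHS of the per-DHS
supporting-read count (the "max rule"), making counts insensitive to how
many quiet DHS a gene carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .annotation import DRE, INTRAGENIC, ClassifiedDHS
from .genomic_io import GeneModel, GenomicInterval, HiCContact


@dataclass
class PairAnnotation:
    """A candidate DRE-gene pair with per-dataset Hi-C evidence.

    ``counts[dataset]`` is the max-rule read count; ``best_dhs[dataset]`` the
    intragenic DHS attaining it (first in genomic order on ties).  ``pcc`` and
    ``distance_class`` are attached by the prediction stage.
    """

    dre_id: str
    gene_id: str
    counts: dict[str, int] = field(default_factory=dict)
    best_dhs: dict[str, str] = field(default_factory=dict)
    pcc: float | None = None
    distance_class: str | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.dre_id, self.gene_id)


@dataclass(frozen=True)
class DensityProfile:
    """Observed/background Hi-C read density around target centers."""

    offsets: tuple[int, ...]
    ratio: tuple[float, ...]
    n_targets_used: int


def count_pair_reads(
    contacts: Mapping[str, Sequence[HiCContact]],
    classified: Sequence[ClassifiedDHS],
    genes: Sequence[GeneModel],
    flank: int = 1000,
) -> list[PairAnnotation]:
    """Max-rule per-dataset read counts for every supported (DRE, gene) pair.

    Returns one :class:`PairAnnotation` per pair with at least one supporting
    read in any dataset.  Genes with no intragenic DHS yield no pairs.
    """
    dre_tree: dict[str, IntervalTree] = {}
    dhs_tree: dict[str, IntervalTree] = {}
    gene_order = {g.gene_id: i for i, g in enumerate(genes)}

    for c in classified:
        iv = c.interval
        if c.category == DRE:
            dre_tree.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, c.dhs_id
            )
        elif c.category == INTRAGENIC:
            center = iv.center
            lo = max(0, center - flank)
            # capture window is [center - flank, center + flank)
            for gid in c.host_genes:
                if gid in gene_order:
                    dhs_tree.setdefault(iv.chrom, IntervalTree()).addi(
                        lo, center + flank, (gid, c.dhs_id)
                    )

    # (dre, gene, dhs, dataset) -> reads
    per_dhs: dict[tuple[str, str, str, str], int] = {}
    for dataset, recs in contacts.items():
        for ct in recs:
            ends = ((ct.chrom1, ct.pos1), (ct.chrom2, ct.pos2))
            for (ch_a, pos_a), (ch_b, pos_b) in (ends, ends[::-1]):
                dres = dre_tree.get(ch_a)
                wins = dhs_tree.get(ch_b)
                if not dres or not wins:
                    continue
                dre_hits = dres[pos_a]
                if not dre_hits:
                    continue
                win_hits = wins[pos_b]
                if not win_hits:
                    continue
                for dh in dre_hits:
                    for wh in win_hits:
                        gid, dhs_id = wh.data
                        k = (dh.data, gid, dhs_id, dataset)
                        per_dhs[k] = per_dhs.get(k, 0) + 1

    # genomic order of intragenic DHS for deterministic tie-breaking
    dhs_rank = {
        c.dhs_id: (c.interval.chrom, c.interval.start, c.interval.end, c.dhs_id)
        for c in classified
    }
    pairs: dict[tuple[str, str], PairAnnotation] = {}
    for (dre_id, gene_id, dhs_id, dataset), n in per_dhs.items():
        pa = pairs.setdefault(
            (dre_id, gene_id), PairAnnotation(dre_id=dre_id, gene_id=gene_id)
        )
        cur = pa.counts.get(dataset, 0)
        if n > cur or (
            n == cur and dhs_rank[dhs_id] < dhs_rank.get(pa.best_dhs.get(dataset, ""),
                                                         ("~", 1 << 60, 0, ""))
        ):
            pa.counts[dataset] = n
            pa.best_dhs[dataset] = dhs_id
    out = list(pairs.values())
    out.sort(key=lambda p: (p.dre_id, p.gene_id))
    return out


def density_profile(
    targets: Sequence[GenomicInterval],
    contacts: Iterable[HiCContact],
    half_width: int = 2000,
    window: int = 50,
    bg_near: int = 5000,
    bg_far: int = 10000,
) -> DensityProfile:
    """Average observed/background read density around target centers.

    Per target with center c: background density = reads in
    [c-bg_far, c-bg_near) u [c+bg_near, c+bg_far) divided by the combined
    flank length; observed density at offset o = reads in the ``window``-bp
    window centered on c+o, divided by ``window``.  The per-offset ratio is
    averaged over all targets with nonzero background.  Every contact end is
    one read point.
    """
    if not targets:
        raise ValueError("targets must be non-empty")
    pts: dict[str, list[int]] = {}
    for ct in contacts:
        pts.setdefault(ct.chrom1, []).append(ct.pos1)
        pts.setdefault(ct.chrom2, []).append(ct.pos2)
    if not pts:
        raise ValueError("no contacts given; density profile undefined")
    pos = {ch: np.sort(np.asarray(p, dtype=np.int64)) for ch, p in pts.items()}

    offsets = np.arange(-half_width, half_width + 1)
    half_w = window // 2
    bg_len = 2 * (bg_far - bg_near)
    acc = np.zeros_like(offsets, dtype=float)
    used = 0
    for t in targets:
        p = pos.get(t.chrom)
        if p is None:
            continue
        c = t.center
        bg = (
            np.searchsorted(p, c - bg_near) - np.searchsorted(p, c - bg_far)
            + np.searchsorted(p, c + bg_far) - np.searchsorted(p, c + bg_near)
        )
        if bg <= 0:
            continue
        bg_density = bg / bg_len
        left = c + offsets - half_w
        obs = (np.searchsorted(p, left + window) - np.searchsorted(p, left)) / window
        acc += obs / bg_density
        used += 1
    if used == 0:
        raise ValueError("all targets have zero background; profile undefined")
    return DensityProfile(
        tuple(int(o) for o in offsets),
        tuple(float(r) for r in acc / used),
        used,
    )


def write_pair_table(
    pairs: Sequence[PairAnnotation], datasets: Sequence[str], path
) -> None:
    with open(path, "w") as fh:
        cols = ["dre_id", "gene_id"]
        cols += [f"count_{d}" for d in datasets]
        cols += [f"best_dhs_{d}" for d in datasets]
        fh.write("\t".join(cols) + "\n")
        for p in sorted(pairs, key=lambda x: x.key):
            row = [p.dre_id, p.gene_id]
            row += [str(p.counts.get(d, 0)) for d in datasets]
            row += [p.best_dhs.get(d, ".") for d in datasets]
            fh.write("\t".join(row) + "\n")


def load_pair_table(path) -> tuple[list[PairAnnotation], list[str]]:
    pairs: list[PairAnnotation] = []
    with open(path) as fh:
        header = next(fh).rstrip("\n").split("\t")
        datasets = [h[len("count_"):] for h in header if h.startswith("count_")]
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rec = dict(zip(header, f))
            pa = PairAnnotation(dre_id=rec["dre_id"], gene_id=rec["gene_id"])
            for d in datasets:
                n = int(rec[f"count_{d}"])
                if n > 0:
                    pa.counts[d] = n
                    if rec.get(f"best_dhs_{d}", ".") != ".":
                        pa.best_dhs[d] = rec[f"best_dhs_{d}"]
            pairs.append(pa)
    return pairs, datasets


def write_density_profile(profile: DensityProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("offset\tratio\n")
        for o, r in zip(profile.offsets, profile.ratio):
            fh.write(f"{o}\t{r:.6g}\n")
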