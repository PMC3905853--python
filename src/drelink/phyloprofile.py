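"""Phylogenetic profiles from pairwise-alignment coverage.

The human genome is partitioned into consecutive non-overlapping sequence
bins at every block boundary of every species' human-coordinate alignment
blocks.  Each bin carries a binary indicator vector of length S (one entry
per non-human species): 1 if at least one block of that species covers the
bin, 0 otherwise.  The profile of a region (a DRE peak or a gene region) is
the bin-length-weighted average of the bin vectors over the region.

Two conventions matter and are fixed here:

* the weighted-average denominator is the *full region length*: human
  sequence aligned to no species contributes 0 to every entry, so profiles
  stay comparable across regions (``denominator="region"``; pass
  ``denominator="aligned"`` to divide by covered length instead);
* multiple homologous blocks of one species over a bin still give indicator
  1 — bin profiles are strictly binary coverage.

Profile similarity is the plain Pearson correlation of two profile vectors;
a zero-variance profile makes the correlation undefined and is reported as
``None`` (never coerced to 0), which excludes the pair downstream.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genomic_io import GenomicInterval
from .annotation import ProfileRegion


@dataclass(frozen=True)
class SequenceBin:
    interval: GenomicInterval
    indicators: tuple[int, ...]

    def __post_init__(self) -> None:
        if not any(self.indicators):
            raise ValueError("a sequence bin must be covered by >=1 species")


@dataclass(frozen=True)
class PhyloProfile:
    values: tuple[float, ...]
    region_length: int

    def __post_init__(self) -> None:
        for v in self.values:
            if not (0.0 <= v <= 1.0 + 1e-12):
                raise ValueError(f"profile value {v} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.values)


class BinIndex:
    """Per-chromosome sorted bins with fast range lookup."""

    def __init__(self, bins_by_chrom: Mapping[str, list[SequenceBin]], n_species: int):
        self.n_species = n_species
        self.bins_by_chrom = {c: list(bs) for c, bs in bins_by_chrom.items()}
        self._starts = {
            c: [b.interval.start for b in bs] for c, bs in self.bins_by_chrom.items()
        }
        self._ends = {
            c: [b.interval.end for b in bs] for c, bs in self.bins_by_chrom.items()
        }

    def overlapping(self, region: GenomicInterval) -> list[SequenceBin]:
        bins = self.bins_by_chrom.get(region.chrom, [])
        if not bins:
            return []
        lo = bisect_right(self._ends[region.chrom], region.start)
        hi = bisect_left(self._starts[region.chrom], region.end)
        return bins[lo:hi]


def build_bins(
    blocks: Mapping[str, Sequence[GenomicInterval]],
) -> BinIndex:
    """Partition each chromosome at all block endpoints and emit covered bins.

    Bin boundaries are the sorted unique endpoints of every species' blocks on
    that chromosome; a bin between consecutive boundaries is emitted iff at
    least one species has a block containing it.  Species order (the profile
    axis) is the iteration order of ``blocks``.
    """
    species = list(blocks)
    n_sp = len(species)
    # gather endpoints and per-species events per chromosome
    endpoints: dict[str, set[int]] = {}
    per_species: dict[str, dict[int, list[tuple[int, int]]]] = {}
    for si, sp in enumerate(species):
        for iv in blocks[sp]:
            endpoints.setdefault(iv.chrom, set()).update((iv.start, iv.end))
            per_species.setdefault(iv.chrom, {}).setdefault(si, []).append(
                (iv.start, iv.end)
            )

    bins_by_chrom: dict[str, list[SequenceBin]] = {}
    for chrom in sorted(endpoints):
        bounds = np.array(sorted(endpoints[chrom]), dtype=np.int64)
        nseg = len(bounds) - 1
        if nseg <= 0:
            continue
        cov = np.zeros((nseg, n_sp), dtype=bool)
        for si, ivs in per_species[chrom].items():
            for a, b in ivs:
                i0 = int(np.searchsorted(bounds, a))
                i1 = int(np.searchsorted(bounds, b))
                cov[i0:i1, si] = True
        chrom_bins: list[SequenceBin] = []
        for k in range(nseg):
            if cov[k].any():
                chrom_bins.append(
                    SequenceBin(
                        GenomicInterval(chrom, int(bounds[k]), int(bounds[k + 1])),
                        tuple(int(x) for x in cov[k]),
                    )
                )
        bins_by_chrom[chrom] = chrom_bins
    return BinIndex(bins_by_chrom, n_sp)


def region_profile(
    region: ProfileRegion | GenomicInterval,
    bins: BinIndex,
    denominator: str = "region",
) -> PhyloProfile:
    """Bin-length-weighted average profile of a region.

    values[i] = sum_b overlap_len(region, b) * indicator_b[i] / L, where L is
    the region length (default) or the total overlapped bin length.
    """
    iv = region.interval if isinstance(region, ProfileRegion) else region
    if len(iv) <= 0:  # GenomicInterval forbids this, but be explicit
        raise ValueError("zero-length region")
    acc = np.zeros(bins.n_species)
    covered = 0
    for b in bins.overlapping(iv):
        ov = min(iv.end, b.interval.end) - max(iv.start, b.interval.start)
        if ov <= 0:
            continue
        covered += ov
        acc += ov * np.asarray(b.indicators, dtype=float)
    if denominator == "region":
        denom = len(iv)
    elif denominator == "aligned":
        if covered == 0:
            return PhyloProfile(tuple(0.0 for _ in range(bins.n_species)), len(iv))
        denom = covered
    else:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    vals = acc / denom
    return PhyloProfile(tuple(float(v) for v in vals), len(iv))


def profile_pcc(a: PhyloProfile | Sequence[float], b: PhyloProfile | Sequence[float]):
    """Pearson correlation of two profiles; None if either has zero variance."""
    av = np.asarray(a.values if isinstance(a, PhyloProfile) else a, dtype=float)
    bv = np.asarray(b.values if isinstance(b, PhyloProfile) else b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError(f"profile length mismatch: {av.shape} vs {bv.shape}")
    ac = av - av.mean()
    bc = bv - bv.mean()
    va, vb = float(ac @ ac), float(bc @ bc)
    if va == 0.0 or vb == 0.0:
        return None
    r = float(ac @ bc) / math.sqrt(va * vb)
    return max(-1.0, min(1.0, r))


def write_bins(bins: BinIndex, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tindicators\n")
        for chrom in sorted(bins.bins_by_chrom):
            for b in bins.bins_by_chrom[chrom]:
                fh.write(
                    f"{chrom}\t{b.interval.start}\t{b.interval.end}\t"
                    f"{''.join(map(str, b.indicators))}\n"
                )


def write_profiles(profiles: Mapping[str, PhyloProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("owner_id\tregion_length\tvalues\n")
        for owner in sorted(profiles):
            p = profiles[owner]
            fh.write(
                f"{owner}\t{p.region_length}\t"
                f"{','.join(f'{v:.10g}' for v in p.values)}\n"
            )


def load_profiles(path) -> dict[str, PhyloProfile]:
    out: dict[str, PhyloProfile] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            owner, length, values = line.rstrip("\n").split("\t")
            out[owner] = PhyloProfile(
                tuple(float(v) for v in values.split(",")), int(length)
            )
    return out
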