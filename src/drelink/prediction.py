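"""Distance filtering, replicate repeatability, and the prediction rules.

Only *distal* pairs — different chromosomes, or a gap above 500 kb between
the DRE interval and the gene body — enter prediction; for closer pairs the
profile correlation is dominated by shared genomic context rather than a
regulatory relationship.

Within one cell line a distal pair becomes a prediction iff its profile
correlation exceeds ``pcc_cutoff`` and either

* some replicate has strictly more than ``read_cutoff`` supporting reads
  (the count rule), or
* every replicate has at least one supporting read (the cross-replicate
  rescue rule).

The final set is the union over cell lines, recording provenance.  Cutoffs
are chosen by inspecting replicate repeatability over a grid: with the
lower-coverage replicate as reference, repeatability at (pcc, reads) is the
fraction of reference pairs passing both cutoffs that have >=1 read in the
other replicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .genomic_io import GeneModel, GenomicInterval

INTER_CHR = "inter_chr"
DISTAL_INTRA = "distal_intra"
WITHIN_500KB = "within_500kb"
WITHIN_50KB = "within_50kb"

DISTAL_CLASSES = frozenset({INTER_CHR, DISTAL_INTRA})

COUNT_RULE = "count_rule"
RESCUE_RULE = "rescue_rule"


@dataclass(frozen=True)
class Prediction:
    dre_id: str
    dre: GenomicInterval
    gene_id: str
    pcc: float
    evidence: str
    cell_lines: frozenset[str]
    counts: dict[str, int] = field(default_factory=dict, compare=False)

    @property
    def key(self) -> tuple[str, str]:
        return (self.dre_id, self.gene_id)


@dataclass
class CutoffGridResult:
    pcc_cutoffs: list[float]
    read_cutoffs: list[int]
    repeatability: list[list[float | None]]  # [pcc][read]; None where S empty
    n_pairs: list[list[int]]


def distance_class(
    dre: GenomicInterval,
    gene: GeneModel,
    far: int = 500_000,
    near: int = 50_000,
) -> str:
    """Distance class of a DRE-gene pair.

    The anchor is the minimum gap between the DRE interval and the gene body
    (0 when they overlap).
    """
    if dre.chrom != gene.chrom:
        return INTER_CHR
    g = dre.gap_to(gene.body)
    if g > far:
        return DISTAL_INTRA
    if g > near:
        return WITHIN_500KB
    return WITHIN_50KB


def choose_reference(totals: Mapping[str, int], rep1: str, rep2: str) -> str:
    """The reference replicate for repeatability: the one with fewer total
    Hi-C reads (ties go to the first)."""
    return rep1 if totals[rep1] <= totals[rep2] else rep2


def repeatability(
    counts_ref: Mapping[tuple[str, str], int],
    counts_other: Mapping[tuple[str, str], int],
    pcc: Mapping[tuple[str, str], float | None],
    pcc_cutoff: float,
    read_cutoff: int,
) -> tuple[float | None, int]:
    """Fraction of reference pairs passing both cutoffs that are confirmed
    (>= 1 read, no cutoffs) in the other replicate.

    Returns ``(repeatability, |S|)``; repeatability is None when no reference
    pair passes.  Pairs with undefined correlation never pass the PCC gate.
    """
    selected = [
        k
        for k, n in counts_ref.items()
        if n >= read_cutoff and pcc.get(k) is not None and pcc[k] >= pcc_cutoff
    ]
    if not selected:
        return None, 0
    confirmed = sum(1 for k in selected if counts_other.get(k, 0) >= 1)
    return confirmed / len(selected), len(selected)


def repeatability_grid(
    counts_ref: Mapping[tuple[str, str], int],
    counts_other: Mapping[tuple[str, str], int],
    pcc: Mapping[tuple[str, str], float | None],
    pcc_cutoffs: Sequence[float] = (0.7, 0.8, 0.9),
    read_cutoffs: Sequence[int] = (1, 2, 3),
) -> CutoffGridResult:
    rep = []
    npairs = []
    for pc in pcc_cutoffs:
        row_r: list[float | None] = []
        row_n: list[int] = []
        for rc in read_cutoffs:
            r, n = repeatability(counts_ref, counts_other, pcc, pc, rc)
            row_r.append(r)
            row_n.append(n)
        rep.append(row_r)
        npairs.append(row_n)
    return CutoffGridResult(list(pcc_cutoffs), list(read_cutoffs), rep, npairs)


def predict_pairs(
    counts_by_cell_line: Mapping[str, Mapping[tuple[str, str], Sequence[int]]],
    pcc: Mapping[tuple[str, str], float | None],
    dre_intervals: Mapping[str, GenomicInterval],
    pcc_cutoff: float = 0.8,
    read_cutoff: int = 2,
) -> list[Prediction]:
    """Apply the count and rescue rules per cell line and merge.

    ``counts_by_cell_line[cell][pair]`` holds the per-replicate read counts of
    a *distal* candidate pair (the caller applies the distance filter).  Both
    gates are strict: pcc > pcc_cutoff, and count > read_cutoff for the count
    rule.  A pair accepted by the count rule anywhere is labelled count_rule
    even if another cell line only rescues it.
    """
    accepted: dict[tuple[str, str], dict] = {}
    for cell, pair_counts in counts_by_cell_line.items():
        for key, reps in pair_counts.items():
            r = pcc.get(key)
            if r is None or r <= pcc_cutoff:
                continue
            reps = list(reps)
            if max(reps, default=0) > read_cutoff:
                route = COUNT_RULE
            elif len(reps) >= 2 and min(reps) >= 1:
                route = RESCUE_RULE
            else:
                continue
            rec = accepted.setdefault(
                key, {"pcc": r, "cells": set(), "route": route, "counts": {}}
            )
            rec["cells"].add(cell)
            if route == COUNT_RULE:
                rec["route"] = COUNT_RULE
            for i, n in enumerate(reps):
                rec["counts"][f"{cell}#rep{i + 1}"] = n

    out = [
        Prediction(
            dre_id=dre_id,
            dre=dre_intervals[dre_id],
            gene_id=gene_id,
            pcc=rec["pcc"],
            evidence=rec["route"],
            cell_lines=frozenset(rec["cells"]),
            counts=rec["counts"],
        )
        for (dre_id, gene_id), rec in accepted.items()
    ]
    out.sort(key=lambda p: (p.dre.chrom, p.dre.start, p.dre.end, p.gene_id))
    return out


def write_grid(grids: Mapping[str, CutoffGridResult], path) -> None:
    """One row per (cell line, pcc cutoff, read cutoff); NA where undefined."""
    with open(path, "w") as fh:
        fh.write("cell_line\tpcc_cutoff\tread_cutoff\trepeatability\tn_pairs\n")
        for cell in sorted(grids):
            g = grids[cell]
            for i, pc in enumerate(g.pcc_cutoffs):
                for j, rc in enumerate(g.read_cutoffs):
                    r = g.repeatability[i][j]
                    fh.write(
                        f"{cell}\t{pc:g}\t{rc}\t"
                        f"{'NA' if r is None else f'{r:.6f}'}\t{g.n_pairs[i][j]}\n"
                    )
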