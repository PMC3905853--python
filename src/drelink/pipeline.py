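"""End-to-end orchestration of the prediction pipeline over a data bundle.

The stages, in order: classify DHS, build sequence bins and region profiles,
count Hi-C support per candidate pair (max rule), restrict to distal pairs,
attach profile correlations, then apply the count/rescue prediction rules
per cell line and merge.  Each stage is also available separately; the CLI
wraps these functions with file-based inputs and outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

from . import annotation, hic_mapping, phyloprofile, prediction
from .annotation import ClassifiedDHS
from .genomic_io import (
    GeneModel,
    GenomicInterval,
    load_alignment_blocks,
    load_genes,
    load_hic_contacts,
    load_intervals,
)


def build_profiles(
    genes: Sequence[GeneModel],
    classified: Sequence[ClassifiedDHS],
    blocks: Mapping[str, Sequence[GenomicInterval]],
    upstream: int = 1000,
    denominator: str = "region",
):
    """Bins plus one profile per DRE (peak region) and per gene (gene region)."""
    bins = phyloprofile.build_bins(blocks)
    profiles: dict[str, phyloprofile.PhyloProfile] = {}
    for c in classified:
        if c.category == annotation.DRE:
            profiles[c.dhs_id] = phyloprofile.region_profile(
                c.interval, bins, denominator
            )
    for g in genes:
        region = annotation.gene_profile_region(g, upstream)
        profiles[g.gene_id] = phyloprofile.region_profile(region, bins, denominator)
    return bins, profiles


def pair_pcc(
    pairs: Sequence[hic_mapping.PairAnnotation],
    profiles: Mapping[str, phyloprofile.PhyloProfile],
) -> dict[tuple[str, str], float | None]:
    out: dict[tuple[str, str], float | None] = {}
    for p in pairs:
        a = profiles.get(p.dre_id)
        b = profiles.get(p.gene_id)
        r = phyloprofile.profile_pcc(a, b) if a is not None and b is not None else None
        out[p.key] = r
        p.pcc = r
    return out


def distal_pairs(
    pairs: Sequence[hic_mapping.PairAnnotation],
    dres: Mapping[str, GenomicInterval],
    genes: Mapping[str, GeneModel],
    far: int = 500_000,
    near: int = 50_000,
) -> list[hic_mapping.PairAnnotation]:
    """Attach a distance class to every pair and keep only distal ones."""
    keep = []
    for p in pairs:
        p.distance_class = prediction.distance_class(
            dres[p.dre_id], genes[p.gene_id], far, near
        )
        if p.distance_class in prediction.DISTAL_CLASSES:
            keep.append(p)
    return keep


def counts_by_cell_line(
    pairs: Sequence[hic_mapping.PairAnnotation],
    cell_lines: Sequence[str],
    replicates: Sequence[str],
) -> dict[str, dict[tuple[str, str], list[int]]]:
    """Reshape per-dataset counts into cell line -> pair -> replicate counts."""
    out: dict[str, dict[tuple[str, str], list[int]]] = {}
    for cell in cell_lines:
        table: dict[tuple[str, str], list[int]] = {}
        for p in pairs:
            reps = [p.counts.get(f"{cell}_{r}", 0) for r in replicates]
            if any(reps):
                table[p.key] = reps
        out[cell] = table
    return out


class DataBundle:
    """A simulate-style input directory loaded into memory."""

    def __init__(self, data_dir):
        data_dir = Path(data_dir)
        self.data_dir = data_dir
        with open(data_dir / "config.json") as fh:
            cfg = json.load(fh)
        self.cell_lines = [f"cl{i + 1}" for i in range(cfg["n_cell_lines"])]
        self.replicates = [f"rep{j + 1}" for j in range(cfg["n_replicates"])]
        self.datasets = [f"{c}_{r}" for c in self.cell_lines for r in self.replicates]
        self.config = cfg
        self.genes = load_genes(data_dir / "genes.tsv", "tsv")
        self.dhs = load_intervals(data_dir / "dhs.bed")
        species = [f"sp{i + 1:02d}" for i in range(cfg["n_species"])]
        self.blocks = load_alignment_blocks(data_dir / "align", species)
        self.contacts = {
            ds: load_hic_contacts(data_dir / "hic" / f"{ds}.bedpe", ds)
            for ds in self.datasets
        }

    @property
    def gene_map(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}


def run_pipeline(
    data_dir,
    tss_flank: int = 2000,
    upstream: int = 1000,
    dhs_flank: int = 1000,
    far: int = 500_000,
    near: int = 50_000,
    pcc_cutoff: float = 0.8,
    read_cutoff: int = 2,
) -> dict:
    """simulate-bundle -> predictions, returning all intermediate artifacts."""
    bundle = DataBundle(data_dir)
    classified = annotation.classify_dhs(bundle.dhs, bundle.genes, tss_flank)
    dres = {
        c.dhs_id: c.interval for c in classified if c.category == annotation.DRE
    }
    bins, profiles = build_profiles(bundle.genes, classified, bundle.blocks, upstream)
    pairs = hic_mapping.count_pair_reads(
        bundle.contacts, classified, bundle.genes, dhs_flank
    )
    distal = distal_pairs(pairs, dres, bundle.gene_map, far, near)
    pcc = pair_pcc(distal, profiles)
    by_cell = counts_by_cell_line(distal, bundle.cell_lines, bundle.replicates)
    predictions = prediction.predict_pairs(
        by_cell, pcc, dres, pcc_cutoff, read_cutoff
    )
    return {
        "bundle": bundle,
        "classified": classified,
        "dres": dres,
        "bins": bins,
        "profiles": profiles,
        "pairs": pairs,
        "distal": distal,
        "pcc": pcc,
        "counts_by_cell_line": by_cell,
        "predictions": predictions,
    }
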