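"""Synthetic dataset generator with planted DRE-target ground truth.

The generator emits every input the pipeline consumes — gene table, DHS BED,
per-species alignment BEDs, per-dataset Hi-C BEDPE, marker BEDs, expression
matrix, a toy GO corpus — plus the planted truth, all deterministic given
the seed.

The statistical structure it emulates:

* every gene and DRE has a latent presence/absence vector across the species
  panel; a *true* DRE copies its target gene's vector entry-wise with
  probability ``rho_true`` (else redraws), so true pairs correlate at about
  ``rho_true`` while background pairs are independent;
* alignment blocks are emitted only for species where the element is
  present, with jittered boundaries, so the phylogenetic-profile machinery
  recovers the latent vectors;
* per dataset (cell line x replicate), each true pair receives
  Poisson(``lambda_signal``) contacts between the DRE and a fixed "loop
  anchor" intragenic DHS of its target (drawn once per pair), on top of an
  independent Poisson(``lambda_noise``)-per-random-pair uniform background — the background ignores genomic-distance decay, which is
  adequate above the 500 kb distance filter where contact frequency is
  nearly flat;
* DREs are laid out in spatial groups (within-group gaps of ~2 kb, well
  under the 5 kb clustering threshold) and each group's true targets are
  drawn from one gene module; module genes share GO annotations and a latent
  tissue-expression profile, so predicted DRE clusters have functionally
  related, co-expressed target-gene sets;
* true pairs are always distal (inter-chromosomal or separated by more than
  500 kb).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genomic_io import GeneModel, GenomicInterval


def _default_marker_probs() -> dict:
    return {
        "dre": {"H3K4me1": 0.6, "H3K4me2": 0.5, "H3K27ac": 0.5},
        "gene": {
            "H3K4me3@promoter": 0.6,
            "H3K9ac@promoter": 0.4,
            "H3K36me3@body": 0.5,
            "H4K20me1@body": 0.4,
            "H3K27me3@promoter": 0.3,
        },
    }


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults are the package's reference conditions: a 45-species panel,
    strongly correlated true pairs (rho_true 0.9), clearly replicated Hi-C
    support at true pairs (lambda_signal 5 reads per pair per dataset) over
    a sparse background (lambda_noise 0.05 expected stray contacts per
    random DRE-gene pair per dataset), two cell lines with two replicates
    each, and 79 expression tissues.
    """

    n_species: int = 45
    n_chromosomes: int = 4
    chrom_length: int = 2_000_000
    n_genes: int = 80
    n_dhs: int = 380
    dres_per_cluster: int = 3
    fraction_true_pairs: float = 0.6
    rho_true: float = 0.9
    p_present: float = 0.5
    lambda_signal: float = 5.0
    lambda_noise: float = 0.05
    n_cell_lines: int = 2
    n_replicates: int = 2
    marker_probs: dict = field(default_factory=_default_marker_probs)
    n_tissues: int = 79
    go_modules: int = 8
    expression_noise: float = 0.5
    boundary_jitter: int = 100
    dhs_flank: int = 1000
    distance_decay: bool = False
    far: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_true_pairs <= 1.0):
            raise ValueError("fraction_true_pairs must be in [0, 1]")
        if not (0.0 <= self.rho_true <= 1.0):
            raise ValueError("rho_true must be in [0, 1]")
        for rate in (self.lambda_signal, self.lambda_noise):
            if rate < 0:
                raise ValueError("Poisson rates must be >= 0")
        for probs in self.marker_probs.values():
            for p in probs.values():
                if not (0.0 <= p <= 1.0):
                    raise ValueError("marker probabilities must be in [0, 1]")

    @property
    def cell_lines(self) -> list[str]:
        return [f"cl{i + 1}" for i in range(self.n_cell_lines)]

    @property
    def replicates(self) -> list[str]:
        return [f"rep{j + 1}" for j in range(self.n_replicates)]

    @property
    def datasets(self) -> list[str]:
        return [f"{c}_{r}" for c in self.cell_lines for r in self.replicates]


@dataclass
class GroundTruth:
    true_pairs: frozenset[tuple[str, str]]
    gene_modules: dict[str, int]


@dataclass
class _Element:
    """An element placed on the genome during layout."""

    eid: str
    interval: GenomicInterval
    kind: str  # gene body is tracked via genes list; here: dre/idhs/pdhs


def generate_dataset(config: SimulationConfig, outdir) -> GroundTruth:
    """Generate the full file bundle under ``outdir`` and return the truth.

    All feasibility checks (chromosome length, distal-target availability)
    run before any file is written; the bundle is byte-identical for a fixed
    config + seed.
    """
    rng = np.random.default_rng(config.seed)
    state = _build_in_memory(config, rng)
    _write_bundle(config, state, Path(outdir))
    return state["truth"]


def _build_in_memory(config: SimulationConfig, rng: np.random.Generator) -> dict:
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    # ---- DHS budget -----------------------------------------------------
    n_promoter = max(0, round(0.05 * config.n_dhs))
    n_intragenic = round(0.60 * config.n_dhs)
    n_dre = config.n_dhs - n_promoter - n_intragenic
    if n_dre <= 0:
        raise ValueError("n_dhs too small: no DREs left after allocation")
    n_groups = math.ceil(n_dre / config.dres_per_cluster)
    dhs_per_gene = [
        n_intragenic // config.n_genes
        + (1 if i < n_intragenic % config.n_genes else 0)
        for i in range(config.n_genes)
    ]

    # ---- layout: interleave genes and DRE groups along each chromosome --
    genes: list[GeneModel] = []
    gene_idhs: dict[str, list[GenomicInterval]] = {}
    dre_groups: list[list[tuple[str, GenomicInterval]]] = []
    promoter_dhs: list[tuple[str, GenomicInterval]] = []

    items: list[tuple[str, int]] = [("gene", i) for i in range(config.n_genes)]
    items += [("group", j) for j in range(n_groups)]
    per_chrom: dict[str, list[tuple[str, int]]] = {c: [] for c in chroms}
    for k, item in enumerate(items):
        per_chrom[chroms[k % len(chroms)]].append(item)

    dre_counter = 0
    for chrom in chroms:
        cursor = 50_000
        for kind, idx in per_chrom[chrom]:
            cursor += int(rng.integers(25_000, 40_000))
            if kind == "gene":
                length = int(rng.integers(8_000, 12_001))
                strand = "+" if rng.random() < 0.5 else "-"
                body = GenomicInterval(chrom, cursor, cursor + length, strand)
                gid = f"g{idx + 1:04d}"
                genes.append(GeneModel(gid, body))
                k_dhs = dhs_per_gene[idx]
                ivs = []
                for d in range(k_dhs):
                    center = body.start + int((d + 1) / (k_dhs + 1) * length)
                    ivs.append(GenomicInterval(chrom, center - 100, center + 100))
                gene_idhs[gid] = ivs
                if len(promoter_dhs) < n_promoter:
                    if strand == "+":
                        piv = GenomicInterval(chrom, body.start - 800, body.start - 650)
                    else:
                        piv = GenomicInterval(chrom, body.end + 650, body.end + 800)
                    promoter_dhs.append((gid, piv))
                cursor = body.end
            else:
                k_in_group = min(
                    config.dres_per_cluster, n_dre - idx * config.dres_per_cluster
                )
                group = []
                for _ in range(k_in_group):
                    iv = GenomicInterval(chrom, cursor, cursor + 200)
                    group.append((f"__dre{dre_counter}", iv))
                    dre_counter += 1
                    cursor = iv.end + 2_000
                dre_groups.append(group)
            if cursor > config.chrom_length - 10_000:
                raise ValueError(
                    f"chrom_length {config.chrom_length} too short for the "
                    f"requested gene/DHS counts on {chrom}"
                )

    # ---- assemble DHS bed with positional ids ---------------------------
    all_dhs: list[tuple[GenomicInterval, str]] = []  # (interval, role marker)
    for gid, ivs in gene_idhs.items():
        for iv in ivs:
            all_dhs.append((iv, "idhs"))
    for gid, iv in promoter_dhs:
        all_dhs.append((iv, "pdhs"))
    flat_dres = [(tmp_id, iv) for group in dre_groups for tmp_id, iv in group]
    for tmp_id, iv in flat_dres:
        all_dhs.append((iv, tmp_id))
    all_dhs.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    dhs_records: list[tuple[GenomicInterval, str]] = []
    dre_id_map: dict[str, str] = {}
    for i, (iv, role) in enumerate(all_dhs):
        dhs_id = f"dhs{i + 1:06d}"
        dhs_records.append((iv, dhs_id))
        if role.startswith("__dre"):
            dre_id_map[role] = dhs_id
    dre_groups = [
        [(dre_id_map[t], iv) for t, iv in group] for group in dre_groups
    ]
    dres: dict[str, GenomicInterval] = {d: iv for g in dre_groups for d, iv in g}

    # ---- gene modules and true-pair targets ------------------------------
    gene_modules = {g.gene_id: i % config.go_modules for i, g in enumerate(genes)}
    gene_by_id = {g.gene_id: g for g in genes}

    def _distal(span: GenomicInterval, g: GeneModel) -> bool:
        return span.chrom != g.chrom or span.gap_to(g.body) > config.far + 10_000

    n_true = round(config.fraction_true_pairs * len(dres))
    ordered_dre_ids = [d for g in dre_groups for d, _ in g]
    true_dres = set()
    if n_true > 0:
        pick = rng.choice(len(ordered_dre_ids), size=n_true, replace=False)
        true_dres = {ordered_dre_ids[i] for i in sorted(pick)}

    true_pairs: set[tuple[str, str]] = set()
    for gi, group in enumerate(dre_groups):
        span = GenomicInterval(
            group[0][1].chrom, group[0][1].start, group[-1][1].end
        )
        module = gi % config.go_modules
        module_candidates = [
            g for g in genes
            if gene_modules[g.gene_id] == module
            and gene_idhs[g.gene_id]
            and _distal(span, g)
        ]
        any_candidates = [
            g for g in genes if gene_idhs[g.gene_id] and _distal(span, g)
        ]
        if not any_candidates:
            raise ValueError(
                "no distal target gene reachable from a DRE group; "
                "increase n_chromosomes or chrom_length"
            )
        pool = module_candidates or any_candidates
        for dre_id, _iv in group:
            if dre_id not in true_dres:
                continue
            target = pool[int(rng.integers(len(pool)))]
            true_pairs.add((dre_id, target.gene_id))

    # ---- latent presence vectors -----------------------------------------
    S = config.n_species
    gene_presence = {
        g.gene_id: (rng.random(S) < config.p_present).astype(np.int8)
        for g in genes
    }
    target_of = dict(true_pairs)
    dre_presence: dict[str, np.ndarray] = {}
    for dre_id in ordered_dre_ids:
        fresh = (rng.random(S) < config.p_present).astype(np.int8)
        if dre_id in target_of:
            copy_mask = rng.random(S) < config.rho_true
            base = gene_presence[target_of[dre_id]]
            dre_presence[dre_id] = np.where(copy_mask, base, fresh).astype(np.int8)
        else:
            dre_presence[dre_id] = fresh

    # ---- alignment blocks --------------------------------------------------
    species = [f"sp{i + 1:02d}" for i in range(S)]
    align: dict[str, list[GenomicInterval]] = {sp: [] for sp in species}
    j = config.boundary_jitter
    for si, sp in enumerate(species):
        for g in genes:
            if gene_presence[g.gene_id][si]:
                b = g.body
                start = (b.start - 1000) if b.strand == "+" else b.start
                end = b.end if b.strand == "+" else (b.end + 1000)
                start = max(0, start - int(rng.integers(0, j + 1)))
                end = end + int(rng.integers(0, j + 1))
                align[sp].append(GenomicInterval(b.chrom, start, end))
        for dre_id in ordered_dre_ids:
            if dre_presence[dre_id][si]:
                iv = dres[dre_id]
                start = max(0, iv.start - int(rng.integers(0, j + 1)))
                end = iv.end + int(rng.integers(0, j + 1))
                align[sp].append(GenomicInterval(iv.chrom, start, end))

    # ---- Hi-C contacts ------------------------------------------------------
    genes_with_dhs = [g for g in genes if gene_idhs[g.gene_id]]
    gene_weights: dict[str, np.ndarray] = {}

    def _contact(dre_iv: GenomicInterval, dhs_iv: GenomicInterval):
        p1 = int(rng.integers(dre_iv.start, dre_iv.end))
        off = int(rng.integers(-config.dhs_flank // 2, config.dhs_flank // 2 + 1))
        p2 = dhs_iv.center + off
        return (
            dre_iv.chrom, max(0, p1 - 25), p1 + 25,
            dhs_iv.chrom, max(0, p2 - 25), p2 + 25,
        )

    hic: dict[str, list[tuple]] = {ds: [] for ds in config.datasets}
    ordered_true = sorted(true_pairs)
    # the looping anchor is a fixed intragenic DHS per pair, so per-dataset
    # pair counts under the max rule are exactly Poisson(lambda_signal)
    anchor_dhs = {
        (dre_id, gid): gene_idhs[gid][int(rng.integers(len(gene_idhs[gid])))]
        for dre_id, gid in ordered_true
    }
    for ds in config.datasets:
        rows = hic[ds]
        for dre_id, gid in ordered_true:
            k = int(rng.poisson(config.lambda_signal))
            dhs_iv = anchor_dhs[(dre_id, gid)]
            for _ in range(k):
                rows.append(_contact(dres[dre_id], dhs_iv))
        # background: independent Poisson(lambda_noise) per (DRE, gene) pair,
        # drawn as one pooled Poisson total assigned uniformly (equivalent)
        n_bg_pairs = len(ordered_dre_ids) * len(genes_with_dhs)
        k_bg = int(rng.poisson(n_bg_pairs * config.lambda_noise))
        for _ in range(k_bg):
            dre_id = ordered_dre_ids[int(rng.integers(len(ordered_dre_ids)))]
            if config.distance_decay:
                w = gene_weights.get(dre_id)
                if w is None:
                    span = dres[dre_id]
                    d = np.array(
                        [
                            0.0 if span.chrom != g.chrom
                            else span.gap_to(g.body)
                            for g in genes_with_dhs
                        ]
                    )
                    w = 1.0 / (1.0 + d / 1e5)
                    w /= w.sum()
                    gene_weights[dre_id] = w
                gi = int(rng.choice(len(genes_with_dhs), p=w))
            else:
                gi = int(rng.integers(len(genes_with_dhs)))
            ivs = gene_idhs[genes_with_dhs[gi].gene_id]
            dhs_iv = ivs[int(rng.integers(len(ivs)))]
            rows.append(_contact(dres[dre_id], dhs_iv))

    # ---- markers -------------------------------------------------------------
    marker_peaks: dict[str, list[GenomicInterval]] = {}
    for marker, p in config.marker_probs.get("dre", {}).items():
        peaks = []
        for dre_id in ordered_dre_ids:
            if rng.random() < p:
                iv = dres[dre_id]
                peaks.append(GenomicInterval(iv.chrom, max(0, iv.start - 50),
                                             iv.end + 50))
        marker_peaks[marker] = peaks
    for marker, p in config.marker_probs.get("gene", {}).items():
        where = marker.split("@", 1)[1]
        peaks = []
        for g in genes:
            if rng.random() < p:
                if where == "promoter":
                    tss = g.tss
                    peaks.append(GenomicInterval(g.chrom, max(0, tss - 200),
                                                 tss + 200))
                else:
                    c = g.body.center
                    peaks.append(GenomicInterval(g.chrom, c - 500, c + 500))
        marker_peaks[marker] = peaks

    # ---- expression ------------------------------------------------------------
    module_profiles = rng.normal(0.0, 1.0, size=(config.go_modules, config.n_tissues))
    expression = {
        g.gene_id: module_profiles[gene_modules[g.gene_id]]
        + rng.normal(0.0, config.expression_noise, config.n_tissues)
        for g in genes
    }

    # ---- GO corpus (3 levels: root -> module parent -> two leaves) --------------
    terms: list[tuple[str, str, str | None]] = [("SGO:0000000", "biological process",
                                                 None)]
    for m in range(config.go_modules):
        parent = f"SGO:{100 + m:07d}"
        terms.append((parent, f"module {m + 1} process", "SGO:0000000"))
        for leaf in range(2):
            terms.append(
                (f"SGO:{200 + 2 * m + leaf:07d}", f"module {m + 1} leaf {leaf + 1}",
                 parent)
            )
    within_module_index: dict[int, int] = {}
    go_annotations: list[tuple[str, str]] = []
    for g in genes:
        m = gene_modules[g.gene_id]
        k = within_module_index.get(m, 0)
        within_module_index[m] = k + 1
        leaf = f"SGO:{200 + 2 * m + (k % 2):07d}"
        go_annotations.append((g.gene_id, leaf))

    return {
        "chroms": chroms,
        "genes": genes,
        "gene_idhs": gene_idhs,
        "dhs_records": dhs_records,
        "dres": dres,
        "species": species,
        "align": align,
        "hic": hic,
        "marker_peaks": marker_peaks,
        "expression": expression,
        "go_terms": terms,
        "go_annotations": go_annotations,
        "truth": GroundTruth(frozenset(true_pairs), gene_modules),
    }


def _write_bundle(config: SimulationConfig, state: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "align").mkdir(exist_ok=True)
    (outdir / "hic").mkdir(exist_ok=True)
    (outdir / "markers").mkdir(exist_ok=True)

    with open(outdir / "genes.tsv", "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for g in state["genes"]:
            b = g.body
            fh.write(f"{g.gene_id}\t{b.chrom}\t{b.start}\t{b.end}\t{b.strand}\n")

    with open(outdir / "dhs.bed", "w") as fh:
        for iv, dhs_id in state["dhs_records"]:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{dhs_id}\n")

    for sp in state["species"]:
        with open(outdir / "align" / f"{sp}.bed", "w") as fh:
            for iv in sorted(state["align"][sp]):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")

    for ds, rows in state["hic"].items():
        with open(outdir / "hic" / f"{ds}.bedpe", "w") as fh:
            for r in rows:
                fh.write("\t".join(str(x) for x in r) + "\n")

    for marker, peaks in state["marker_peaks"].items():
        with open(outdir / "markers" / f"{marker}.bed", "w") as fh:
            for iv in peaks:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")

    tissues = [f"tissue{t + 1:02d}" for t in range(config.n_tissues)]
    with open(outdir / "expression.tsv", "w") as fh:
        fh.write("gene_id\t" + "\t".join(tissues) + "\n")
        for g in state["genes"]:
            vals = state["expression"][g.gene_id]
            fh.write(g.gene_id + "\t" + "\t".join(f"{v:.6f}" for v in vals) + "\n")

    with open(outdir / "go.obo", "w") as fh:
        fh.write("format-version: 1.2\nontology: sgo\n")
        for term_id, name, parent in state["go_terms"]:
            fh.write(f"\n[Term]\nid: {term_id}\nname: {name}\n")
            if parent is not None:
                fh.write(f"is_a: {parent}\n")

    with open(outdir / "go_annotations.tsv", "w") as fh:
        fh.write("gene_id\tterm_id\n")
        for gid, term in state["go_annotations"]:
            fh.write(f"{gid}\t{term}\n")

    truth: GroundTruth = state["truth"]
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("dre_id\tgene_id\n")
        for dre_id, gid in sorted(truth.true_pairs):
            fh.write(f"{dre_id}\t{gid}\n")
    with open(outdir / "gene_modules.tsv", "w") as fh:
        fh.write("gene_id\tmodule\n")
        for gid in sorted(truth.gene_modules):
            fh.write(f"{gid}\t{truth.gene_modules[gid]}\n")

    with open(outdir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_truth(path) -> frozenset[tuple[str, str]]:
    pairs = set()
    with open(path) as fh:
        next(fh)
        for line in fh:
            dre_id, gid = line.rstrip("\n").split("\t")
            pairs.add((dre_id, gid))
    return frozenset(pairs)


@dataclass(frozen=True)
class PredictionScore:
    precision: float | None
    recall: float
    f1: float | None
    n_predicted: int
    n_true: int
    n_correct: int


def score_predictions(
    predicted_pairs, true_pairs
) -> PredictionScore:
    """Set-overlap precision/recall/F1 of predicted vs planted distal pairs.

    Precision (and F1) are None when nothing was predicted.
    """
    pred = {(p.dre_id, p.gene_id) if hasattr(p, "dre_id") else tuple(p)
            for p in predicted_pairs}
    truth = {tuple(t) for t in true_pairs}
    correct = pred & truth
    recall = len(correct) / len(truth) if truth else 0.0
    if not pred:
        return PredictionScore(None, recall, None, 0, len(truth), 0)
    precision = len(correct) / len(pred)
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return PredictionScore(precision, recall, f1, len(pred), len(truth), len(correct))
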