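"""Indirect validation statistics for predicted DRE-target pairs.

Two reusable checks:

* histone-marker combination enrichment — is a DRE-side marker (H3K4me1/2,
  H3K27ac) jointly present with a gene-side marker (H3K4me3/H3K4ac/H3K9ac at
  the promoter; H3K36me3/H4K20me1 at the gene body; H3K27me3 at the promoter)
  among predicted pairs more often than the product of the marginal rates
  would predict?  Tested with a 1-df chi-square, no continuity correction.
* knockout differential-expression enrichment — among predicted target
  genes, are the targets whose DRE is bound by a given TF more often
  differentially expressed after knocking out the TF (or its recruiting
  partner)?  Tested with a two-sided Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .genomic_io import GeneModel, GenomicInterval


@dataclass
class MarkerAssignment:
    """Per-DRE and per-gene marker sets; gene markers carry an ``@promoter``
    or ``@body`` suffix distinguishing where the peak was required."""

    dre_markers: dict[str, set[str]]
    gene_markers: dict[str, set[str]]


@dataclass(frozen=True)
class EnrichmentResult:
    marker_pair: tuple[str, str]
    observed: float
    expected: float
    ratio: float
    chi2: float
    chi2_p: float
    n_pairs: int


def assign_markers(
    peaks: Mapping[str, Sequence[GenomicInterval]],
    dres: Mapping[str, GenomicInterval],
    genes: Sequence[GeneModel],
    promoter_flank: int = 2000,
) -> MarkerAssignment:
    """Assign markers by >=1 bp peak overlap.

    ``peaks`` maps a marker name to its peak intervals.  A plain name (e.g.
    ``H3K4me1``) is assigned to DREs by overlap with the DRE interval; a
    suffixed name (``H3K4me3@promoter``, ``H3K36me3@body``) is assigned to
    genes by overlap with the promoter window (TSS +/- promoter_flank) or the
    gene body respectively.
    """
    dre_markers: dict[str, set[str]] = {d: set() for d in dres}
    gene_markers: dict[str, set[str]] = {g.gene_id: set() for g in genes}
    for marker, ivs in peaks.items():
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in ivs:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        if "@" in marker:
            _, where = marker.split("@", 1)
            for g in genes:
                if where == "promoter":
                    tss = g.tss
                    target = GenomicInterval(
                        g.chrom, max(0, tss - promoter_flank), tss + promoter_flank + 1
                    )
                elif where == "body":
                    target = g.body
                else:
                    raise ValueError(f"unknown marker location in {marker!r}")
                if any(target.overlaps(p) for p in by_chrom.get(g.chrom, ())):
                    gene_markers[g.gene_id].add(marker)
        else:
            for dre_id, iv in dres.items():
                if any(iv.overlaps(p) for p in by_chrom.get(iv.chrom, ())):
                    dre_markers[dre_id].add(marker)
    return MarkerAssignment(dre_markers, gene_markers)


def marker_enrichment(
    pairs: Sequence[tuple[str, str]],
    markers: MarkerAssignment,
    marker_pair: tuple[str, str],
) -> EnrichmentResult:
    """Observed/expected fraction of pairs carrying both markers.

    Marginals are computed over the unique DREs and unique genes occurring in
    the pair set; the expected fraction is their product (independence).
    Significance comes from the pair-level 2x2 contingency table of DRE-side
    marker presence against gene-side marker presence (1 df chi-square, no
    continuity correction); a table with an empty margin yields chi2 = 0,
    p = 1.
    """
    if not pairs:
        raise ValueError("empty pair set")
    dre_marker, gene_marker = marker_pair
    uniq_dres = sorted({d for d, _ in pairs})
    uniq_genes = sorted({g for _, g in pairs})
    p_dre = sum(
        1 for d in uniq_dres if dre_marker in markers.dre_markers.get(d, ())
    ) / len(uniq_dres)
    p_gene = sum(
        1 for g in uniq_genes if gene_marker in markers.gene_markers.get(g, ())
    ) / len(uniq_genes)
    expected = p_dre * p_gene

    n = len(pairs)
    a = b = c = d = 0
    for dre_id, gid in pairs:
        x = dre_marker in markers.dre_markers.get(dre_id, ())
        y = gene_marker in markers.gene_markers.get(gid, ())
        if x and y:
            a += 1
        elif x:
            b += 1
        elif y:
            c += 1
        else:
            d += 1
    observed = a / n
    ratio = observed / expected if expected > 0 else float("inf") if observed else 0.0

    table = [[a, b], [c, d]]
    if min(a + b, c + d, a + c, b + d) == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        chi2, p = float(chi2), float(p)
    return EnrichmentResult(marker_pair, observed, expected, ratio, chi2, p, n)


def differential_genes(
    table: pd.DataFrame,
    p_threshold: float = 0.05,
    fc_up: float = 1.5,
    fc_down: float = 0.7,
) -> set[str]:
    """Apply the DE rule to a per-gene table with columns gene_id, p,
    fold_change: significant iff p < 0.05 and fold change > 1.5 or < 0.7."""
    mask = (table["p"] < p_threshold) & (
        (table["fold_change"] > fc_up) | (table["fold_change"] < fc_down)
    )
    return set(table.loc[mask, "gene_id"])


@dataclass(frozen=True)
class DEEnrichmentResult:
    fraction_all: float
    fraction_tf: float
    fisher_odds: float
    fisher_p: float
    table: tuple[tuple[int, int], tuple[int, int]]


def de_enrichment(
    targets_all: Iterable[str],
    targets_tf: Iterable[str],
    de_genes: Iterable[str],
    exclude: Iterable[str] = (),
) -> DEEnrichmentResult:
    """DE fraction among all predicted targets vs TF-bound-DRE targets.

    Two-sided Fisher's exact test on the 2x2 table (DE vs not) x (TF-bound vs
    not) within ``targets_all``; genes in ``exclude`` are removed from both
    groups first.
    """
    excl = set(exclude)
    all_set = set(targets_all) - excl
    tf_set = (set(targets_tf) & all_set) - excl
    if not tf_set:
        raise ValueError("targets_tf empty after exclusion")
    de = set(de_genes)
    rest = all_set - tf_set
    a = len(tf_set & de)
    b = len(tf_set - de)
    c = len(rest & de)
    d = len(rest - de)
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return DEEnrichmentResult(
        fraction_all=len(all_set & de) / len(all_set) if all_set else 0.0,
        fraction_tf=a / len(tf_set),
        fisher_odds=float(odds),
        fisher_p=float(p),
        table=((a, b), (c, d)),
    )


def write_enrichment(results: Sequence[EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("dre_marker\tgene_marker\tobserved\texpected\tratio\tchi2\tp\tn\n")
        for r in results:
            fh.write(
                f"{r.marker_pair[0]}\t{r.marker_pair[1]}\t{r.observed:.6f}\t"
                f"{r.expected:.6f}\t{r.ratio:.6f}\t{r.chi2:.6f}\t{r.chi2_p:.6g}\t"
                f"{r.n_pairs}\n"
            )
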