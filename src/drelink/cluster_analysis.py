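"""DRE clustering and the functional-relatedness / co-expression analyses.

Predicted DREs are chained into clusters by single linkage with a 5 kb gap
threshold; a cluster's target-gene set is the union of its members' predicted
targets.  For clusters with three or more target genes we score how related
those genes are, either by Resnik semantic similarity over a biological-
process GO corpus or by the Pearson correlation of tissue expression
profiles, and compare the proportion of clusters scoring above each cutoff
against same-size random gene sets.

Resnik similarity of two genes is the maximum information content of a
common ancestor over all pairs of their annotated terms, where
IC(t) = -ln(p(t)) and p(t) is the fraction of annotated genes annotated to t
or any descendant.  Terms annotated (after propagation) to fewer than
``min_genes_per_term`` genes are excluded, and IEA-evidence annotations are
expected to be excluded upstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import GenomicInterval


@dataclass(frozen=True)
class DRECluster:
    cluster_id: str
    members: tuple[str, ...]  # dre_ids sorted by position
    span: GenomicInterval
    target_genes: frozenset[str]


def cluster_dres(
    dres: Mapping[str, GenomicInterval],
    targets: Mapping[str, frozenset[str] | set[str]] | None = None,
    gap: int = 5000,
) -> list[DRECluster]:
    """Single-linkage chaining of DREs with inter-DRE gaps <= ``gap`` bp.

    DREs are sorted by (chrom, start); a DRE joins the open cluster when the
    gap between its start and the cluster span's end is at most ``gap``.
    Clusters never span chromosomes, and every DRE lands in exactly one
    cluster.
    """
    targets = targets or {}
    order = sorted(dres.items(), key=lambda kv: (kv[1].chrom, kv[1].start, kv[1].end))
    clusters: list[DRECluster] = []
    open_members: list[str] = []
    span_chrom, span_start, span_end = None, 0, 0

    def _close() -> None:
        if not open_members:
            return
        tg = frozenset().union(*(frozenset(targets.get(m, ())) for m in open_members))
        clusters.append(
            DRECluster(
                cluster_id=f"cluster{len(clusters) + 1:05d}",
                members=tuple(open_members),
                span=GenomicInterval(span_chrom, span_start, span_end),
                target_genes=tg,
            )
        )

    for dre_id, iv in order:
        if (
            span_chrom == iv.chrom
            and max(0, iv.start - span_end) <= gap
        ):
            open_members.append(dre_id)
            span_end = max(span_end, iv.end)
        else:
            _close()
            open_members = [dre_id]
            span_chrom, span_start, span_end = iv.chrom, iv.start, iv.end
    _close()
    return clusters


class GOCorpus:
    """A biological-process GO DAG (is_a edges) with gene annotations and
    per-term information content."""

    def __init__(
        self,
        parents: Mapping[str, set[str]],
        annotations: Mapping[str, set[str]],
        min_genes_per_term: int = 3,
    ):
        self.parents = {t: set(ps) for t, ps in parents.items()}
        self._check_acyclic()
        self._ancestors_cache: dict[str, frozenset[str]] = {}

        # propagate annotations to ancestors, then count genes per term
        self._gene_terms: dict[str, frozenset[str]] = {}
        genes_per_term: dict[str, set[str]] = {}
        for gene, terms in annotations.items():
            full = set()
            for t in terms:
                full |= self.ancestors(t)
            self._gene_terms[gene] = frozenset(full)
            for t in full:
                genes_per_term.setdefault(t, set()).add(gene)

        n_genes = len(self._gene_terms)
        self.valid_terms = {
            t for t, gs in genes_per_term.items() if len(gs) >= min_genes_per_term
        }
        self.ic = {
            t: -math.log(len(genes_per_term[t]) / n_genes) for t in self.valid_terms
        }

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(t: str) -> None:
            state[t] = 1
            for p in self.parents.get(t, ()):
                s = state.get(p, 0)
                if s == 1:
                    raise ValueError(f"cycle in GO DAG at term {t}")
                if s == 0:
                    visit(p)
            state[t] = 2

        for t in list(self.parents):
            if state.get(t, 0) == 0:
                visit(t)

    def ancestors(self, term: str) -> frozenset[str]:
        """The term itself plus all transitive is_a ancestors."""
        cached = self._ancestors_cache.get(term)
        if cached is not None:
            return cached
        acc = {term}
        for p in self.parents.get(term, ()):
            acc |= self.ancestors(p)
        out = frozenset(acc)
        self._ancestors_cache[term] = out
        return out

    def annotated_genes(self) -> list[str]:
        return sorted(g for g, ts in self._gene_terms.items() if ts & self.valid_terms)

    def gene_terms(self, gene: str) -> frozenset[str]:
        """Propagated, validity-filtered term set of a gene (may be empty)."""
        return self._gene_terms.get(gene, frozenset()) & frozenset(self.valid_terms)

    @classmethod
    def from_files(
        cls, obo_path, annotation_path, min_genes_per_term: int = 3
    ) -> "GOCorpus":
        """Load from an OBO file (is_a edges only) and a 2-column
        gene<TAB>term TSV."""
        import obonet

        graph = obonet.read_obo(obo_path)
        parents: dict[str, set[str]] = {t: set() for t in graph.nodes}
        for child, parent, etype in graph.edges(keys=True):
            if etype == "is_a":
                parents.setdefault(child, set()).add(parent)
        annotations: dict[str, set[str]] = {}
        with open(annotation_path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if f[0] == "gene_id":
                    continue
                annotations.setdefault(f[0], set()).add(f[1])
        return cls(parents, annotations, min_genes_per_term)


def resnik_similarity(g1: str, g2: str, corpus: GOCorpus) -> float | None:
    """Max IC of a common ancestor of any term pair of the two genes.

    None when either gene lacks usable annotations (pair skipped upstream).
    Genes sharing only the root score IC(root) = 0.
    """
    t1 = corpus.gene_terms(g1)
    t2 = corpus.gene_terms(g2)
    if not t1 or not t2:
        return None
    common = t1 & t2
    if not common:
        return None
    return max(corpus.ic[t] for t in common)


class ExpressionMatrix:
    """Genes x tissues expression table; pairwise co-expression PCC."""

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    def pcc(self, g1: str, g2: str) -> float | None:
        if g1 not in self.frame.index or g2 not in self.frame.index:
            return None
        a = self.frame.loc[g1].to_numpy(dtype=float)
        b = self.frame.loc[g2].to_numpy(dtype=float)
        ac, bc = a - a.mean(), b - b.mean()
        va, vb = float(ac @ ac), float(bc @ bc)
        if va == 0.0 or vb == 0.0:
            return None
        return float(ac @ bc) / math.sqrt(va * vb)


@dataclass
class ScoreCurves:
    cutoffs: list[float]
    observed: list[float]
    control_mean: list[float] | None
    control_sd: list[float] | None
    p_value: float | None
    cluster_means: dict[str, float] = field(default_factory=dict)


def _mean_pair_score(
    gene_set: Sequence[str],
    metric,
    gene_pos: Mapping[str, GenomicInterval] | None,
    min_gap: int | None,
) -> float | None:
    """Mean metric over unordered gene pairs; undefined pairs skipped; pairs
    closer than min_gap (same chromosome) excluded when requested."""
    genes = sorted(set(gene_set))
    vals = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if min_gap is not None and gene_pos is not None:
                a, b = gene_pos.get(genes[i]), gene_pos.get(genes[j])
                if (
                    a is not None
                    and b is not None
                    and a.chrom == b.chrom
                    and a.gap_to(b) < min_gap
                ):
                    continue
            s = metric(genes[i], genes[j])
            if s is not None:
                vals.append(s)
    return float(np.mean(vals)) if vals else None


def cluster_score_curves(
    clusters: Sequence[DRECluster],
    metric,
    universe: Sequence[str],
    cutoffs: Sequence[float],
    n_controls: int = 100,
    min_gap: int | None = None,
    gene_pos: Mapping[str, GenomicInterval] | None = None,
    min_targets: int = 3,
    seed: int = 0,
) -> ScoreCurves:
    """Observed vs random-control proportion-above-cutoff curves.

    ``metric(g1, g2)`` returns a pairwise score or None.  Only clusters with
    at least ``min_targets`` target genes enter; a cluster whose every pair is
    undefined is excluded.  Each control replicate redraws, per cluster, an
    equal-size gene set uniformly without replacement from ``universe`` and
    rebuilds the curve; the Monte Carlo p-value compares the mean observed
    proportion across cutoffs with the control distribution of the same
    statistic.
    """
    rng = np.random.default_rng(seed)
    eligible = [c for c in clusters if len(c.target_genes) >= min_targets]
    means: dict[str, float] = {}
    sizes: list[int] = []
    for c in eligible:
        m = _mean_pair_score(sorted(c.target_genes), metric, gene_pos, min_gap)
        if m is None:
            continue
        means[c.cluster_id] = m
        sizes.append(len(c.target_genes))
    if not means:
        raise ValueError("no cluster has a defined mean pair score")

    obs_vals = np.array(list(means.values()))
    observed = [float(np.mean(obs_vals > c)) for c in cutoffs]

    if n_controls <= 0:
        return ScoreCurves(list(cutoffs), observed, None, None, None, means)

    universe = list(universe)
    ctrl_props = np.zeros((n_controls, len(cutoffs)))
    for r in range(n_controls):
        ctrl_means = []
        for size in sizes:
            pick = rng.choice(len(universe), size=min(size, len(universe)),
                              replace=False)
            m = _mean_pair_score([universe[i] for i in pick], metric,
                                 gene_pos, min_gap)
            if m is not None:
                ctrl_means.append(m)
        cm = np.array(ctrl_means) if ctrl_means else np.array([-np.inf])
        ctrl_props[r] = [float(np.mean(cm > c)) for c in cutoffs]

    obs_stat = float(np.mean(observed))
    ctrl_stat = ctrl_props.mean(axis=1)
    p = (1 + int(np.sum(ctrl_stat >= obs_stat))) / (n_controls + 1)
    return ScoreCurves(
        list(cutoffs),
        observed,
        [float(x) for x in ctrl_props.mean(axis=0)],
        [float(x) for x in ctrl_props.std(axis=0, ddof=1)]
        if n_controls > 1
        else [0.0] * len(cutoffs),
        p,
        means,
    )


def write_clusters(clusters: Sequence[DRECluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tchrom\tstart\tend\tmembers\ttarget_genes\n")
        for c in clusters:
            fh.write(
                f"{c.cluster_id}\t{c.span.chrom}\t{c.span.start}\t{c.span.end}\t"
                f"{','.join(c.members)}\t{','.join(sorted(c.target_genes))}\n"
            )


def load_clusters(path) -> list[DRECluster]:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            cid, chrom, start, end, members, tg = line.rstrip("\n").split("\t")
            out.append(
                DRECluster(
                    cid,
                    tuple(members.split(",")),
                    GenomicInterval(chrom, int(start), int(end)),
                    frozenset(g for g in tg.split(",") if g),
                )
            )
    return out


def write_curves(curves: ScoreCurves, path) -> None:
    with open(path, "w") as fh:
        fh.write("cutoff\tobserved\tcontrol_mean\tcontrol_sd\n")
        for i, c in enumerate(curves.cutoffs):
            cm = "NA" if curves.control_mean is None else f"{curves.control_mean[i]:.6f}"
            cs = "NA" if curves.control_sd is None else f"{curves.control_sd[i]:.6f}"
            fh.write(f"{c:g}\t{curves.observed[i]:.6f}\t{cm}\t{cs}\n")
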