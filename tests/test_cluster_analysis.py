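import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drelink import cluster_analysis as ca
from drelink.genomic_io import GenomicInterval
from .oracles import transitive_closure_clusters

LN2 = 0.6931471805599453


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


class TestClusterDres:
    def test_gap_chaining(self):
        dres = {"a": iv("chr1", 0, 100), "b": iv("chr1", 4000, 4100),
                "c": iv("chr1", 20_000, 20_100)}
        got = ca.cluster_dres(dres, gap=5000)
        assert [set(c.members) for c in got] == [{"a", "b"}, {"c"}]
        assert got[0].span == iv("chr1", 0, 4100)

    def test_singleton(self):
        (c,) = ca.cluster_dres({"a": iv("chr1", 10, 20)})
        assert c.members == ("a",)

    def test_chain_merges_regardless_of_span(self):
        dres = {f"d{i}": iv("chr1", i * 4200, i * 4200 + 100) for i in range(30)}
        got = ca.cluster_dres(dres, gap=5000)
        assert len(got) == 1 and len(got[0].members) == 30

    def test_clusters_never_span_chromosomes(self):
        dres = {"a": iv("chr1", 0, 100), "b": iv("chr2", 0, 100)}
        assert len(ca.cluster_dres(dres, gap=5000)) == 2

    def test_target_union(self):
        dres = {"a": iv("chr1", 0, 100), "b": iv("chr1", 1000, 1100)}
        targets = {"a": {"g1"}, "b": {"g2", "g1"}}
        (c,) = ca.cluster_dres(dres, targets, gap=5000)
        assert c.target_genes == {"g1", "g2"}

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.integers(0, 60_000), min_size=1, max_size=40))
    def test_partition_and_gap_invariants(self, starts):
        dres = {f"d{i}": iv("chr1", s, s + 100) for i, s in enumerate(starts)}
        clusters = ca.cluster_dres(dres, gap=5000)
        seen = [m for c in clusters for m in c.members]
        assert sorted(seen) == sorted(dres)  # every DRE in exactly one cluster
        spans = sorted((c.span.start, c.span.end) for c in clusters)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 - e1 > 5000  # adjacent clusters farther than the gap

    def test_matches_transitive_closure(self, rng):
        dres = {}
        for i in range(500):
            chrom = f"chr{int(rng.integers(1, 4))}"
            s = int(rng.integers(0, 800_000))
            dres[f"d{i}"] = iv(chrom, s, s + int(rng.integers(50, 400)))
        got = {frozenset(c.members) for c in ca.cluster_dres(dres, gap=5000)}
        want = transitive_closure_clusters(dres, gap=5000)
        assert got == want


@pytest.fixture
def toy_corpus():
    # root -> a -> {b, c}; g1 in b, g2 in c, g3/g4 at root
    parents = {"root": set(), "a": {"root"}, "b": {"a"}, "c": {"a"}}
    annotations = {"g1": {"b"}, "g2": {"c"}, "g3": {"root"}, "g4": {"root"}}
    return ca.GOCorpus(parents, annotations, min_genes_per_term=1)


class TestResnik:
    def test_self_similarity_is_term_ic(self, toy_corpus):
        assert ca.resnik_similarity("g1", "g1", toy_corpus) == pytest.approx(
            -math.log(1 / 4)
        )

    def test_root_only_ancestor_scores_zero(self, toy_corpus):
        assert ca.resnik_similarity("g1", "g3", toy_corpus) == pytest.approx(0.0)

    def test_shared_internal_ancestor(self, toy_corpus):
        # common ancestor of b and c is a, annotated to 2 of 4 genes
        assert ca.resnik_similarity("g1", "g2", toy_corpus) == pytest.approx(LN2)

    def test_unannotated_gene_is_undefined(self, toy_corpus):
        assert ca.resnik_similarity("g1", "missing", toy_corpus) is None

    def test_symmetry_and_self_dominance(self, toy_corpus):
        for g in ("g1", "g2", "g3"):
            for h in ("g1", "g2", "g3"):
                assert ca.resnik_similarity(g, h, toy_corpus) == pytest.approx(
                    ca.resnik_similarity(h, g, toy_corpus)
                )
            assert ca.resnik_similarity(g, g, toy_corpus) >= max(
                ca.resnik_similarity(g, h, toy_corpus)
                for h in ("g1", "g2", "g3")
            )

    def test_min_genes_filter_drops_specific_terms(self):
        parents = {"root": set(), "a": {"root"}, "b": {"a"}, "c": {"a"}}
        annotations = {"g1": {"b"}, "g2": {"c"}, "g3": {"root"}, "g4": {"root"}}
        corpus = ca.GOCorpus(parents, annotations, min_genes_per_term=3)
        # only root survives (4 genes); a/b/c have < 3
        assert ca.resnik_similarity("g1", "g2", corpus) == pytest.approx(0.0)

    def test_ic_monotone_down_the_dag(self, toy_corpus):
        for t, ps in toy_corpus.parents.items():
            for p in ps:
                if t in toy_corpus.ic and p in toy_corpus.ic:
                    assert toy_corpus.ic[t] >= toy_corpus.ic[p]

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            ca.GOCorpus({"a": {"b"}, "b": {"a"}}, {"g": {"a"}})


def test_corpus_from_files(tmp_path):
    obo = tmp_path / "go.obo"
    obo.write_text(
        "format-version: 1.2\n\n[Term]\nid: T:0\nname: root\n\n"
        "[Term]\nid: T:1\nname: child\nis_a: T:0 ! root\n"
    )
    ann = tmp_path / "ann.tsv"
    ann.write_text("gene_id\tterm_id\ng1\tT:1\ng2\tT:0\ng3\tT:0\n")
    corpus = ca.GOCorpus.from_files(obo, ann, min_genes_per_term=1)
    assert corpus.ic["T:1"] == pytest.approx(-math.log(1 / 3))
    assert ca.resnik_similarity("g1", "g2", corpus) == pytest.approx(0.0)


def _clusters(score_sets):
    return [
        ca.DRECluster(f"c{i}", ("x",), GenomicInterval("chr1", 1, 2),
                      frozenset(gs))
        for i, gs in enumerate(score_sets)
    ]


class TestScoreCurves:
    def test_observed_proportion_direct_count(self):
        # two clusters with mean scores 2.0 and 0.5 at cutoff 1.0 -> 0.5
        scores = {("a", "b"): 2.0, ("c", "d"): 0.5}

        def metric(x, y):
            return scores.get((x, y), scores.get((y, x)))

        clusters = _clusters([{"a", "b"}, {"c", "d"}])
        curves = ca.cluster_score_curves(
            clusters, metric, ["a", "b", "c", "d"], [1.0],
            n_controls=0, min_targets=2,
        )
        assert curves.observed == [0.5]
        assert curves.p_value is None and curves.control_mean is None

    def test_exchangeable_scores_give_flat_pvalue(self):
        # every gene pair scores identically: observed == control, p ~ 1
        clusters = _clusters([{"a", "b", "c"}, {"d", "e", "f"}])
        curves = ca.cluster_score_curves(
            clusters, lambda x, y: 1.0, list("abcdefgh"), [0.5, 1.5],
            n_controls=50, seed=3,
        )
        assert curves.observed == curves.control_mean
        assert curves.p_value == pytest.approx(1.0)

    def test_min_targets_filters_small_clusters(self):
        clusters = _clusters([{"a", "b"}, {"c", "d", "e"}])
        curves = ca.cluster_score_curves(
            clusters, lambda x, y: 1.0, list("abcde"), [0.5], n_controls=0
        )
        assert len(curves.cluster_means) == 1

    def test_min_gap_excludes_nearby_gene_pairs(self):
        pos = {"a": iv("chr1", 0, 1000), "b": iv("chr1", 2000, 3000),
               "c": iv("chr2", 0, 1000)}
        calls = []

        def metric(x, y):
            calls.append((x, y))
            return 1.0

        clusters = _clusters([{"a", "b", "c"}])
        ca.cluster_score_curves(
            clusters, metric, list("abc"), [0.5], n_controls=0,
            min_gap=500_000, gene_pos=pos,
        )
        assert ("a", "b") not in calls  # same chromosome, 1 kb apart

    def test_all_pairs_undefined_is_error(self):
        clusters = _clusters([{"a", "b", "c"}])
        with pytest.raises(ValueError):
            ca.cluster_score_curves(
                clusters, lambda x, y: None, list("abc"), [0.5], n_controls=0
            )


def test_cluster_table_round_trip(tmp_path):
    clusters = ca.cluster_dres(
        {"a": iv("chr1", 0, 100), "b": iv("chr1", 1000, 1100)},
        {"a": {"g1"}, "b": {"g2"}},
    )
    ca.write_clusters(clusters, tmp_path / "c.tsv")
    assert ca.load_clusters(tmp_path / "c.tsv") == clusters
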