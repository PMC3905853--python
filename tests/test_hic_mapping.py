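import numpy as np
import pytest
from scipy import stats

from drelink import hic_mapping as hm
from drelink.annotation import classify_dhs
from drelink.genomic_io import BedInterval, GenomicInterval, HiCContact
from .conftest import make_gene
from .oracles import brute_force_pair_counts


def contact(chrom1, p1, chrom2, p2, ds="d1"):
    return HiCContact(chrom1, p1, chrom2, p2, ds)


@pytest.fixture
def simple_setup():
    """One DRE on chr2; one gene on chr1 with two intragenic DHS."""
    gene = make_gene("g1", "chr1", 10_000, 30_000, "+")
    dhs = [
        BedInterval("chr1", 14_900, 15_100, name="A"),   # center 15000
        BedInterval("chr1", 24_900, 25_100, name="B"),   # center 25000
        BedInterval("chr2", 500_000, 500_200, name="dre1"),
    ]
    classified = classify_dhs(dhs, [gene])
    return classified, [gene]


class TestCountPairReads:
    def test_max_rule_picks_best_dhs(self, simple_setup):
        classified, genes = simple_setup
        contacts = {"d1": [
            contact("chr2", 500_050, "chr1", 15_000),
            contact("chr1", 15_200, "chr2", 500_199),  # reversed ends
            contact("chr2", 500_100, "chr1", 14_500),
            contact("chr2", 500_100, "chr1", 25_000),  # DHS B, 1 read
        ]}
        (pa,) = hm.count_pair_reads(contacts, classified, genes)
        assert pa.key == ("dre1", "g1")
        assert pa.counts == {"d1": 3}
        assert pa.best_dhs == {"d1": "A"}

    def test_gene_without_intragenic_dhs_yields_nothing(self):
        gene = make_gene("g1", "chr1", 10_000, 30_000, "+")
        dhs = [BedInterval("chr2", 0, 200, name="dre1")]
        classified = classify_dhs(dhs, [gene])
        contacts = {"d1": [contact("chr2", 100, "chr1", 15_000)]}
        assert hm.count_pair_reads(contacts, classified, [gene]) == []

    def test_both_ends_in_same_dre_supports_nothing(self, simple_setup):
        classified, genes = simple_setup
        contacts = {"d1": [contact("chr2", 500_010, "chr2", 500_190)]}
        assert hm.count_pair_reads(contacts, classified, genes) == []

    def test_outside_capture_window_not_counted(self, simple_setup):
        classified, genes = simple_setup
        contacts = {"d1": [contact("chr2", 500_050, "chr1", 16_100)]}  # 1100 > flank
        assert hm.count_pair_reads(contacts, classified, genes) == []

    def test_adding_weaker_dhs_leaves_count_unchanged(self, simple_setup):
        classified, genes = simple_setup
        contacts = {"d1": [
            contact("chr2", 500_050, "chr1", 15_000),
            contact("chr2", 500_060, "chr1", 15_010),
            contact("chr2", 500_100, "chr1", 25_000),  # weaker DHS B
        ]}
        (pa,) = hm.count_pair_reads(contacts, classified, genes)
        assert pa.counts["d1"] == 2
        without_b = {"d1": contacts["d1"][:2]}
        (pa2,) = hm.count_pair_reads(without_b, classified, genes)
        assert pa2.counts["d1"] == pa.counts["d1"]

    def test_matches_brute_force_on_random_instance(self, rng):
        genes, dhs = [], []
        for i in range(8):
            s = 10_000 + i * 40_000
            genes.append(make_gene(f"g{i}", "chr1", s, s + 20_000, "+"))
            for d in range(3):
                c = s + 4000 + d * 6000
                dhs.append(BedInterval("chr1", c - 100, c + 100,
                                           name=f"i{i}_{d}"))
        for j in range(12):
            s = 1_000_000 + j * 10_000
            dhs.append(BedInterval("chr2", s, s + 200, name=f"dre{j}"))
        classified = classify_dhs(dhs, genes)
        contacts = {}
        for ds in ("d1", "d2"):
            recs = []
            for _ in range(250):
                p1 = int(rng.integers(1_000_000, 1_130_000))
                p2 = int(rng.integers(0, 340_000))
                recs.append(contact("chr2", p1, "chr1", p2, ds))
            contacts[ds] = recs
        got = hm.count_pair_reads(contacts, classified, genes)
        want = brute_force_pair_counts(contacts, classified, genes)
        got_flat = {
            (p.dre_id, p.gene_id, ds): n
            for p in got
            for ds, n in p.counts.items()
        }
        assert got_flat == want

    def test_counts_independent_of_dhs_number(self, rng):
        """With one signal-bearing DHS per gene, the max-rule count must not
        grow with how many quiet DHS the gene carries."""
        n_genes = 500
        genes, dhs, contacts = [], [], []
        dre = BedInterval("chrX", 1000, 1200, name="dre")
        dhs.append(dre)
        k_dhs = rng.integers(1, 9, size=n_genes)
        for i in range(n_genes):
            s = 10_000 + i * 60_000
            genes.append(make_gene(f"g{i}", "chr1", s, s + 50_000, "+"))
            for d in range(int(k_dhs[i])):
                c = s + 3000 + d * 5000
                dhs.append(BedInterval("chr1", c - 100, c + 100,
                                           name=f"i{i}_{d}"))
            # fixed per-DHS signal at the first DHS only
            for _ in range(int(rng.poisson(5))):
                contacts.append(contact("chrX", 1100, "chr1", s + 3000))
        classified = classify_dhs(dhs, genes)
        pairs = hm.count_pair_reads({"d1": contacts}, classified, genes)
        counts = {p.gene_id: p.counts["d1"] for p in pairs}
        xs = [int(k_dhs[i]) for i in range(n_genes) if f"g{i}" in counts]
        ys = [counts[f"g{i}"] for i in range(n_genes) if f"g{i}" in counts]
        rho = stats.spearmanr(xs, ys).statistic
        assert abs(rho) < 0.1


class TestDensityProfile:
    def test_uniform_reads_give_flat_ratio(self, rng):
        targets = [GenomicInterval("chr1", c - 100, c + 100)
                   for c in range(50_000, 450_000, 25_000)]
        pos = rng.integers(0, 500_000, size=40_000)
        contacts = [contact("chr1", int(p), "chrZ", 0) for p in pos]
        prof = hm.density_profile(targets, contacts)
        ratios = np.array(prof.ratio)
        assert abs(float(ratios.mean()) - 1.0) < 0.05
        assert np.all(ratios > 0.3) and np.all(ratios < 2.5)

    def test_zero_background_is_error(self):
        targets = [GenomicInterval("chr1", 99_900, 100_100)]
        contacts = [contact("chr1", 100_000, "chrZ", 0)]
        with pytest.raises(ValueError, match="background"):
            hm.density_profile(targets, contacts)

    def test_center_peak_counted_directly(self):
        c = 100_000
        targets = [GenomicInterval("chr1", c - 100, c + 100)]
        # 10 reads exactly at the center + 1 background read at c+6000
        contacts = [contact("chr1", c, "chrZ", 0) for _ in range(10)]
        contacts.append(contact("chr1", c + 6000, "chrZ", 0))
        prof = hm.density_profile(targets, contacts)
        at0 = prof.ratio[prof.offsets.index(0)]
        # observed density 10/50 over background density 1/10000
        assert at0 == pytest.approx((10 / 50) / (1 / 10_000))

    def test_empty_contacts_is_error(self):
        with pytest.raises(ValueError):
            hm.density_profile([GenomicInterval("chr1", 0, 100)], [])


def test_pair_table_round_trip(tmp_path, simple_setup):
    classified, genes = simple_setup
    contacts = {"d1": [contact("chr2", 500_050, "chr1", 15_000)],
                "d2": [contact("chr2", 500_051, "chr1", 15_001)]}
    pairs = hm.count_pair_reads(contacts, classified, genes)
    hm.write_pair_table(pairs, ["d1", "d2"], tmp_path / "pairs.tsv")
    back, datasets = hm.load_pair_table(tmp_path / "pairs.tsv")
    assert datasets == ["d1", "d2"]
    assert [(p.key, p.counts, p.best_dhs) for p in back] == [
        (p.key, p.counts, p.best_dhs) for p in pairs
    ]
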