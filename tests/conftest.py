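import numpy as np
import pytest

from drelink.genomic_io import GeneModel, GenomicInterval


def make_gene(gene_id, chrom, start, end, strand="+"):
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, strand))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One reference-condition synthetic bundle shared across tests."""
    from drelink.synthetic_data import SimulationConfig, generate_dataset

    d = tmp_path_factory.mktemp("bundle")
    cfg = SimulationConfig(seed=7)
    truth = generate_dataset(cfg, d)
    return d, cfg, truth
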