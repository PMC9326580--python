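import numpy as np
import pytest

from eskor.io_formats import FragmentSet, GeneModel


def make_gene(
    gene_id="G1",
    isoform_id=None,
    chrom="chr1",
    strand="+",
    tx_start=0,
    tx_end=1000,
    exons=None,
):
    return GeneModel(
        gene_id=gene_id,
        isoform_id=isoform_id or f"{gene_id}.1",
        chrom=chrom,
        strand=strand,
        tx_start=tx_start,
        tx_end=tx_end,
        exons=tuple(exons) if exons else ((tx_start, tx_end),),
    )


def make_fragments(fragments, condition="UNT", total_mapped=None):
    return FragmentSet.from_fragments(condition, fragments, total_mapped)


def random_sequence(rng, length, gc=0.5):
    bases = np.frombuffer(b"CGAT", dtype=np.uint8)
    u = rng.random(length)
    codes = np.full(length, bases[3])
    codes[u < gc + (1 - gc) / 2] = bases[2]
    codes[u < gc] = bases[1]
    codes[u < gc / 2] = bases[0]
    return codes.tobytes().decode("ascii")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_sim():
    """A desk-scale synthetic dataset exercising every pipeline stage."""
    from eskor.synthetic_data import SimConfig, simulate_dataset

    return simulate_dataset(
        SimConfig(n_genes=60, length_range=(6_000, 20_000), depth=200_000, seed=3)
    )
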