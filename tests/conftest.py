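import numpy as np
import pytest

from mapseq.genomeio import GeneModel, Genome, Transcript, Variant, VariantSet
from mapseq.simpop import SimConfig, simulate_genome


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def toy_genome():
    """60-bp chromosome whose first 9 bases are the complete CDS ATG GCT TAA."""
    seq = "ATGGCTTAA" + "GATTACAGGC" * 5 + "A"
    return Genome({"c1": seq})


@pytest.fixture
def toy_gene():
    """Single-exon plus-strand gene covering the toy CDS at c1:1-9."""
    t = Transcript("t1.1", exons=[(1, 9)], cds=[(1, 9, 0)])
    return GeneModel("g1", "c1", "+", [t])


@pytest.fixture(scope="session")
def sim_bundle():
    """One 20-Mb simulated genome with gene models, shared across tests."""
    cfg = SimConfig(seed=1)
    genome, genes = simulate_genome(cfg)
    return cfg, genome, genes


def make_variant(chrom="c1", pos=10, ref="G", alt="A", qual=50.0,
                 ref_count=5, alt_count=45):
    return Variant(chrom, pos, ref, alt, qual, ref_count, alt_count)


def random_variant_set(rng, n=1000, chroms=("c1", "c2"), length=5_000_000,
                       sample="rand"):
    """Seeded random VariantSet mixing SNPs and small indels."""
    records = {}
    bases = "ACGT"
    while len(records) < n:
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(1, length))
        kind = rng.random()
        ref = bases[int(rng.integers(4))]
        if kind < 0.7:
            alt = bases[int(rng.integers(4))]
            if alt == ref:
                continue
        elif kind < 0.85:
            alt = ref + "".join(bases[int(b)] for b in rng.integers(0, 4, 2))
        else:
            ref = ref + "".join(bases[int(b)] for b in rng.integers(0, 4, 2))
            alt = ref[0]
        dp = int(rng.integers(1, 80))
        alt_c = int(rng.binomial(dp, rng.random()))
        key = (chrom, pos, ref, alt)
        if key in records:
            continue
        records[key] = Variant(chrom, pos, ref, alt,
                               float(rng.integers(1, 250)), dp - alt_c, alt_c)
    return VariantSet(sample, records.values(), list(chroms))
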