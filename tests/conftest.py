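import numpy as np
import pytest

from cnvscape.sv_io import CNVRecord, CNVTable, GeneModel, GenomeIndex


def make_record(
    locus_id="c1",
    scaffold="s1",
    start=0,
    end=1000,
    svtype="DEL",
    genotypes=(1, 1),
):
    return CNVRecord(
        locus_id=locus_id,
        scaffold=scaffold,
        start=start,
        end=end,
        svtype=svtype,
        genotypes=tuple(genotypes),
    )


def make_table(records, n_samples=None, groups=None):
    if n_samples is None:
        n_samples = len(records[0].genotypes) if records else 2
    samples = tuple(f"smp{i + 1}" for i in range(n_samples))
    return CNVTable(records=list(records), samples=samples, groups=groups)


@pytest.fixture
def toy_genome():
    return GenomeIndex(("s1", "s2", "s3"), (4_000_000, 3_500_000, 2_500_000))


@pytest.fixture
def small_genome():
    return GenomeIndex(("s1", "s2"), (1_000, 500))


def random_table(rng, genome, n_records, n_samples=4, max_len=5_000):
    """Random CNVs with valid coordinates on the given genome."""
    records = []
    p = np.array(genome.lengths, dtype=float)
    p /= p.sum()
    for i in range(n_records):
        si = int(rng.choice(len(genome.names), p=p))
        scaffold = genome.names[si]
        length = int(rng.integers(1_000, max_len + 1))
        start = int(rng.integers(0, genome.lengths[si] - length))
        genotypes = tuple(int(g) for g in rng.integers(0, 3, size=n_samples))
        svtype = "DEL" if rng.random() < 0.8 else "DUP"
        records.append(
            make_record(f"c{i}", scaffold, start, start + length, svtype, genotypes)
        )
    return make_table(records, n_samples=n_samples)


def random_genes(rng, genome, n_genes, max_len=50_000):
    genes = []
    for i in range(n_genes):
        si = int(rng.integers(0, len(genome.names)))
        scaffold = genome.names[si]
        length = int(rng.integers(1_000, max_len + 1))
        start = int(rng.integers(0, genome.lengths[si] - length))
        genes.append(
            GeneModel(gene_id=f"g{i}", scaffold=scaffold, start=start, end=start + length)
        )
    return genes
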