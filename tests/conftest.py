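import numpy as np
import pytest

from popsweep.genotypes import GenotypeMatrix, PopulationMap


def make_gm(genotypes, pos=None, chrom="chr1", sample_ids=None, alt=None,
            gq=None, mq=None, contig_lengths=None):
    """Build a GenotypeMatrix from VCF-style genotype strings.

    ``genotypes`` is a list of per-site lists like ["0/0", "0|1", "./."].
    """
    n_sites = len(genotypes)
    n_samples = len(genotypes[0]) if n_sites else 0
    if sample_ids is None:
        sample_ids = [f"s{j + 1}" for j in range(n_samples)]
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    chroms = [chrom] * n_sites if isinstance(chrom, str) else list(chrom)
    alleles = np.empty((n_sites, n_samples, 2), dtype=np.int8)
    phased = np.zeros((n_sites, n_samples), dtype=bool)
    for i, row in enumerate(genotypes):
        for j, g in enumerate(row):
            sep = "|" if "|" in g else "/"
            a, b = g.split(sep)
            alleles[i, j, 0] = -1 if a == "." else int(a)
            alleles[i, j, 1] = -1 if b == "." else int(b)
            phased[i, j] = sep == "|"
    return GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(["A"] * n_sites, dtype=object),
        alt=list(alt) if alt is not None else [("C",)] * n_sites,
        alleles=alleles,
        phased=phased,
        gq=None if gq is None else np.asarray(gq, dtype=np.float32),
        mq=None if mq is None else np.asarray(mq, dtype=np.float32),
        contig_lengths=contig_lengths,
    )


def two_group_popmap(gm, n_a=None):
    """First half of samples 'native'/nat group, second half 'commercial'."""
    n = gm.n_samples
    n_a = n_a if n_a is not None else n // 2
    assignment = {}
    for j, s in enumerate(gm.sample_ids):
        assignment[s] = "nat" if j < n_a else "com"
    return PopulationMap(assignment=assignment,
                         superset={"nat": "native", "com": "commercial"})


@pytest.fixture(scope="session")
def small_panel():
    """Default small simulated panel: 2 pops x 20 diploids, 5000 SNPs."""
    from popsweep.simulate import SimConfig, simulate
    cfg = SimConfig(seed=7)
    gm, pm, truth = simulate(cfg)
    return cfg, gm, pm, truth
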