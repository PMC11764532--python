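import numpy as np
import pandas as pd
import pytest

from wolfpop.genotype_io import Dataset


def make_dataset(genotypes, populations, chrom=None, pos=None, alleles=None):
    """Small-Dataset builder for toy tests.

    ``genotypes``: (n_samples, n_snps) array-like with -1 for missing;
    ``populations``: one label per sample.
    """
    g = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_snps = g.shape
    if pos is None:
        pos = (np.arange(n_snps) + 1) * 100_000
    if chrom is None:
        chrom = ["1"] * n_snps
    if alleles is None:
        alleles = [("A", "G")] * n_snps
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{k + 1}" for k in range(n_snps)],
            "chrom": chrom,
            "pos_bp": pos,
            "allele_a": [a for a, _ in alleles],
            "allele_b": [b for _, b in alleles],
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"ind{k + 1}" for k in range(n_samples)],
            "population": populations,
        }
    )
    return Dataset(snps=snps, samples=samples, genotypes=g)


@pytest.fixture
def two_pop_toy():
    """Two populations of 3 samples at 4 SNPs, fully called."""
    g = [
        [0, 1, 2, 0],
        [0, 1, 1, 0],
        [1, 2, 2, 0],
        [2, 1, 0, 2],
        [2, 2, 0, 2],
        [1, 1, 0, 1],
    ]
    return make_dataset(g, ["popA"] * 3 + ["popB"] * 3)
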