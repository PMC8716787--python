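import numpy as np
import pytest

from epiboost.boosted_additivity import BoostConfig
from epiboost.disease_simulator import genotypes_from_pool, synth_haplotype_pool
from epiboost.genotype_data import GenePartition, GenotypeMatrix, PhenotypeVector, SnpInfo


@pytest.fixture(scope="session")
def pool():
    """Default two-gene haplotype pool (90 haplotypes, 6 + 7 SNPs)."""
    return synth_haplotype_pool(seed=11)


@pytest.fixture(scope="session")
def fast_config():
    """Low-fidelity boosting profile for quick unit tests."""
    return BoostConfig(num_rounds=30, learning_rate=0.3, n_folds=3, seed=0)


@pytest.fixture(scope="session")
def desk_config():
    return BoostConfig.desk(seed=0)


@pytest.fixture()
def small_matrix():
    """Tiny 4-sample, 3-SNP genotype matrix over two genes."""
    values = np.array(
        [
            [0, 1, 2],
            [1, 0, 0],
            [2, 2, 1],
            [0, 1, 0],
        ],
        dtype=np.int8,
    )
    snps = [
        SnpInfo("rs1", "A"),
        SnpInfo("rs2", "A"),
        SnpInfo("rs3", "B"),
    ]
    return GenotypeMatrix(values=values, snps=snps, sample_ids=["s1", "s2", "s3", "s4"])


@pytest.fixture()
def xor_data(pool):
    """Deterministic XOR phenotype from one SNP carrier flag per gene."""
    geno = genotypes_from_pool(pool, 1000, seed=5)
    u = (geno.values[:, pool.gene_blocks.s1[2]] >= 1).astype(int)
    v = (geno.values[:, pool.gene_blocks.s2[3]] >= 1).astype(int)
    pheno = PhenotypeVector(u ^ v)
    return geno, pheno


def additive_labels(geno, partition, seed=0, scale=1.0):
    """Logistic labels from an additive cross-gene log-odds (interaction null)."""
    rng = np.random.default_rng(seed)
    w1 = rng.normal(0, scale, size=len(partition.s1))
    w2 = rng.normal(0, scale, size=len(partition.s2))
    eta = geno.values[:, partition.s1] @ w1 + geno.values[:, partition.s2] @ w2
    eta -= np.median(eta)
    p = 1 / (1 + np.exp(-eta))
    return PhenotypeVector((rng.random(len(p)) < p).astype(int))
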