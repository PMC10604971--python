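import numpy as np
import pandas as pd
import pytest

from epiblup.core_data import GenotypeData
from epiblup.synthetic_data import ArchitectureConfig, simulate_dataset


def make_genotypes(haplotypes, chrom=None, pos=None) -> GenotypeData:
    """Build a GenotypeData directly from an (n, m, 2) haplotype array."""
    haps = np.asarray(haplotypes, dtype=np.int8)
    n, m, _ = haps.shape
    chrom = chrom if chrom is not None else ["1"] * m
    pos = pos if pos is not None else list(range(1000, 1000 * (m + 1), 1000))
    variants = pd.DataFrame({
        "chrom": chrom,
        "pos": pos,
        "id": [f"snp{j}" for j in range(m)],
        "ref": "A",
        "alt": "G",
    })
    return GenotypeData(
        sample_ids=[f"s{i}" for i in range(n)],
        variants=variants,
        haplotypes=haps,
        dosage=haps.sum(axis=2).astype(float),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """60 individuals, 5 blocks x 6 SNPs, additive + dominance + pairwise signal."""
    cfg = ArchitectureConfig(
        n=60, n_blocks=5, snps_per_block=6,
        variance_fractions={"A": 0.3, "D": 0.1, "AA": 0.2},
        n_causal={"A": 10, "D": 10, "AA": 20},
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def random_codes():
    """Centered random additive/dominance code matrices (n=8, m=6)."""
    from epiblup.grm_builders import CodeMatrix

    rng = np.random.default_rng(5)
    n, m = 8, 6
    ids = [f"s{i}" for i in range(n)]
    snps = [f"v{j}" for j in range(m)]
    Wv = rng.standard_normal((n, m))
    Wv -= Wv.mean(axis=0)
    Hv = rng.standard_normal((n, m))
    Hv -= Hv.mean(axis=0)
    return (CodeMatrix("additive", Wv, snps, ids),
            CodeMatrix("dominance", Hv, snps, ids))
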