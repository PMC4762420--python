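import numpy as np
import pandas as pd
import pytest

from prscog import GenotypeDataset, SimulationConfig, simulate_cohort


def make_dataset(dosages, ids=None, chrom="1", mafs=None, alleles=None) -> GenotypeDataset:
    """Build a GenotypeDataset from a raw dosage matrix (rows = samples)."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    ids = ids or [f"rs{j + 1}" for j in range(m)]
    if alleles is None:
        alleles = [("A", "G")] * m
    variants = pd.DataFrame(
        {
            "id": ids,
            "chrom": chrom,
            "pos": np.arange(1, m + 1) * 100,
            "a1": [a for a, _ in alleles],
            "a2": [b for _, b in alleles],
        }
    )
    samples = [f"S{i + 1}" for i in range(n)]
    return GenotypeDataset(variants=variants, samples=samples, dosages=dosages)


def random_dataset(rng, n, m, maf_low=0.1, maf_high=0.5, missing=0.0) -> GenotypeDataset:
    mafs = rng.uniform(maf_low, maf_high, size=m)
    dosages = rng.binomial(2, mafs, size=(n, m)).astype(float)
    if missing > 0:
        dosages[rng.random((n, m)) < missing] = np.nan
    return make_dataset(dosages)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_samples=400, n_snps=1000, n_blocks=100, seed=7, n_gwas=5000
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """One small synthetic cohort shared across read-only tests."""
    return simulate_cohort(small_config)
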