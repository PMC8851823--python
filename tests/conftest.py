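import numpy as np
import pandas as pd
import pytest

from kinreject import GenotypeMatrix, SampleRoles, SimConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_matrix(calls, sample_prefix="s", chrom="1"):
    """Build a GenotypeMatrix from a raw samples x SNPs array."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_snps = calls.shape
    samples = [f"{sample_prefix}{i + 1}" for i in range(n_samples)]
    snps = pd.DataFrame({
        "snp_id": [f"snp{j + 1}" for j in range(n_snps)],
        "chrom": [chrom] * n_snps,
        "pos": list(range(1, n_snps + 1)),
    })
    return GenotypeMatrix(samples, snps, calls)


@pytest.fixture
def small_sim():
    """A small crossbred dataset with errors, duplicates and failing SNPs."""
    cfg = SimConfig(
        n_sires=4, n_dams=10, n_offspring=30, n_snps=4000,
        error_rate=0.005, missing_rate=0.01,
        n_duplicate_samples=1, n_failing_snps=4,
        unrelated_parent_fraction=0.3, seed=11,
    )
    return simulate(cfg)


@pytest.fixture
def clean_sim():
    """Error-free dataset where every offspring has genotyped parents."""
    cfg = SimConfig(
        n_sires=3, n_dams=6, n_offspring=20, n_snps=3000,
        error_rate=0.0, missing_rate=0.0,
        n_duplicate_samples=0, n_failing_snps=0,
        unrelated_parent_fraction=0.0, seed=7,
    )
    return simulate(cfg)
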