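import numpy as np
import pandas as pd
import pytest

from ecodiff import genotyping, simulate
from ecodiff.genotyping import GenotypeMatrix


@pytest.fixture(scope="session")
def small_config() -> simulate.SimConfig:
    """A cheap two-chromosome configuration for unit tests."""
    return simulate.SimConfig(
        seed=42,
        n_pop1=20,
        n_pop2=20,
        n_chrom=2,
        chrom_length=500_000,
        n_snps=1_000,
        fst_background=0.06,
        missing_rate=0.3,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    freqs, truth = simulate.simulate_frequencies(small_config)
    matrix, table, truth2 = simulate.simulate_genotype_matrix(freqs, small_config)
    truth.true_dosage = truth2.true_dosage
    return freqs, matrix, table, truth


def make_matrix(dosage, populations=None, chrom="chr1", start_pos=100, spacing=100):
    """Small GenotypeMatrix from a dosage array (sites x samples)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_samples = dosage.shape
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start_pos + spacing * np.arange(n_sites),
            "ref": "A",
            "alt": "G",
        }
    )
    if populations is None:
        half = n_samples // 2
        populations = ["pop1"] * half + ["pop2"] * (n_samples - half)
    samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(
        sites=sites,
        samples=samples,
        populations=np.array(populations, dtype=object),
        dosage=dosage,
    )
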