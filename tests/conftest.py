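import numpy as np
import pandas as pd
import pytest

from feedgenomics.simpop import SimConfig, simulate_population


@pytest.fixture(scope="session")
def small_population():
    """Four-trait population at reduced size for structural tests."""
    config = SimConfig(n_families=10, n_snps=1000, seed=101)
    ped, geno, pheno, truth = simulate_population(config)
    return config, ped, geno, pheno, truth


@pytest.fixture(scope="session")
def signal_population():
    """Single-trait population with h2=0.3 for estimation tests."""
    config = SimConfig(
        n_families=20,
        n_snps=2000,
        traits=("T1",),
        true_h2=(0.3,),
        true_c2=(0.05,),
        genetic_corr=((1.0,),),
        trait_means=(0.0,),
        trait_sds=(1.0,),
        seed=202,
    )
    ped, geno, pheno, truth = simulate_population(config)
    return config, ped, geno, pheno, truth


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.PCG64(7))


def founder_panel(n_animals: int, n_snps: int, seed: int, maf_range=(0.2, 0.4)):
    """Unrelated-sample genotype panel in Hardy-Weinberg proportions."""
    from feedgenomics.data import GenotypeData, chrom_label

    rng = np.random.Generator(np.random.PCG64(seed))
    p = rng.uniform(*maf_range, size=n_snps)
    calls = rng.binomial(2, p, size=(n_animals, n_snps)).astype(np.int8)
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"S{i}" for i in range(n_snps)],
            "chrom": [chrom_label(1 + i % 5) for i in range(n_snps)],
            "pos": np.arange(1, n_snps + 1) * 1000,
            "minor": "A",
            "major": "C",
        }
    )
    return GenotypeData(
        animals=[f"X{i}" for i in range(n_animals)], snp_map=snp_map, calls=calls
    )
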