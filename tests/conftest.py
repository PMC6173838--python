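import pytest

from syntenic import SimConfig, simulate


@pytest.fixture(scope="session")
def small_clean_dataset():
    """Noise-free 4-chromosome dataset; every hit is a gene's true origin."""
    return simulate(SimConfig(seed=11, n_chrom_ref=4, genes_per_chrom=30,
                              n_fissions=0, scaffold_mean_genes=8))


@pytest.fixture(scope="session")
def noisy_dataset():
    """Dataset with translocations, fission and all three hit-noise channels."""
    return simulate(
        SimConfig(seed=11, n_chrom_ref=6, genes_per_chrom=40, n_translocations=4,
                  n_fissions=1, n_losses=6, n_pseudogenes=3, scaffold_mean_genes=10,
                  hit_miss_rate=0.1, spurious_hit_rate=0.2, paralog_tie_rate=0.1)
    )
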