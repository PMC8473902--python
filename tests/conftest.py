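import numpy as np
import pytest

from straintyper import (GenomeSimConfig, SpectraSimConfig, simulate_genomes,
                         simulate_spectrum_set)


@pytest.fixture(scope="session")
def small_spectra():
    """3 strains x 3 replicates of one species."""
    return simulate_spectrum_set(
        SpectraSimConfig(strains_per_species=3, replicates_per_strain=3, seed=11)
    )


@pytest.fixture(scope="session")
def genome_sim():
    """3 strains, 20 kb, 0.5% divergence each from the root."""
    return simulate_genomes(
        GenomeSimConfig(genome_length=20_000, n_strains=3, divergence=0.005, seed=7)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
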