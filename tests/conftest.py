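"""Shared fixtures: small genomes, founder populations and architectures."""
import numpy as np
import pytest

from panmixsel.genome_sim import (GenomeConfig, GenomeMap, LocusFrequencies,
                                  build_genome, high_ld_spec,
                                  make_reference_population,
                                  sample_allele_frequencies)
from panmixsel.trait_model import build_architecture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_map():
    """Two chromosomes, 40 SNPs + 12 QTL."""
    cfg = GenomeConfig((80.0, 50.0), (25, 15), (8, 4))
    return build_genome(cfg, seed=7)


@pytest.fixture
def toy_founders(toy_map):
    freqs = sample_allele_frequencies(high_ld_spec(30), toy_map, seed=8)
    return make_reference_population(freqs, toy_map, n_per_sex=30, seed=9)


@pytest.fixture
def toy_arch(toy_map, toy_founders):
    fav = toy_founders.dosage(toy_map.qtl_cols).mean(axis=0) / 2.0
    return build_architecture(toy_map.n_qtl, gen0_fav_freq=fav,
                              epistasis_fraction=0.5, seed=10)


@pytest.fixture
def flat_map():
    """One chromosome, evenly spaced SNPs only — handy for LD oracles."""
    pos = np.linspace(1.0, 99.0, 20)
    return GenomeMap(np.array([100.0]), [pos], [np.array([])])


def constant_freqs(gmap, p1, p2):
    n = gmap.n_loci
    return LocusFrequencies(np.full(n, p1), np.full(n, p2))
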