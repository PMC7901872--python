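import numpy as np
import pytest
from hypothesis import settings

import rloopkit as rk

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def specific_world():
    """100 isolated strand-specific loci (no divergent partners, fixed
    strength 30, every ssDNA strand retained) on a 1 Mb chromosome."""
    g = rk.simulate_genome(1, 1_000_000, 0.42, seed=5)
    genes, loci = rk.annotate_genes(
        g, 100, divergent_fraction=0.0, expressed_fraction=1.0, seed=5,
        strength_mean=30.0, strength_sigma=0.0, ssdna_free_fraction=0.0)
    return g, genes, loci


@pytest.fixture(scope="session")
def divergent_world():
    """Study-condition promoters: 75% divergent, variable strengths."""
    g = rk.simulate_genome(1, 1_000_000, 0.42, seed=6)
    genes, loci = rk.annotate_genes(
        g, 100, divergent_fraction=0.75, expressed_fraction=1.0, seed=6)
    return g, genes, loci


@pytest.fixture(scope="session")
def enhancer_world():
    """Four planted enhancer groups of 40 with skew 0.4 on one chromosome."""
    g = rk.simulate_genome(1, 800_000, 0.42, seed=3)
    g, enhancers, loci = rk.plant_enhancers(g, (40, 40, 40, 40), skew=0.4,
                                            seed=3)
    return g, enhancers, loci


@pytest.fixture(scope="session")
def bismapr_track(specific_world):
    g, genes, loci = specific_world
    recs = rk.run_chemistry(g, loci, "bismapr", p_conv=1.0, seed=7)
    return rk.build_tracks(recs, g.lengths)


@pytest.fixture(scope="session")
def mapr_track(specific_world):
    g, genes, loci = specific_world
    recs = rk.run_chemistry(g, loci, "mapr", seed=7)
    return rk.build_tracks(recs, g.lengths)
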