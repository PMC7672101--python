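"""Shared synthetic scenes, built once per session."""

import numpy as np
import pytest

from lesionscape import synthetic as syn
from lesionscape.catalog import GenomicTrack


@pytest.fixture(scope="session")
def small_genome():
    """2 x 1 Mb genome with 20 genes; fast enough for most tests."""
    return syn.make_genome(
        syn.GenomeSpec(n_chroms=2, chrom_length=1_000_000, n_genes=20,
                       gene_length_range=(8_000, 40_000), seed=101)
    )


@pytest.fixture(scope="session")
def small_tracks(small_genome):
    return syn.make_tracks(small_genome, seed=102)


@pytest.fixture(scope="session")
def small_scene(small_genome, small_tracks):
    spec = syn.MutagenesisSpec(seed=103, n_samples=2, n_sbs=2_000)
    records, truth = syn.make_catalog(small_genome, small_tracks, spec)
    return small_genome, small_tracks, spec, records, truth


@pytest.fixture(scope="session")
def medium_scene():
    """Larger scene used by the asymmetry-recovery tests: 2 x 5 Mb,
    100 genes, 4 samples x 5,000 SBS (20,000 mutations), pure lesion-driven
    process so the injected factors are directly estimable."""
    genome = syn.make_genome(syn.GenomeSpec(seed=111))
    tracks = syn.make_tracks(genome, seed=112)
    spec = syn.MutagenesisSpec(seed=113, n_samples=4, n_sbs=5_000,
                               mixture=(1.0, 0.0))
    records, truth = syn.make_catalog(genome, tracks, spec)
    return genome, tracks, spec, records, truth


@pytest.fixture(scope="session")
def whole_genome_regions(small_genome):
    return GenomicTrack(
        [(c, 0, L, 1.0) for c, L in small_genome.chrom_lengths.items()]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
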