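import numpy as np
import pytest

from k27compare.intervals import GenomicInterval
from k27compare.peak_calling import TagTrack
from k27compare.synthetic_data import (
    EffectSpec,
    PeakClassSpec,
    SimulationConfig,
    generate_genome,
    simulate_tracks,
)


def small_config(**overrides) -> SimulationConfig:
    """A fast, small simulated study used across tests."""
    defaults = dict(
        chrom_lengths={"chr1": 120_000, "chr2": 80_000},
        n_genes=40,
        n_peaks=20,
        seed=11,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_study():
    """Genome + tracks + truth for the default small configuration."""
    config = small_config()
    genome = generate_genome(config)
    tracks, truth = simulate_tracks(genome, config)
    return config, genome, tracks, truth


@pytest.fixture()
def uniform_track():
    """A track with one tag every 10 bp on a 100 kb chromosome."""
    return TagTrack({"chr1": np.arange(0, 100_000, 10)})


def make_intervals(spans, chrom="chr1"):
    return [GenomicInterval(chrom, s, e) for s, e in spans]


def null_pair_config(n_peaks=400, seed=5):
    """Two-sample study in which the mutant has no true effect."""
    return SimulationConfig(
        chrom_lengths={"chr1": 1_200_000, "chr2": 800_000},
        n_genes=500,
        n_peaks=n_peaks,
        samples=("mut",),
        peak_classes=[],
        seed=seed,
    )


def reduction_config(fold=2.0, fraction=0.25, seed=13, kind="uniform_reduction",
                     halfwidth=250, n_peaks=200):
    """Study with a single mutant applying one reduction class."""
    return SimulationConfig(
        chrom_lengths={"chr1": 900_000, "chr2": 600_000},
        n_genes=400,
        n_peaks=n_peaks,
        samples=("mut",),
        peak_classes=[
            PeakClassSpec(
                "affected",
                fraction,
                {"mut": EffectSpec(kind, fold, halfwidth)},
            )
        ],
        seed=seed,
    )
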