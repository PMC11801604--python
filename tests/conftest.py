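"""Shared fixtures: small hand-built maps and one session-scoped simulation.

The session simulation is the package's reference study condition for
recovery tests: a two-chromosome genome with 450 kb arms (long enough to
fit the bias polynomial over its full 400 kb range), 300 genes, 15%
essential, overdispersion alpha = 0.1, ten generations of expansion and a
mean sequencing depth of ~20 reads per insertion site.
"""

from types import SimpleNamespace

import numpy as np
import pytest

import satay_fitness as sf


@pytest.fixture
def tiny_map() -> sf.InsertionMap:
    return sf.InsertionMap.from_records(
        [
            ("chrI", 100, 3),
            ("chrI", 250, 1),
            ("chrI", 600, 5),
            ("chrII", 40, 2),
        ],
        sample_name="tiny",
    )


@pytest.fixture(scope="session")
def end_to_end() -> SimpleNamespace:
    genome = sf.simulate_genome(
        n_chrom=2,
        arm_length=450_000,
        n_genes=300,
        essential_fraction=0.15,
        seed=11,
    )
    truth = sf.default_truth(genome, seed=11, alpha=0.1)
    depth = int(20 * 0.08 * sum(genome.chrom_lengths.values()))
    library = sf.simulate_library(genome, truth, depth=depth, seed=11)
    result = sf.estimate_fitness(library, genome.genes, genome.centromeres)
    return SimpleNamespace(
        genome=genome, truth=truth, library=library, result=result, depth=depth
    )


@pytest.fixture
def flat_bias_model() -> sf.BiasModel:
    """A constant-rate model lambda = 0.1 bp^-1 everywhere."""
    return sf.BiasModel(
        coefficients=(0.0, 0.1, 0.0, 0.0),
        r_cut=200_000,
        lambda_plateau=0.1,
        rss=0.0,
        fit_range=400_000,
    )


def random_insertion_map(
    rng: np.random.Generator, n_sites: int = 200, length: int = 10_000
) -> sf.InsertionMap:
    """A small random map for symmetry/round-trip style tests."""
    pos = np.sort(rng.choice(np.arange(1, length + 1), size=n_sites, replace=False))
    reads = rng.integers(1, 50, size=n_sites)
    return sf.InsertionMap(sites={"chr1": (pos.astype(np.int64), reads.astype(np.int64))})
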