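"""Shared synthetic fixtures; everything is generated at test time."""

import numpy as np
import pytest

from hicpileup.contact_io import BinnedGenome
from hicpileup.synthetic import (
    PlantedLoop,
    SyntheticSpec,
    plant_loops,
    random_loop_sites,
    simulate_contacts,
    write_cool_fixture,
)


@pytest.fixture(scope="session")
def null_sim():
    """Feature-free decay matrix, 2 chromosomes x 300 bins, exact weights."""
    spec = SyntheticSpec(
        chrom_lengths=(("chr1", 3_000_000), ("chr2", 3_000_000)),
        resolution=10_000,
        decay_exponent=1.0,
        diagonal_value=100.0,
        seed=11,
        weight_mode="exact",
    )
    return simulate_contacts(spec)


@pytest.fixture(scope="session")
def loop_sim():
    """500 fold-3 loops (3x3 footprint) planted sparsely on a 4x15 Mb genome.

    The genome is large relative to the loop count so the planted signal
    contaminates the chromosome-wide expected by well under 1%.
    """
    base = SyntheticSpec(
        chrom_lengths=tuple((f"chr{k + 1}", 15_000_000) for k in range(4)),
        resolution=10_000,
        decay_exponent=1.0,
        diagonal_value=100.0,
        seed=23,
        weight_mode="exact",
    )
    rng = np.random.default_rng(23)
    sites = random_loop_sites(base.genome(), 500, rng, 12, 80, 25)
    spec = plant_loops(base, [PlantedLoop(c, i, j, 3.0, footprint=3) for c, i, j in sites])
    matrix, truth = simulate_contacts(spec)
    return matrix, truth, sites


@pytest.fixture(scope="session")
def cool_path(tmp_path_factory, null_sim):
    matrix, truth = null_sim
    path = tmp_path_factory.mktemp("cool") / "null.cool"
    write_cool_fixture(matrix, path, ground_truth=truth)
    return path


@pytest.fixture
def tiny_genome():
    return BinnedGenome(("chr1", "chr2"), (500_000, 400_000), 10_000)
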