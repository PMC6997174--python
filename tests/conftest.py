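"""Shared fixtures: small simulated clades reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from corephylo.simulate import SimulationConfig, simulate_clade


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def small_clade():
    """5 taxa, 30 kb, 0.5% per-branch divergence, substitution-only."""
    return simulate_clade(
        SimulationConfig(n_taxa=5, genome_length=30_000, branch_length=0.005, seed=7)
    )


@pytest.fixture(scope="session")
def small_clade_inputs(small_clade):
    from corephylo.workflow import SampleInput

    return [
        SampleInput(name=n, data_type="complete", genome=recs)
        for n, recs in small_clade.samples.items()
    ]
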