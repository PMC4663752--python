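"""Shared fixtures: synthetic studies at the scales the tests need.

Expensive simulations are session-scoped so the whole suite pays for them
once; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from vigmap import anchoring as anch
from vigmap import simulate as sim

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return BASES[rng.integers(0, 4, n)].tobytes().decode()


@pytest.fixture(scope="session")
def default_truth() -> sim.TruthSet:
    """The standard study: 2 LGs x 1 Mb, 500 F2 plants, clean fragmentation."""
    return sim.simulate_study(sim.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_placements(default_truth):
    return anch.place_probes(
        default_truth.probes(), default_truth.scaffolds
    )


@pytest.fixture(scope="session")
def defect_truth() -> sim.TruthSet:
    """A larger genome with 12 planted chimeras and 8 planted inversions."""
    cfg = sim.SimConfig(
        seed=7, n_lgs=4, lg_size=1_500_000, marker_spacing=50_000,
        n_scaffolds=44, n_chimeras=12, n_inversions=8,
    )
    truth = sim.simulate_genome(cfg)
    sim.fragment_assembly(truth)
    return truth


@pytest.fixture(scope="session")
def defect_placements(defect_truth):
    return anch.place_probes(defect_truth.probes(), defect_truth.scaffolds)


@pytest.fixture(scope="session")
def variant_fixture(default_truth):
    """Two-parent variant tables with planted pass/fail classes."""
    return sim.simulate_variants(default_truth)
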