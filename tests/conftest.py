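"""Shared fixtures: seeded random molecules, references, and simulations."""

from __future__ import annotations

import numpy as np
import pytest

from omsweep import (
    ErrorProfile,
    MapContig,
    Molecule,
    MoleculeSet,
    random_reference,
    simulate_molecules,
)


def make_molecule(rng: np.random.Generator, mol_id: int) -> Molecule:
    length = float(round(rng.uniform(50_000, 300_000), 1))
    n = int(rng.integers(0, 25))
    pos = np.sort(rng.uniform(1.0, length, size=n))
    pos = np.unique(np.round(pos, 1))
    pos = pos[pos > 0]
    return Molecule(mol_id, length, tuple(float(p) for p in pos))


def make_moleculeset(seed: int, n: int, metadata: dict | None = None) -> MoleculeSet:
    rng = np.random.default_rng(seed)
    return MoleculeSet(
        [make_molecule(rng, i + 1) for i in range(n)],
        metadata or {"BNX File Version": "1.2"},
    )


def make_contig(rng: np.random.Generator, contig_id: int) -> MapContig:
    length = float(round(rng.uniform(100_000, 2_000_000), 1))
    n = int(rng.integers(1, 40))
    pos = np.unique(np.round(np.sort(rng.uniform(1.0, length, size=n)), 1))
    cov = rng.integers(1, 60, size=pos.size)
    occ = np.minimum(cov, rng.integers(1, 60, size=pos.size))
    return MapContig(
        contig_id,
        length,
        tuple(float(p) for p in pos),
        tuple(int(o) for o in occ),
        tuple(int(c) for c in cov),
    )


@pytest.fixture(scope="session")
def small_reference() -> MapContig:
    return random_reference(1_000_000, density_per_100kbp=10.5, seed=7)


@pytest.fixture(scope="session")
def noiseless_sim(small_reference):
    ms, truth = simulate_molecules(
        small_reference,
        err=ErrorProfile(0.0, 0.0, 0.0, 1.0, seed=3),
        n_molecules=60,
    )
    return ms, truth


@pytest.fixture(scope="session")
def noisy_sim(small_reference):
    ms, truth = simulate_molecules(
        small_reference,
        err=ErrorProfile(seed=9),
        n_molecules=60,
    )
    return ms, truth
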