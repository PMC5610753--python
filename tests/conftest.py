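"""Shared fixtures: random molecular graphs and small planted datasets."""

import numpy as np
import pytest

from qsarlab import (AtomicProperties, AtomicPropertyTable, DescriptorTable,
                     MolecularGraph, SyntheticSpec, generate_dataset)
from qsarlab.molgraph import Atom

ELEMENTS = ["C", "N", "O", "S", "Cl"]


def random_molecular_graph(rng: np.random.Generator, n_min=4, n_max=12,
                           with_coords=False) -> MolecularGraph:
    """Random connected heavy-atom graph (tree + extra edges)."""
    n = int(rng.integers(n_min, n_max + 1))
    atoms = [Atom(str(rng.choice(ELEMENTS)), hybridization="sp3",
                  xyz=tuple(rng.normal(size=3) * 3) if with_coords else None)
             for _ in range(n)]
    edges = {(int(rng.integers(0, k)), k) for k in range(1, n)}   # random tree
    extra = int(rng.integers(0, max(1, n // 3)))
    for _ in range(extra):
        i, j = sorted(rng.choice(n, size=2, replace=False).tolist())
        edges.add((i, j))
    bonds = [(i, j, 1.0) for i, j in sorted(edges)]
    return MolecularGraph(atoms, bonds)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def unit_props():
    """Test property table: C/N/O weigh 1/2/3 on every property (no scaling)."""
    return AtomicPropertyTable({
        "C": AtomicProperties(1, 1, 1, 1),
        "N": AtomicProperties(2, 2, 2, 2),
        "O": AtomicProperties(3, 3, 3, 3),
    }, carbon_scaled=False)


@pytest.fixture
def planted_table() -> DescriptorTable:
    """40 compounds, 10 independent descriptors, y = 2·D003 + ε(σ=0.01)."""
    spec = SyntheticSpec(n_train=40, n_test=0, p=10, support=(3,), beta=(2.0,),
                         intercept=0.0, noise_sd=0.01, seed=7)
    return generate_dataset(spec).train


@pytest.fixture
def small_table() -> DescriptorTable:
    """27 compounds × 8 correlated descriptors with moderate noise."""
    spec = SyntheticSpec(n_train=27, n_test=7, p=8, block_sizes=(4,),
                         block_rho=0.6, support=(0, 5), beta=(1.0, -0.8),
                         intercept=5.0, noise_sd=0.3, seed=11)
    return generate_dataset(spec).train
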