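"""Synthetic descriptor data and toy molecules.

The generator emulates the statistical shape of the study setting this
package is built for: a small training set (27 compounds) plus a small
external test set (7), a few hundred descriptors organised in strongly
collinear blocks, and an activity (pIC50) that is a sparse linear function
of a handful of descriptors plus Gaussian noise.  Collinearity is induced
by a shared latent factor per block,

    x = sqrt(ρ)·z_block + sqrt(1−ρ)·ε,

which gives every within-block pair a population correlation of ρ — the
"forcefully correlated and numerous X variables" regime PLS is credited
with handling.  Descriptor marginals are standard normal; model builders
standardize internally anyway.

Randomness uses one root seed with per-purpose substreams (descriptors,
noise, train/test split) so the draws are reproducible bit-for-bit.

Toy molecules are tiny, fully specified :class:`MolecularGraph` fixtures
for descriptor unit tests and screening demos.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .data import DescriptorTable
from .exceptions import SpecificationError, UnknownTemplateError
from .molgraph import Atom, MolecularGraph


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one synthetic dataset (identical spec ⇒ identical data)."""

    n_train: int = 27
    n_test: int = 7
    p: int = 200
    block_sizes: tuple[int, ...] = ()
    block_rho: float = 0.0
    support: tuple[int, ...] = ()
    beta: tuple[float, ...] = ()
    intercept: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_train < 2:
            raise SpecificationError("n_train must be ≥ 2")
        if self.n_test < 0:
            raise SpecificationError("n_test must be ≥ 0")
        if self.p < 1:
            raise SpecificationError("p must be ≥ 1")
        if sum(self.block_sizes) > self.p:
            raise SpecificationError("block sizes exceed descriptor count")
        if any(b < 1 for b in self.block_sizes):
            raise SpecificationError("block sizes must be positive")
        if not (0.0 <= self.block_rho < 1.0):
            raise SpecificationError("block_rho must lie in [0, 1)")
        if len(self.support) != len(self.beta):
            raise SpecificationError("support and beta lengths differ")
        if any(not (0 <= j < self.p) for j in self.support):
            raise SpecificationError("support index out of range")
        if len(set(self.support)) != len(self.support):
            raise SpecificationError("duplicate support indices")
        if self.noise_sd < 0:
            raise SpecificationError("noise_sd must be ≥ 0")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            d = json.load(fh)
        for k in ("block_sizes", "support", "beta"):
            d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class SyntheticDataset:
    train: DescriptorTable
    test: DescriptorTable
    truth: SyntheticSpec


def study_spec(seed: int = 0, noise_sd: float = 0.15) -> SyntheticSpec:
    """The package's reference study condition.

    27 training + 7 test compounds, 200 descriptors of which 100 sit in ten
    collinear blocks (ρ = 0.8), a 5-descriptor true model and pIC50 noise of
    0.15 — the scale of a careful cytotoxicity assay on a log10 axis.
    """
    return SyntheticSpec(
        n_train=27, n_test=7, p=200,
        block_sizes=(10,) * 10, block_rho=0.8,
        support=(3, 17, 42, 120, 187),
        beta=(1.2, -1.0, 0.9, 0.7, -0.8),
        intercept=4.97, noise_sd=noise_sd, seed=seed,
    )


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one dataset from the spec's generative model.

    Descriptors: block members share a latent standard-normal factor with
    loading sqrt(block_rho); descriptors outside any block are independent
    N(0,1).  Activity = intercept + Σ beta·x[support] + N(0, noise_sd²).
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_x, rng_noise, rng_split = (np.random.default_rng(s) for s in ss.spawn(3))

    n = spec.n_train + spec.n_test
    X = np.empty((n, spec.p))
    col = 0
    rho = spec.block_rho
    for size in spec.block_sizes:
        z = rng_x.standard_normal((n, 1))
        eps = rng_x.standard_normal((n, size))
        X[:, col:col + size] = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps
        col += size
    if col < spec.p:
        X[:, col:] = rng_x.standard_normal((n, spec.p - col))

    y = spec.intercept + X[:, list(spec.support)] @ np.asarray(spec.beta)
    y = y + spec.noise_sd * rng_noise.standard_normal(n)

    names = [f"D{j:03d}" for j in range(spec.p)]
    order = rng_split.permutation(n)
    train_rows = np.sort(order[:spec.n_train])
    test_rows = np.sort(order[spec.n_train:])
    train = DescriptorTable.from_arrays(
        [f"train_{k + 1:02d}" for k in range(spec.n_train)],
        names, X[train_rows], y[train_rows])
    test = DescriptorTable.from_arrays(
        [f"test_{k + 1:02d}" for k in range(spec.n_test)],
        names, X[test_rows], y[test_rows] if spec.n_test else None)
    return SyntheticDataset(train=train, test=test, truth=spec)


# ---------------------------------------------------------------------------
# toy molecules
# ---------------------------------------------------------------------------

def _path(elements, hybrid=None, coords=None):
    atoms = [Atom(el,
                  hybridization=None if hybrid is None else hybrid[k],
                  xyz=None if coords is None else tuple(coords[k]))
             for k, el in enumerate(elements)]
    bonds = [(k, k + 1, 1.0) for k in range(len(elements) - 1)]
    return MolecularGraph(atoms, bonds)


def _dimethyl_ether():
    # CH3-O-CH3 with explicit hydrogens
    atoms = [Atom("C", hybridization="sp3"), Atom("O", hybridization="sp3"),
             Atom("C", hybridization="sp3")]
    bonds = [(0, 1, 1.0), (1, 2, 1.0)]
    for c in (0, 2):
        for _ in range(3):
            atoms.append(Atom("H", hybridization="s"))
            bonds.append((c, len(atoms) - 1, 1.0))
    return MolecularGraph(atoms, bonds)


def _chlorobenzene():
    atoms = [Atom("C", aromatic=True, hybridization="sp2") for _ in range(6)]
    bonds = [(k, (k + 1) % 6, 1.5) for k in range(6)]
    atoms.append(Atom("Cl", hybridization="sp3"))
    bonds.append((0, 6, 1.0))
    for k in range(1, 6):
        atoms.append(Atom("H", hybridization="s"))
        bonds.append((k, len(atoms) - 1, 1.0))
    return MolecularGraph(atoms, bonds)


def _ethylene():
    atoms = [Atom("C", hybridization="sp2"), Atom("C", hybridization="sp2")]
    bonds = [(0, 1, 2.0)]
    for c in (0, 0, 1, 1):
        atoms.append(Atom("H", hybridization="s"))
        bonds.append((c, len(atoms) - 1, 1.0))
    return MolecularGraph(atoms, bonds)


def _acetanilide():
    # CH3-C(=O)-NH-C6H5, explicit hydrogens
    atoms = [Atom("C", hybridization="sp3"),       # 0 methyl
             Atom("C", hybridization="sp2"),       # 1 carbonyl C
             Atom("O", hybridization="sp2"),       # 2 carbonyl O
             Atom("N", hybridization="sp3")]       # 3 amide N
    bonds = [(0, 1, 1.0), (1, 2, 2.0), (1, 3, 1.0)]
    ring0 = len(atoms)
    for _ in range(6):
        atoms.append(Atom("C", aromatic=True, hybridization="sp2"))
    for k in range(6):
        bonds.append((ring0 + k, ring0 + (k + 1) % 6, 1.5))
    bonds.append((3, ring0, 1.0))
    for _ in range(3):                              # methyl Hs
        atoms.append(Atom("H", hybridization="s"))
        bonds.append((0, len(atoms) - 1, 1.0))
    atoms.append(Atom("H", hybridization="s"))      # amide H
    bonds.append((3, len(atoms) - 1, 1.0))
    for k in range(1, 6):                           # ring Hs
        atoms.append(Atom("H", hybridization="s"))
        bonds.append((ring0 + k, len(atoms) - 1, 1.0))
    return MolecularGraph(atoms, bonds)


def _bisamide():
    # CH3-NH-C(=O)-CH2-C(=O)-NH2: two inequivalent amide N-H sites
    atoms = [Atom("N", hybridization="sp3"),    # 0 N-methyl amide N (1 H)
             Atom("C", hybridization="sp2"),    # 1
             Atom("O", hybridization="sp2"),    # 2
             Atom("C", hybridization="sp3"),    # 3 methylene
             Atom("C", hybridization="sp2"),    # 4
             Atom("O", hybridization="sp2"),    # 5
             Atom("N", hybridization="sp3"),    # 6 primary amide N (2 H)
             Atom("C", hybridization="sp3")]    # 7 N-methyl
    bonds = [(0, 1, 1.0), (1, 2, 2.0), (1, 3, 1.0),
             (3, 4, 1.0), (4, 5, 2.0), (4, 6, 1.0), (0, 7, 1.0)]
    for c in (0, 3, 3, 6, 6, 7, 7, 7):
        atoms.append(Atom("H", hybridization="s"))
        bonds.append((c, len(atoms) - 1, 1.0))
    return MolecularGraph(atoms, bonds)


_TEMPLATES = {
    # two oxygens a single bond and 1.5 Å apart — minimal G(O..O) fixture
    "dioxygen_1p5A": lambda: _path(["O", "O"],
                                   coords=[(0, 0, 0), (1.5, 0, 0)]),
    # 3-atom path whose elements C,N,O give weights 1,2,3 under the unit
    # test property table (C=1, N=2, O=3)
    "path3_w123": lambda: _path(["C", "N", "O"], hybrid=["sp3"] * 3),
    # 4-atom carbon path: degrees 1,2,2,1, exactly one 3-bond path
    "path4": lambda: _path(["C"] * 4, hybrid=["sp3"] * 4),
    "path3": lambda: _path(["C"] * 3, hybrid=["sp3"] * 3),
    # three O on a 3-4-5 right triangle — G(O..O) = 12
    "o3_right_triangle": lambda: _path(
        ["O"] * 3, coords=[(0, 0, 0), (3, 0, 0), (0, 4, 0)]),
    "linear_ether": _dimethyl_ether,
    "chlorobenzene": _chlorobenzene,
    "ethylene": _ethylene,
    "acetanilide": _acetanilide,
    "bisamide": _bisamide,
}


def toy_molecule_names() -> list[str]:
    return sorted(_TEMPLATES)


def generate_toy_molecule(template_name: str) -> MolecularGraph:
    """Return a fresh copy of a documented fixture molecule."""
    try:
        factory = _TEMPLATES[template_name]
    except KeyError:
        raise UnknownTemplateError(
            f"unknown toy molecule {template_name!r}; "
            f"available: {', '.join(toy_molecule_names())}") from None
    g = factory()
    return MolecularGraph([replace(a) for a in g.atoms], list(g.bonds))
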