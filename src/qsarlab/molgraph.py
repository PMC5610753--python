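"""Molecular graphs and the atomic property table behind descriptor weights.

A :class:`MolecularGraph` is a minimal chemical graph: ordered atoms
(element, formal charge, aromatic flag, hybridization label, optional 3D
coordinates in Å) and bonds with orders.  It is deliberately lighter than an
RDKit molecule — descriptor code needs exactly this much and the test
fixtures construct graphs directly — but a converter from RDKit (and hence
SDF/MOL files) is provided.

The :class:`AtomicPropertyTable` carries the four atomic weightings the 2D
autocorrelation descriptors use: mass, van der Waals volume, polarizability
and Sanderson electronegativity.  Weights are carbon-scaled (w_i = p_i / p_C)
following the convention of the Dragon descriptor software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .exceptions import SpecificationError

HALOGENS = frozenset({"F", "Cl", "Br", "I"})

# property code letters used in descriptor names (MATS7v, GATS6m, ...)
PROPERTY_CODES = {
    "m": "mass",
    "v": "vdw_volume",
    "p": "polarizability",
    "e": "electronegativity",
}


@dataclass(frozen=True)
class AtomicProperties:
    mass: float                 # u
    vdw_volume: float           # Å^3, from Bondi radii (4/3 π r^3)
    polarizability: float       # 10^-24 cm^3
    electronegativity: float    # Sanderson scale

    def __post_init__(self):
        for name in ("mass", "vdw_volume", "polarizability", "electronegativity"):
            if getattr(self, name) <= 0:
                raise SpecificationError(f"atomic property {name} must be positive")


@dataclass(frozen=True)
class AtomicPropertyTable:
    """Element → atomic property mapping with carbon-scaled weight lookup."""

    properties: Mapping[str, AtomicProperties]
    carbon_scaled: bool = True

    def weight(self, element: str, prop: str) -> float:
        try:
            value = getattr(self.properties[element], prop)
        except KeyError:
            raise SpecificationError(f"no atomic properties for element {element!r}")
        if self.carbon_scaled:
            value /= getattr(self.properties["C"], prop)
        return value

    def weights(self, elements: Iterable[str], prop: str) -> np.ndarray:
        return np.array([self.weight(el, prop) for el in elements], dtype=float)


DEFAULT_PROPERTIES = AtomicPropertyTable({
    #                       mass     VvdW   polar  Sanderson
    "H": AtomicProperties(1.008, 7.24, 0.667, 2.592),
    "C": AtomicProperties(12.011, 20.58, 1.760, 2.746),
    "N": AtomicProperties(14.007, 15.60, 1.100, 3.194),
    "O": AtomicProperties(15.999, 14.71, 0.802, 3.654),
    "F": AtomicProperties(18.998, 13.31, 0.557, 4.000),
    "S": AtomicProperties(32.060, 24.43, 2.900, 2.957),
    "Cl": AtomicProperties(35.450, 22.45, 2.180, 3.475),
    "Br": AtomicProperties(79.904, 26.52, 3.050, 3.219),
    "I": AtomicProperties(126.904, 32.52, 5.350, 2.778),
})


@dataclass
class Atom:
    element: str
    formal_charge: int = 0
    aromatic: bool = False
    hybridization: str | None = None   # "sp", "sp2", "sp3" (lower case)
    xyz: tuple[float, float, float] | None = None


@dataclass
class MolecularGraph:
    """Atoms plus bonds (pairs of atom indices with a bond order)."""

    atoms: list[Atom]
    bonds: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.atoms)
        norm = []
        for b in self.bonds:
            i, j = int(b[0]), int(b[1])
            order = float(b[2]) if len(b) > 2 else 1.0
            if i == j:
                raise SpecificationError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise SpecificationError(f"bond ({i},{j}) references missing atom")
            norm.append((i, j, order))
        self.bonds = norm
        with_xyz = sum(a.xyz is not None for a in self.atoms)
        if with_xyz not in (0, n):
            raise SpecificationError("either all atoms carry coordinates or none")

    # -- views -------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def has_coordinates(self) -> bool:
        return bool(self.atoms) and self.atoms[0].xyz is not None

    def coordinates(self) -> np.ndarray:
        if not self.has_coordinates:
            raise SpecificationError("graph has no 3D coordinates")
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def neighbors(self, idx: int) -> list[int]:
        out = []
        for i, j, _ in self.bonds:
            if i == idx:
                out.append(j)
            elif j == idx:
                out.append(i)
        return out

    def bond_order(self, i: int, j: int) -> float | None:
        for a, b, order in self.bonds:
            if {a, b} == {i, j}:
                return order
        return None

    def adjacency(self) -> np.ndarray:
        A = np.zeros((self.n_atoms, self.n_atoms))
        for i, j, _ in self.bonds:
            A[i, j] = A[j, i] = 1.0
        return A

    def heavy_atom_graph(self) -> tuple["MolecularGraph", list[int]]:
        """Hydrogen-suppressed copy plus the kept original indices."""
        keep = [i for i, a in enumerate(self.atoms) if a.element != "H"]
        remap = {old: new for new, old in enumerate(keep)}
        atoms = [replace(self.atoms[i]) for i in keep]
        bonds = [(remap[i], remap[j], o) for i, j, o in self.bonds
                 if i in remap and j in remap]
        return MolecularGraph(atoms, bonds), keep

    def translated(self, shift) -> "MolecularGraph":
        shift = np.asarray(shift, dtype=float)
        atoms = [replace(a, xyz=tuple(np.asarray(a.xyz) + shift)) for a in self.atoms]
        return MolecularGraph(atoms, list(self.bonds))

    def rotated(self, R) -> "MolecularGraph":
        R = np.asarray(R, dtype=float)
        atoms = [replace(a, xyz=tuple(R @ np.asarray(a.xyz))) for a in self.atoms]
        return MolecularGraph(atoms, list(self.bonds))

    def permuted(self, perm: list[int]) -> "MolecularGraph":
        """Reindex atoms so new atom k is old atom perm[k]."""
        inverse = {old: new for new, old in enumerate(perm)}
        atoms = [replace(self.atoms[old]) for old in perm]
        bonds = [(inverse[i], inverse[j], o) for i, j, o in self.bonds]
        return MolecularGraph(atoms, bonds)

    def to_networkx(self):
        import networkx as nx

        G = nx.Graph()
        for i, a in enumerate(self.atoms):
            G.add_node(i, element=a.element, charge=a.formal_charge,
                       aromatic=a.aromatic)
        for i, j, o in self.bonds:
            G.add_edge(i, j, order=o)
        return G

    # -- RDKit bridge ------------------------------------------------------
    @classmethod
    def from_rdkit(cls, mol) -> "MolecularGraph":
        """Convert an RDKit Mol (with explicit Hs as present in the input)."""
        conf = mol.GetConformer() if mol.GetNumConformers() else None
        atoms = []
        for atom in mol.GetAtoms():
            xyz = None
            if conf is not None:
                p = conf.GetAtomPosition(atom.GetIdx())
                xyz = (p.x, p.y, p.z)
            atoms.append(Atom(
                element=atom.GetSymbol(),
                formal_charge=atom.GetFormalCharge(),
                aromatic=atom.GetIsAromatic(),
                hybridization=str(atom.GetHybridization()).lower(),
                xyz=xyz,
            ))
        bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
                 for b in mol.GetBonds()]
        return cls(atoms, bonds)


def read_sdf(path, names: list[str] | None = None) -> dict[str, MolecularGraph]:
    """Read an SDF/MOL file into named molecular graphs.

    Molecule names come from the SDF title line (falling back to mol_<k>);
    3D coordinates are honoured when the file provides them.
    """
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    out: dict[str, MolecularGraph] = {}
    for k, mol in enumerate(supplier):
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") \
            else f"mol_{k}"
        if names is not None:
            name = names[k]
        out[name] = MolecularGraph.from_rdkit(mol)
    return out


def pairwise_distance(a: tuple[float, float, float],
                      b: tuple[float, float, float]) -> float:
    return math.dist(a, b)
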