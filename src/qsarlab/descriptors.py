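"""Molecular descriptor calculators.

Implements the descriptor families the QSAR models use:

* quantum-chemical indices (hardness η, softness S, electronegativity χ,
  electrophilicity ω) from HOMO/LUMO energies,
* 2D autocorrelations over topological distance "lags" — Broto-Moreau ATS,
  Moran MATS and Geary GATS — weighted by atomic mass (m), van der Waals
  volume (v), polarizability (p) or Sanderson electronegativity (e),
* the average 3rd-order connectivity index X3A,
* geometric element-pair distance sums G(A..B) and asphericity ASP,
* the fragment counts nROR (aliphatic ethers), nPhX (halogen on aromatic
  carbon) and H-048 (H on C2(sp3)/C1(sp2)/C0(sp) carbons).

Topological descriptors work on the hydrogen-suppressed graph (the Dragon
convention); H-048 requires explicit hydrogens.  A quantity that is a sum
over a lag with no contributing pair is defined as 0 and logged, so that
descriptor matrices stay rectangular for regression.

Descriptor names that the package cannot compute natively (e.g. Ss, qpos,
MAXDP, X3AV, ATS8p at exotic weightings) may be supplied through an external
table; :func:`compute_descriptor_table` merges both sources and records the
provenance of every column.
"""

from __future__ import annotations

import itertools
import logging
import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .data import DescriptorTable
from .exceptions import DegenerateInputError, MissingDescriptorError, SpecificationError
from .molgraph import (DEFAULT_PROPERTIES, HALOGENS, PROPERTY_CODES,
                       AtomicPropertyTable, MolecularGraph)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# quantum-chemical indices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectronicSummary:
    """Per-compound quantum-chemistry output taken as given."""

    homo: float
    lumo: float
    dmx: float = 0.0
    dmy: float = 0.0
    dmz: float = 0.0

    def __post_init__(self):
        if not (math.isfinite(self.homo) and math.isfinite(self.lumo)):
            raise SpecificationError("HOMO/LUMO energies must be finite")


@dataclass(frozen=True)
class QuantumIndices:
    hardness: float          # η
    softness: float          # S = 1/η
    electronegativity: float  # χ
    electrophilicity: float  # ω = χ²/(2η)


def quantum_indices(es: ElectronicSummary, convention: str = "paper") -> QuantumIndices:
    """Hardness, softness, electronegativity and electrophilicity.

    ``convention="paper"`` (default) uses the source study's printed
    formulas, η = 0.5·(HOMO+LUMO) and χ = −0.5·(HOMO−LUMO) — note these swap
    the roles the textbook definitions assign to η and χ.
    ``convention="standard"`` uses the conventional η = 0.5·(LUMO−HOMO),
    χ = −0.5·(HOMO+LUMO).
    """
    if convention == "paper":
        eta = 0.5 * (es.homo + es.lumo)
        chi = -0.5 * (es.homo - es.lumo)
    elif convention == "standard":
        eta = 0.5 * (es.lumo - es.homo)
        chi = -0.5 * (es.homo + es.lumo)
    else:
        raise SpecificationError(f"unknown convention {convention!r}")
    if eta == 0:
        raise DegenerateInputError(
            "hardness η = 0: softness S = 1/η and electrophilicity ω = χ²/(2η) "
            "are undefined")
    return QuantumIndices(
        hardness=eta,
        softness=1.0 / eta,
        electronegativity=chi,
        electrophilicity=chi ** 2 / (2.0 * eta),
    )


# ---------------------------------------------------------------------------
# topological machinery
# ---------------------------------------------------------------------------

def topological_distances(g: MolecularGraph, hydrogen_policy: str = "suppress"):
    """All-pairs shortest-path bond counts.

    Returns ``(D, kept)`` where ``kept`` lists the original atom indices
    retained under the hydrogen policy ("suppress" or "keep"); unreachable
    pairs are ``inf``.
    """
    if g.n_atoms == 0:
        raise SpecificationError("empty graph")
    if hydrogen_policy == "suppress":
        h, kept = g.heavy_atom_graph()
    elif hydrogen_policy == "keep":
        h, kept = g, list(range(g.n_atoms))
    else:
        raise SpecificationError(f"unknown hydrogen policy {hydrogen_policy!r}")
    if h.n_atoms == 0:
        raise DegenerateInputError("no heavy atoms left after H suppression")
    D = shortest_path(h.adjacency(), method="D", unweighted=True)
    return D, kept


def _lag_weights(g, props, prop, hydrogen_policy):
    if prop in PROPERTY_CODES:
        prop = PROPERTY_CODES[prop]
    if prop not in ("mass", "vdw_volume", "polarizability", "electronegativity"):
        raise SpecificationError(f"unsupported atomic property {prop!r}")
    D, kept = topological_distances(g, hydrogen_policy)
    elements = [g.atoms[i].element for i in kept]
    w = props.weights(elements, prop)
    return D, w


def broto_moreau_ats(g: MolecularGraph, props: AtomicPropertyTable = DEFAULT_PROPERTIES,
                     property: str = "mass", lag: int = 1,
                     hydrogen_policy: str = "suppress") -> float:
    """Broto-Moreau autocorrelation ATS: Σ_{d(i,j)=lag} w_i·w_j (unordered pairs)."""
    if lag < 1:
        raise SpecificationError("lag must be ≥ 1")
    D, w = _lag_weights(g, props, property, hydrogen_policy)
    n = len(w)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] == lag:
                total += w[i] * w[j]
    return total


def _lag_pairs(D, lag):
    """Ordered index pairs (i != j) at exact topological distance lag."""
    ii, jj = np.nonzero(D == lag)
    mask = ii != jj
    return ii[mask], jj[mask]


def moran_mats(g: MolecularGraph, props: AtomicPropertyTable = DEFAULT_PROPERTIES,
               property: str = "mass", lag: int = 1,
               hydrogen_policy: str = "suppress") -> float:
    """Moran autocorrelation MATS at the given lag (ordered-pair convention)."""
    D, w = _lag_weights(g, props, property, hydrogen_policy)
    n = len(w)
    if n < 2:
        raise DegenerateInputError("Moran autocorrelation needs ≥ 2 retained atoms")
    dev = w - w.mean()
    denom = float(dev @ dev) / n
    if denom == 0:
        raise DegenerateInputError("zero weight variance: Moran index undefined")
    ii, jj = _lag_pairs(D, lag)
    if len(ii) == 0:
        log.debug("MATS lag %d: no atom pair at this lag; defined as 0", lag)
        return 0.0
    num = float(np.sum(dev[ii] * dev[jj])) / len(ii)
    return num / denom


def geary_gats(g: MolecularGraph, props: AtomicPropertyTable = DEFAULT_PROPERTIES,
               property: str = "mass", lag: int = 1,
               hydrogen_policy: str = "suppress") -> float:
    """Geary autocorrelation GATS at the given lag (ordered-pair convention)."""
    D, w = _lag_weights(g, props, property, hydrogen_policy)
    n = len(w)
    if n < 2:
        raise DegenerateInputError("Geary autocorrelation needs ≥ 2 retained atoms")
    dev = w - w.mean()
    denom = float(dev @ dev) / (n - 1)
    if denom == 0:
        raise DegenerateInputError("zero weight variance: Geary index undefined")
    ii, jj = _lag_pairs(D, lag)
    if len(ii) == 0:
        log.debug("GATS lag %d: no atom pair at this lag; defined as 0", lag)
        return 0.0
    num = float(np.sum((w[ii] - w[jj]) ** 2)) / (2 * len(ii))
    return num / denom


def avg_connectivity_chi3(g: MolecularGraph) -> float:
    """Average 3rd-order connectivity index X3A on the H-suppressed graph.

    Mean over simple 3-bond paths i-j-k-l of (δi·δj·δk·δl)^(-1/2), where δ
    is the heavy-atom vertex degree.  Defined as 0 (logged) when the graph
    has no 3-bond path.
    """
    h, _ = g.heavy_atom_graph()
    n = h.n_atoms
    adj = [h.neighbors(i) for i in range(n)]
    deg = np.array([len(a) for a in adj], dtype=float)
    total, count = 0.0, 0
    # walk j-k edges as the middle bond; extend on both sides
    for j in range(n):
        for k in adj[j]:
            if k <= j:
                continue
            for i in adj[j]:
                if i == k:
                    continue
                for l in adj[k]:
                    if l == j or l == i:
                        continue
                    total += (deg[i] * deg[j] * deg[k] * deg[l]) ** -0.5
                    count += 1
    if count == 0:
        log.debug("X3A: no 3-bond path; defined as 0")
        return 0.0
    # fixing the middle-edge orientation visits each undirected path once
    return total / count


# ---------------------------------------------------------------------------
# geometric descriptors
# ---------------------------------------------------------------------------

def geometric_pair_sum(g: MolecularGraph, element_a: str, element_b: str) -> float:
    """Sum of Euclidean distances (Å) over unordered pairs of the two elements.

    With identical elements (e.g. G(O..O)) each unordered O,O pair counts
    once; 0 when fewer than one qualifying pair exists.
    """
    if not g.has_coordinates:
        raise SpecificationError("geometric descriptor needs 3D coordinates")
    coords = g.coordinates()
    idx_a = [i for i, a in enumerate(g.atoms) if a.element == element_a]
    idx_b = [i for i, a in enumerate(g.atoms) if a.element == element_b]
    total = 0.0
    if element_a == element_b:
        for i, j in itertools.combinations(idx_a, 2):
            total += float(np.linalg.norm(coords[i] - coords[j]))
    else:
        for i in idx_a:
            for j in idx_b:
                total += float(np.linalg.norm(coords[i] - coords[j]))
    return total


def asphericity(g: MolecularGraph) -> float:
    """Asphericity from the unweighted gyration tensor; 0 = spherical, 1 = linear."""
    if not g.has_coordinates:
        raise SpecificationError("asphericity needs 3D coordinates")
    if g.n_atoms < 2:
        raise SpecificationError("asphericity needs ≥ 2 atoms")
    coords = g.coordinates()
    centered = coords - coords.mean(axis=0)
    T = centered.T @ centered / len(coords)
    lam = np.sort(np.linalg.eigvalsh(T))[::-1]
    s = lam.sum()
    if s <= 0:
        raise DegenerateInputError("all atoms coincident: asphericity undefined")
    l1, l2, l3 = lam
    return float(((l1 - l2) ** 2 + (l2 - l3) ** 2 + (l1 - l3) ** 2) / (2 * s ** 2))


# ---------------------------------------------------------------------------
# fragment counts
# ---------------------------------------------------------------------------

def _is_carbonyl_carbon(g: MolecularGraph, idx: int) -> bool:
    for j in g.neighbors(idx):
        if g.atoms[j].element == "O" and (g.bond_order(idx, j) or 0) >= 2:
            return True
    return False


def fragment_counts(g: MolecularGraph) -> dict[str, int]:
    """Counts of nROR (aliphatic ethers), nPhX (aromatic C–halogen) and H-048.

    Rules:

    * nROR — oxygen bonded to exactly two sp3, non-aromatic, non-carbonyl
      carbons.
    * nPhX — halogen (F/Cl/Br/I) bonded to an aromatic carbon.
    * H-048 — hydrogen on a carbon of class C2(sp3), C1(sp2) or C0(sp),
      where the digit counts carbon neighbours; requires explicit hydrogens
      and populated hybridization labels.
    """
    carbons = [i for i, a in enumerate(g.atoms) if a.element == "C"]
    if any(g.atoms[i].hybridization is None for i in carbons):
        raise SpecificationError(
            "fragment counts need hybridization labels on every carbon")

    n_ror = 0
    for i, atom in enumerate(g.atoms):
        if atom.element != "O" or atom.aromatic:
            continue
        heavy = [j for j in g.neighbors(i) if g.atoms[j].element != "H"]
        if len(heavy) != 2:
            continue
        ok = True
        for j in heavy:
            nb = g.atoms[j]
            if (nb.element != "C" or nb.aromatic or nb.hybridization != "sp3"
                    or _is_carbonyl_carbon(g, j)):
                ok = False
        n_ror += ok

    n_phx = 0
    for i, atom in enumerate(g.atoms):
        if atom.element in HALOGENS:
            n_phx += any(g.atoms[j].element == "C" and g.atoms[j].aromatic
                         for j in g.neighbors(i))

    h048 = 0
    for i, atom in enumerate(g.atoms):
        if atom.element != "H":
            continue
        for j in g.neighbors(i):
            nb = g.atoms[j]
            if nb.element != "C":
                continue
            n_c = sum(g.atoms[k].element == "C" for k in g.neighbors(j))
            if ((nb.hybridization == "sp3" and n_c == 2)
                    or (nb.hybridization == "sp2" and n_c == 1)
                    or (nb.hybridization == "sp" and n_c == 0)):
                h048 += 1
    return {"nROR": n_ror, "nPhX": n_phx, "H-048": h048}


# ---------------------------------------------------------------------------
# descriptor-table assembly
# ---------------------------------------------------------------------------

_AUTOCORR_RE = re.compile(r"^(ATS|MATS|GATS)(\d+)([mvpe])$")
_GEOM_RE = re.compile(r"^G\((\w+)\.\.(\w+)\)$")

_ELECTRONIC_COLUMNS = {"HOMO": "homo", "LUMO": "lumo",
                       "DMX": "dmx", "DMY": "dmy", "DMZ": "dmz",
                       "DipY": "dmy"}
_QUANTUM_FIELDS = {"eta": "hardness", "S": "softness",
                   "chi": "electronegativity", "omega": "electrophilicity"}


def _native_value(name: str, g: MolecularGraph, es: ElectronicSummary | None,
                  props: AtomicPropertyTable, convention: str):
    """Compute one named descriptor, or return None if not natively known."""
    m = _AUTOCORR_RE.match(name)
    if m:
        family, lag, code = m.group(1), int(m.group(2)), m.group(3)
        fn = {"ATS": broto_moreau_ats, "MATS": moran_mats, "GATS": geary_gats}[family]
        return fn(g, props, PROPERTY_CODES[code], lag)
    m = _GEOM_RE.match(name)
    if m:
        return geometric_pair_sum(g, m.group(1), m.group(2))
    if name == "X3A":
        return avg_connectivity_chi3(g)
    if name == "ASP":
        return asphericity(g)
    if name in ("nROR", "nPhX", "H-048"):
        return float(fragment_counts(g)[name])
    if name in _ELECTRONIC_COLUMNS:
        if es is None:
            raise MissingDescriptorError([name])
        return getattr(es, _ELECTRONIC_COLUMNS[name])
    if name in _QUANTUM_FIELDS:
        if es is None:
            raise MissingDescriptorError([name])
        return getattr(quantum_indices(es, convention), _QUANTUM_FIELDS[name])
    return None


def is_native(name: str) -> bool:
    return bool(_AUTOCORR_RE.match(name) or _GEOM_RE.match(name)
                or name in ("X3A", "ASP", "nROR", "nPhX", "H-048")
                or name in _ELECTRONIC_COLUMNS or name in _QUANTUM_FIELDS)


def compute_descriptor_table(molecules: dict[str, MolecularGraph],
                             electronic: dict[str, ElectronicSummary] | None = None,
                             requested: list[str] | None = None,
                             external: pd.DataFrame | None = None,
                             props: AtomicPropertyTable = DEFAULT_PROPERTIES,
                             convention: str = "paper"):
    """Assemble a DescriptorTable for the requested descriptor names.

    Each requested name is either computed natively or copied from
    ``external`` (a compound × descriptor DataFrame, e.g. software output
    the package does not reimplement).  Returns ``(table, provenance)``
    where provenance maps column → "native" | "external".  Every name that
    resolves nowhere is reported in one aggregated error.
    """
    if requested is None:
        raise SpecificationError("requested descriptor list is required")
    ids = list(molecules)
    unresolved = [n for n in requested
                  if not is_native(n)
                  and (external is None or n not in external.columns)]
    if unresolved:
        raise MissingDescriptorError(unresolved)

    provenance: dict[str, str] = {}
    columns: dict[str, list[float]] = {n: [] for n in requested}
    for name in requested:
        if is_native(name):
            provenance[name] = "native"
            for cid in ids:
                es = electronic.get(cid) if electronic else None
                columns[name].append(_native_value(name, molecules[cid], es,
                                                   props, convention))
        else:
            provenance[name] = "external"
            columns[name] = [float(external.loc[cid, name]) for cid in ids]

    table = DescriptorTable(pd.DataFrame(columns, index=ids))
    return table, provenance


def electronic_from_frame(df: pd.DataFrame) -> dict[str, ElectronicSummary]:
    """Build per-compound electronic summaries from a table.

    Expects columns HOMO and LUMO, plus optional DMX/DMY/DMZ; the index is
    the compound identifier.
    """
    out = {}
    for cid, row in df.iterrows():
        out[str(cid)] = ElectronicSummary(
            homo=float(row["HOMO"]), lumo=float(row["LUMO"]),
            dmx=float(row.get("DMX", 0.0)), dmy=float(row.get("DMY", 0.0)),
            dmz=float(row.get("DMZ", 0.0)))
    return out
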