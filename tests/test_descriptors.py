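"""Descriptor calculators against hand computations and brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsarlab import (DEFAULT_PROPERTIES, ElectronicSummary, MolecularGraph,
                     asphericity, avg_connectivity_chi3, broto_moreau_ats,
                     compute_descriptor_table, fragment_counts, geary_gats,
                     geometric_pair_sum, moran_mats, quantum_indices,
                     topological_distances, generate_toy_molecule)
from qsarlab.descriptors import electronic_from_frame
from qsarlab.exceptions import (DegenerateInputError, MissingDescriptorError,
                                SpecificationError)
from qsarlab.molgraph import Atom

from conftest import random_molecular_graph

# ---------------------------------------------------------------------------
# quantum indices
# ---------------------------------------------------------------------------


def test_quantum_indices_printed_formulas():
    qi = quantum_indices(ElectronicSummary(homo=-9, lumo=-1))
    assert qi.hardness == pytest.approx(-5.0)
    assert qi.electronegativity == pytest.approx(4.0)
    assert qi.softness == pytest.approx(-0.2)
    assert qi.electrophilicity == pytest.approx(-1.6)


def test_quantum_indices_standard_convention():
    qi = quantum_indices(ElectronicSummary(homo=-9, lumo=-1),
                         convention="standard")
    assert qi.hardness == pytest.approx(4.0)       # 0.5 (LUMO−HOMO)
    assert qi.electronegativity == pytest.approx(5.0)


@pytest.mark.parametrize("homo,lumo", [(0, 0), (-3, 3), (-7.5, 7.5)])
def test_zero_hardness_rejected(homo, lumo):
    with pytest.raises(DegenerateInputError, match="S.*ω|softness"):
        quantum_indices(ElectronicSummary(homo=homo, lumo=lumo))


@given(homo=st.floats(-15, 5), lumo=st.floats(-15, 5))
@settings(max_examples=50, derandomize=True)
def test_quantum_index_identities(homo, lumo):
    if homo + lumo == 0:
        return
    qi = quantum_indices(ElectronicSummary(homo=homo, lumo=lumo))
    assert qi.softness * qi.hardness == pytest.approx(1.0)
    assert qi.electrophilicity == pytest.approx(
        qi.electronegativity ** 2 / (2 * qi.hardness))


# ---------------------------------------------------------------------------
# topological distances
# ---------------------------------------------------------------------------


def test_path_distance():
    g = generate_toy_molecule("path3")
    D, kept = topological_distances(g)
    assert D[0, 2] == 2 and kept == [0, 1, 2]


def test_disconnected_pair_is_infinite():
    g = MolecularGraph([Atom("C"), Atom("C"), Atom("C")], [(0, 1, 1.0)])
    D, _ = topological_distances(g)
    assert np.isinf(D[0, 2])
    # and contributes to no lag sum
    assert broto_moreau_ats(g, DEFAULT_PROPERTIES, "mass", 2) == 0.0


def test_distances_match_bfs_oracle(rng):
    for _ in range(30):
        g = random_molecular_graph(rng)
        D, _ = topological_distances(g, hydrogen_policy="keep")
        lengths = dict(nx.all_pairs_shortest_path_length(g.to_networkx()))
        for i in range(g.n_atoms):
            for j in range(g.n_atoms):
                expected = lengths[i].get(j, np.inf)
                assert D[i, j] == expected


# ---------------------------------------------------------------------------
# 2D autocorrelations: hand values and brute-force oracles
# ---------------------------------------------------------------------------


def _oracle_autocorr(g, props, prop, lag):
    """Brute-force ATS/MATS/GATS via explicit double loops over BFS distances."""
    h, kept = g.heavy_atom_graph()
    lengths = dict(nx.all_pairs_shortest_path_length(h.to_networkx()))
    w = props.weights([a.element for a in h.atoms], prop)
    n = len(w)
    wbar = w.mean()
    ats = sum(w[i] * w[j] for i in range(n) for j in range(i + 1, n)
              if lengths[i].get(j) == lag)
    ordered = [(i, j) for i in range(n) for j in range(n)
               if i != j and lengths[i].get(j) == lag]
    var_n = sum((x - wbar) ** 2 for x in w) / n
    var_n1 = sum((x - wbar) ** 2 for x in w) / (n - 1)
    if ordered and var_n > 0:
        mats = (sum((w[i] - wbar) * (w[j] - wbar) for i, j in ordered)
                / len(ordered)) / var_n
        gats = (sum((w[i] - w[j]) ** 2 for i, j in ordered)
                / (2 * len(ordered))) / var_n1
    else:
        mats = gats = 0.0
    return ats, mats, gats


def test_weighted_path_hand_values(unit_props):
    g = generate_toy_molecule("path3_w123")
    assert broto_moreau_ats(g, unit_props, "mass", 1) == pytest.approx(8.0)
    assert moran_mats(g, unit_props, "mass", 1) == pytest.approx(0.0)
    assert geary_gats(g, unit_props, "mass", 1) == pytest.approx(0.5)


def test_lag_beyond_diameter_is_zero(unit_props):
    g = generate_toy_molecule("path3_w123")
    assert broto_moreau_ats(g, unit_props, "mass", 9) == 0.0
    assert moran_mats(g, unit_props, "mass", 9) == 0.0
    assert geary_gats(g, unit_props, "mass", 9) == 0.0


def test_constant_weights_rejected():
    g = generate_toy_molecule("path4")  # all carbon → zero weight variance
    with pytest.raises(DegenerateInputError):
        moran_mats(g, DEFAULT_PROPERTIES, "mass", 1)
    with pytest.raises(DegenerateInputError):
        geary_gats(g, DEFAULT_PROPERTIES, "mass", 1)


def test_autocorrelations_match_bruteforce_oracle(rng):
    """≥100 random graphs × several lags, agreement to 1e-12."""
    checked = 0
    for _ in range(110):
        g = random_molecular_graph(rng)
        if len(set(g.elements)) < 2:
            continue
        for lag in (1, 2, 3):
            ats_o, mats_o, gats_o = _oracle_autocorr(
                g, DEFAULT_PROPERTIES, "polarizability", lag)
            assert broto_moreau_ats(g, DEFAULT_PROPERTIES, "polarizability",
                                    lag) == pytest.approx(ats_o, abs=1e-12)
            assert moran_mats(g, DEFAULT_PROPERTIES, "polarizability",
                              lag) == pytest.approx(mats_o, abs=1e-12)
            assert geary_gats(g, DEFAULT_PROPERTIES, "polarizability",
                              lag) == pytest.approx(gats_o, abs=1e-12)
        checked += 1
    assert checked >= 100


def test_autocorrelations_invariant_to_atom_permutation(rng):
    for _ in range(20):
        g = random_molecular_graph(rng)
        if len(set(g.elements)) < 2:
            continue
        perm = rng.permutation(g.n_atoms).tolist()
        gp = g.permuted(perm)
        for fn in (broto_moreau_ats, moran_mats, geary_gats):
            assert fn(g, DEFAULT_PROPERTIES, "mass", 2) == pytest.approx(
                fn(gp, DEFAULT_PROPERTIES, "mass", 2), abs=1e-12)


def test_duplicated_graph_locality(unit_props):
    """Two disconnected copies: Moran is exactly local (its variance norm
    uses 1/A); Geary's 1/(A−1) norm shifts slightly, so it is checked
    against the brute-force oracle on the doubled graph instead."""
    g = generate_toy_molecule("path3_w123")
    atoms = [Atom(a.element, hybridization=a.hybridization)
             for a in g.atoms for _ in (0,)] * 2
    bonds = list(g.bonds) + [(i + 3, j + 3, o) for i, j, o in g.bonds]
    doubled = MolecularGraph(atoms, bonds)
    assert moran_mats(doubled, unit_props, "mass", 1) == pytest.approx(
        moran_mats(g, unit_props, "mass", 1), abs=1e-12)
    _, _, gats_o = _oracle_autocorr(doubled, unit_props, "mass", 1)
    assert geary_gats(doubled, unit_props, "mass", 1) == pytest.approx(
        gats_o, abs=1e-12)


# ---------------------------------------------------------------------------
# geometric descriptors
# ---------------------------------------------------------------------------


def test_geometric_pair_sum_cases():
    assert geometric_pair_sum(generate_toy_molecule("dioxygen_1p5A"),
                              "O", "O") == pytest.approx(1.5)
    assert geometric_pair_sum(generate_toy_molecule("o3_right_triangle"),
                              "O", "O") == pytest.approx(12.0)
    # zero or one oxygen → empty sum
    g = MolecularGraph([Atom("C", xyz=(0, 0, 0)), Atom("O", xyz=(1, 0, 0))],
                       [(0, 1, 1.0)])
    assert geometric_pair_sum(g, "O", "O") == 0.0
    with pytest.raises(SpecificationError):
        geometric_pair_sum(generate_toy_molecule("path3"), "O", "O")


def test_geometric_pair_sum_rigid_motion_invariant(rng):
    g = random_molecular_graph(rng, with_coords=True)
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta), 0],
                  [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
    moved = g.rotated(R).translated([3.2, -1.1, 0.5])
    for a, b in [("C", "C"), ("C", "O"), ("O", "O")]:
        assert geometric_pair_sum(g, a, b) == pytest.approx(
            geometric_pair_sum(moved, a, b), abs=1e-9)


def test_asphericity_limits():
    line = MolecularGraph([Atom("C", xyz=(float(k), 0, 0)) for k in range(5)])
    assert asphericity(line) == pytest.approx(1.0)
    # regular tetrahedron: all gyration eigenvalues equal
    t = 1 / np.sqrt(3)
    tet = MolecularGraph([Atom("C", xyz=p) for p in
                          [(t, t, t), (t, -t, -t), (-t, t, -t), (-t, -t, t)]])
    assert asphericity(tet) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(DegenerateInputError):
        asphericity(MolecularGraph([Atom("C", xyz=(1, 1, 1))] * 3))


def test_asphericity_matches_eigen_oracle(rng):
    for _ in range(20):
        g = random_molecular_graph(rng, with_coords=True)
        coords = g.coordinates() - g.coordinates().mean(axis=0)
        lam = np.sort(np.linalg.eigvalsh(coords.T @ coords / len(coords)))[::-1]
        expect = (((lam[0] - lam[1]) ** 2 + (lam[1] - lam[2]) ** 2
                   + (lam[0] - lam[2]) ** 2) / (2 * lam.sum() ** 2))
        assert asphericity(g) == pytest.approx(expect, abs=1e-10)


# ---------------------------------------------------------------------------
# connectivity index
# ---------------------------------------------------------------------------


def _oracle_chi3(g):
    """Exhaustive simple-path enumeration on the H-suppressed graph."""
    h, _ = g.heavy_atom_graph()
    G = h.to_networkx()
    deg = dict(G.degree)
    paths = set()
    for s, t in itertools.combinations(G.nodes, 2):
        for path in nx.all_simple_paths(G, s, t, cutoff=3):
            if len(path) == 4:
                paths.add(tuple(path) if path[0] < path[-1]
                          else tuple(reversed(path)))
    if not paths:
        return 0.0
    vals = [np.prod([deg[v] for v in p]) ** -0.5 for p in paths]
    return float(np.mean(vals))


def test_chi3_hand_value_and_empty_case():
    assert avg_connectivity_chi3(generate_toy_molecule("path4")) == \
        pytest.approx(0.5)
    assert avg_connectivity_chi3(generate_toy_molecule("path3")) == 0.0


def test_chi3_matches_path_enumeration_oracle(rng):
    for _ in range(40):
        g = random_molecular_graph(rng, n_max=9)
        assert avg_connectivity_chi3(g) == pytest.approx(_oracle_chi3(g),
                                                         abs=1e-12)


# ---------------------------------------------------------------------------
# fragment counts
# ---------------------------------------------------------------------------


def test_fragment_count_rules():
    assert fragment_counts(generate_toy_molecule("linear_ether"))["nROR"] == 1
    assert fragment_counts(generate_toy_molecule("chlorobenzene"))["nPhX"] == 1
    assert fragment_counts(generate_toy_molecule("ethylene"))["H-048"] == 4
    # ester oxygen flanked by a carbonyl carbon is NOT an aliphatic ether
    acet = generate_toy_molecule("acetanilide")
    assert fragment_counts(acet)["nROR"] == 0


def test_fragment_counts_need_annotations():
    g = MolecularGraph([Atom("C"), Atom("C")], [(0, 1, 1.0)])
    with pytest.raises(SpecificationError):
        fragment_counts(g)


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------


def test_table_assembly_passthrough_and_composition(unit_props):
    import pandas as pd

    mols = {"a": generate_toy_molecule("path3_w123"),
            "b": generate_toy_molecule("path3_w123")}
    elec = electronic_from_frame(pd.DataFrame(
        {"HOMO": [-9.0, -8.0], "LUMO": [-1.0, -2.0], "DMY": [0.5, -0.2]},
        index=["a", "b"]))
    table, prov = compute_descriptor_table(
        mols, elec, ["DipY", "MATS1m"], props=unit_props)
    np.testing.assert_allclose(table.X["DipY"], [0.5, -0.2])
    assert table.X.loc["a", "MATS1m"] == pytest.approx(
        moran_mats(mols["a"], unit_props, "mass", 1))
    assert prov == {"DipY": "native", "MATS1m": "native"}


def test_table_assembly_external_and_errors():
    import pandas as pd

    mols = {"a": generate_toy_molecule("path3_w123")}
    external = pd.DataFrame({"Ss": [12.5]}, index=["a"])
    table, prov = compute_descriptor_table(mols, None, ["Ss"],
                                           external=external)
    assert table.X.loc["a", "Ss"] == 12.5 and prov["Ss"] == "external"
    with pytest.raises(MissingDescriptorError) as err:
        compute_descriptor_table(mols, None, ["Ss", "qpos"])
    assert "Ss" in str(err.value) and "qpos" in str(err.value)
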