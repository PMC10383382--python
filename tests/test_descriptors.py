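import itertools
import math

import networkx as nx
import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import QED as RDQED

from pfasbind.descriptors import (
    MODELED_DESCRIPTORS,
    avg_connectivity_index,
    augmented_edge_adjacency_eigenvalue,
    descriptor_table,
    eccentric_deviation,
    edge_adjacency_matrix,
    geary_autocorrelation,
    mcgowan_volume,
    moran_autocorrelation,
    packing_density_index,
    qed,
    vsa_total,
)
from pfasbind.graph import MolecularGraph, build_graph

from conftest import random_molecular_graph


# ---------------------------------------------------------------------------
# graph building


@pytest.mark.parametrize(
    "smiles, n_atoms, n_bonds, degrees",
    [
        ("CC", 2, 1, [1, 1]),
        ("C1CCCCC1", 6, 6, [2] * 6),
        ("O=C(O)C(F)(F)F", 7, 6, None),
    ],
)
def test_build_graph_basic_topology(smiles, n_atoms, n_bonds, degrees):
    g = build_graph(smiles)
    assert g.n_atoms == n_atoms
    assert g.n_bonds == n_bonds
    if degrees is not None:
        assert g.degrees == degrees
    else:
        assert max(g.degrees) == 4  # central carbon of trifluoroacetic acid


def test_build_graph_rejects_bad_smiles():
    with pytest.raises(ValueError, match="not_a_smiles"):
        build_graph("not_a_smiles((")


def test_graph_degree_invariant_enforced():
    from pfasbind.graph import Atom

    atoms = [Atom("C", 12.0, 20.0, 2), Atom("C", 12.0, 20.0, 1)]
    with pytest.raises(ValueError, match="degree"):
        MolecularGraph(atoms, [(0, 1, 1.0)])


# ---------------------------------------------------------------------------
# connectivity index


def _oracle_connectivity(g: MolecularGraph, order: int) -> float:
    """Exhaustive simple-path enumeration through networkx."""
    nxg = g.to_networkx()
    deg = g.degrees
    total, count = 0.0, 0
    for i, j in itertools.combinations(range(g.n_atoms), 2):
        for path in nx.all_simple_paths(nxg, i, j, cutoff=order):
            if len(path) == order + 1:
                total += 1.0 / math.sqrt(math.prod(deg[v] for v in path))
                count += 1
    return total / count if count else 0.0


@pytest.mark.parametrize(
    "smiles, order, expected",
    [
        ("CCCCC", 4, 1.0 / math.sqrt(8)),  # single path, degrees 1,2,2,2,1
        ("CC", 1, 1.0),
        ("CCCC", 4, 0.0),  # no 5-vertex path
    ],
)
def test_avg_connectivity_known_values(smiles, order, expected):
    assert avg_connectivity_index(smiles, order) == pytest.approx(expected, abs=1e-12)


def test_avg_connectivity_matches_path_enumeration_oracle():
    rng = np.random.default_rng(42)
    for _ in range(60):
        g = random_molecular_graph(rng, max_atoms=10)
        for order in (2, 3, 4):
            assert avg_connectivity_index(g, order) == pytest.approx(
                _oracle_connectivity(g, order), abs=1e-12
            )


# ---------------------------------------------------------------------------
# eccentric deviation


def test_decc_known_values():
    assert eccentric_deviation("C1CCCCC1") == 0.0  # all eccentricities equal
    assert eccentric_deviation("C") == 0.0
    # pentane eccentricities 4,3,2,3,4; mean 3.2
    assert eccentric_deviation("CCCCC") == pytest.approx(0.64, abs=1e-12)


def test_decc_matches_scipy_shortest_path_oracle():
    from scipy.sparse.csgraph import shortest_path

    rng = np.random.default_rng(7)
    for _ in range(60):
        g = random_molecular_graph(rng, max_atoms=12)
        A = np.zeros((g.n_atoms, g.n_atoms))
        for i, j, _ in g.bonds:
            A[i, j] = A[j, i] = 1
        D = shortest_path(A, unweighted=True)
        ecc = D.max(axis=1)
        expected = float(np.mean(np.abs(ecc - ecc.mean())))
        assert eccentric_deviation(g) == pytest.approx(expected, abs=1e-12)


def test_decc_raises_on_disconnected_graph():
    g = MolecularGraph.from_adjacency([(0, 1)], 4)
    with pytest.raises(ValueError, match="disconnected"):
        eccentric_deviation(g)


# ---------------------------------------------------------------------------
# edge adjacency eigenvalues


def test_edge_eigenvalue_known_values():
    assert augmented_edge_adjacency_eigenvalue("CC", 1) == pytest.approx(1.0)
    # propane: two order-1 bonds sharing an atom -> [[1,1],[1,1]], eigs (2, 0)
    assert augmented_edge_adjacency_eigenvalue("CCC", 1) == pytest.approx(2.0)
    assert augmented_edge_adjacency_eigenvalue("CCC", 2) == pytest.approx(0.0)


def test_edge_eigenvalue_padding_below_k_bonds():
    # pentane has 4 bonds < 12 -> deterministic 0
    assert augmented_edge_adjacency_eigenvalue("CCCCC", 12) == 0.0


def test_eigenvalue_trace_equals_bond_order_sum(pfas24):
    for rec in pfas24:
        g = build_graph(rec.smiles)
        E = edge_adjacency_matrix(g)
        assert np.sum(np.linalg.eigvalsh(E)) == pytest.approx(
            sum(order for _, _, order in g.bonds), abs=1e-8
        )


def test_aromatic_bond_order_on_diagonal():
    E = edge_adjacency_matrix(build_graph("c1ccccc1"))
    assert np.allclose(np.diag(E), 1.5)


# ---------------------------------------------------------------------------
# autocorrelations


def _oracle_autocorr(g, lag, w, kind):
    """Brute-force double sum over ordered atom pairs."""
    nxg = g.to_networkx()
    D = dict(nx.all_pairs_shortest_path_length(nxg))
    n = g.n_atoms
    wbar = np.mean(w)
    pairs = [(i, j) for i in range(n) for j in range(n)
             if i != j and D[i].get(j) == lag]
    if not pairs:
        return 0.0
    if kind == "moran":
        denom = sum((wi - wbar) ** 2 for wi in w) / n
        if denom == 0:
            return 0.0
        num = sum((w[i] - wbar) * (w[j] - wbar) for i, j in pairs) / len(pairs)
        return num / denom
    denom = sum((wi - wbar) ** 2 for wi in w) / (n - 1)
    if denom == 0:
        return 0.0
    num = sum((w[i] - w[j]) ** 2 for i, j in pairs) / (2 * len(pairs))
    return num / denom


def test_autocorrelation_zero_conventions():
    # lag beyond diameter
    assert moran_autocorrelation("CCC", 5, "mass") == 0.0
    assert geary_autocorrelation("CCC", 5, "vdw_volume") == 0.0
    # homonuclear chain: zero weight variance
    assert moran_autocorrelation("CCCCC", 2, "mass") == 0.0
    assert geary_autocorrelation("CCCCC", 1, "mass") == 0.0


def test_three_atom_chain_hand_computed():
    g = MolecularGraph.from_adjacency([(0, 1), (1, 2)], 3, masses=[1.0, 2.0, 1.0])
    w = np.array([1.0, 2.0, 1.0]) / 12.011  # carbon-scaled
    c = w - w.mean()
    # lag 2: ordered pairs (0,2),(2,0)
    moran_expected = (c[0] * c[2]) / (np.sum(c**2) / 3)
    assert moran_autocorrelation(g, 2, "mass") == pytest.approx(moran_expected, abs=1e-12)
    # lag 1: ordered pairs (0,1),(1,0),(1,2),(2,1)
    num = (2 * (w[0] - w[1]) ** 2 + 2 * (w[1] - w[2]) ** 2) / (2 * 4)
    geary_expected = num / (np.sum(c**2) / 2)
    assert geary_autocorrelation(g, 1, "mass") == pytest.approx(geary_expected, abs=1e-12)


def test_autocorrelations_match_double_sum_oracle():
    rng = np.random.default_rng(11)
    for _ in range(100):
        g = random_molecular_graph(rng, max_atoms=10)
        w = g.weights("mass")
        for lag in (1, 2, 3):
            assert moran_autocorrelation(g, lag, "mass") == pytest.approx(
                _oracle_autocorr(g, lag, w, "moran"), abs=1e-10
            )
            assert geary_autocorrelation(g, lag, "mass") == pytest.approx(
                _oracle_autocorr(g, lag, w, "geary"), abs=1e-10
            )


# ---------------------------------------------------------------------------
# volumes, surfaces, PDI


def test_mcgowan_volume_increment_oracle():
    # methane: (16.35 + 4*8.71 - 4*6.56)/100
    assert mcgowan_volume("C") == pytest.approx(0.2495, abs=1e-10)
    # ethane: 2 C + 6 H, 7 bonds total
    expected = (2 * 16.35 + 6 * 8.71 - 7 * 6.56) / 100
    assert mcgowan_volume("CC") == pytest.approx(expected, abs=1e-10)


def test_mcgowan_unknown_element_raises():
    g = build_graph("[U]")
    with pytest.raises(ValueError, match="U"):
        mcgowan_volume(g)


def test_vsa_total_positive_and_monotone():
    sa_ethane = vsa_total("CC")
    sa_propane = vsa_total("CCC")
    assert sa_ethane > 0
    assert sa_propane > sa_ethane


def test_pdi_is_ratio_and_positive_for_all_fixture_compounds(pfas24, pfas24_descriptors):
    for rec in pfas24:
        g = build_graph(rec.smiles)
        assert packing_density_index(g) == pytest.approx(
            mcgowan_volume(g) / vsa_total(g), rel=1e-12
        )
    assert (pfas24_descriptors["PDI"] > 0).all()


# ---------------------------------------------------------------------------
# QED


def test_qed_matches_rdkit_reference_parameterization(pfas24):
    for rec in pfas24:
        mol = Chem.MolFromSmiles(rec.smiles)
        assert qed(rec.smiles, weights="unit") == pytest.approx(
            RDQED.weights_none(mol), abs=1e-10
        )
        assert qed(rec.smiles, weights="mean") == pytest.approx(
            RDQED.weights_mean(mol), abs=1e-10
        )


def test_qed_geometric_mean_identities():
    from pfasbind.descriptors import (
        QED_ADS_PARAMS,
        QED_PROPERTY_ORDER,
        ads_desirability,
        qed_properties,
    )

    props = qed_properties("CCO")
    d = [ads_desirability(props[k], QED_ADS_PARAMS[k]) for k in QED_PROPERTY_ORDER]
    # unit weights reduce to the plain geometric mean of desirabilities
    assert qed("CCO", weights="unit") == pytest.approx(
        math.exp(np.mean(np.log(d))), abs=1e-12
    )
    # scaling all weights by a constant leaves the weighted mean unchanged
    assert qed("CCO", weights=[2.0] * 8) == pytest.approx(
        qed("CCO", weights="unit"), abs=1e-12
    )


def test_qed_in_unit_interval_for_fixture(pfas24_descriptors):
    assert ((pfas24_descriptors["QED"] > 0) & (pfas24_descriptors["QED"] <= 1)).all()


# ---------------------------------------------------------------------------
# batch table and invariance


def test_descriptor_table_shape_and_determinism(pfas24):
    df = descriptor_table(pfas24, MODELED_DESCRIPTORS)
    assert df.shape == (24, 7)
    assert not df.isna().any().any()
    df2 = descriptor_table(pfas24, MODELED_DESCRIPTORS)
    assert (df == df2).all().all()


def test_descriptor_table_permutation_and_duplicates(pfas24):
    pairs = [(r.smiles, r.id) for r in pfas24][:5]
    fwd = descriptor_table(pairs)
    rev = descriptor_table(pairs[::-1])
    assert (fwd.loc[rev.index[::-1]].to_numpy() == fwd.to_numpy()).all()
    dup = descriptor_table([(pairs[0][0], "a"), (pairs[0][0], "b")])
    assert (dup.loc["a"].to_numpy() == dup.loc["b"].to_numpy()).all()


def test_descriptor_table_collects_failures_without_aborting():
    df = descriptor_table([("CC", "ok"), ("[U]", "bad")], names=("Vx",))
    assert df.attrs["failures"].keys() == {"bad"}
    assert not np.isnan(df.loc["ok", "Vx"])
    assert np.isnan(df.loc["bad", "Vx"])


def test_unknown_descriptor_name_rejected(pfas24):
    with pytest.raises(ValueError, match="nonsense"):
        descriptor_table(pfas24, names=("nonsense",))


def test_descriptors_invariant_under_atom_reindexing():
    from rdkit import Chem as _C

    rng = np.random.default_rng(3)
    smiles = "OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F"  # PFOA
    mol = _C.MolFromSmiles(smiles)
    base = [compute for compute in _all_modeled(smiles)]
    for _ in range(5):
        perm = rng.permutation(mol.GetNumAtoms()).tolist()
        renum = _C.RenumberAtoms(mol, [int(x) for x in perm])
        alt = _C.MolToSmiles(renum, canonical=False)
        assert _all_modeled(alt) == pytest.approx(base, abs=1e-9)


def _all_modeled(smiles):
    from pfasbind.descriptors import compute_descriptor

    return [compute_descriptor(smiles, n) for n in MODELED_DESCRIPTORS]
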