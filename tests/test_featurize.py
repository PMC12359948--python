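"""Graph featurisation: schemas, feature values, serialisation."""

import numpy as np
import pytest
from rdkit import Chem

from molgnn.conformers import conformer_pipeline
from molgnn.featurize import (
    ATOMIC_NUMBERS,
    FeatureSchema,
    GraphDataset,
    build_graph,
    compute_gasteiger_charges,
)

BASIC = FeatureSchema("basic")
CUSTOM = FeatureSchema("custom")


def featurise(smiles, mode, label=0, seed=4):
    mol = Chem.MolFromSmiles(smiles)
    conf = conformer_pipeline(mol, seed=seed) if mode == "custom" else None
    return build_graph(mol, label, FeatureSchema(mode), conformer=conf, graph_id=smiles), mol


def feature_slice(schema, name):
    """Column slice of one named feature in the node matrix."""
    sizes = {
        "atomic_number": len(ATOMIC_NUMBERS),
        "degree": 1,
        "formal_charge": 1,
        "hybridization": 6,
        "aromaticity": 1,
        "num_hydrogens": 1,
        "in_ring": 1,
        "chirality": 4,
        "radical_electrons": 1,
        "gasteiger_charge": 1,
        "total_valence": 1,
        "explicit_valence": 1,
    }
    start = 0
    for feat in schema.node_features:
        if feat == name:
            return slice(start, start + sizes[feat])
        start += sizes[feat]
    raise KeyError(name)


def test_schema_dimensions():
    assert BASIC.d_node == 9 and BASIC.d_edge == 4
    assert CUSTOM.d_node == 28 and CUSTOM.d_edge == 6
    assert CUSTOM.d_node > BASIC.d_node and CUSTOM.d_edge > BASIC.d_edge


def test_benzene_node_features():
    g, _ = featurise("c1ccccc1", "custom")
    arom = g.node_matrix[:, feature_slice(CUSTOM, "aromaticity")]
    ring = g.node_matrix[:, feature_slice(CUSTOM, "in_ring")]
    hyb = g.node_matrix[:, feature_slice(CUSTOM, "hybridization")]
    nh = g.node_matrix[:, feature_slice(CUSTOM, "num_hydrogens")]
    assert np.all(arom == 1) and np.all(ring == 1)
    assert np.all(hyb[:, 1] == 1)  # SP2
    assert np.all(nh == 1)


def test_methane_node_features():
    g, _ = featurise("C", "custom")
    assert g.n_nodes == 1 and g.n_arcs == 0
    assert g.node_matrix[0, feature_slice(CUSTOM, "degree")] == 0
    assert g.node_matrix[0, feature_slice(CUSTOM, "num_hydrogens")] == 4
    assert g.node_matrix[0, feature_slice(CUSTOM, "formal_charge")] == 0
    assert g.node_matrix[0, feature_slice(CUSTOM, "total_valence")] == 4


def test_gasteiger_matches_toolkit():
    mol = Chem.MolFromSmiles("CC(=O)Oc1ccccc1C(=O)O")
    from rdkit.Chem import AllChem

    oracle = Chem.MolFromSmiles("CC(=O)Oc1ccccc1C(=O)O")
    AllChem.ComputeGasteigerCharges(oracle)
    expect = np.array([a.GetDoubleProp("_GasteigerCharge") for a in oracle.GetAtoms()])
    assert np.abs(compute_gasteiger_charges(mol) - expect).max() < 1e-6
    g, _ = featurise("CC(=O)Oc1ccccc1C(=O)O", "custom")
    got = g.node_matrix[:, feature_slice(CUSTOM, "gasteiger_charge")].ravel()
    assert np.abs(got - expect).max() < 1e-6


def test_edge_features_benzene_and_ethane():
    g, _ = featurise("c1ccccc1", "custom")
    assert g.n_nodes == 6 and g.n_arcs == 12
    # aromatic type one-hot index 3, ring flag set, plausible length
    assert np.all(g.edge_matrix[:, 3] == 1)
    assert np.all(g.edge_matrix[:, 4] == 1)
    assert np.all((g.edge_matrix[:, 5] > 1.35) & (g.edge_matrix[:, 5] < 1.45))
    e, _ = featurise("CC", "basic")
    assert e.edge_matrix.shape == (2, 4)
    assert np.all(e.edge_matrix[:, 0] == 1)  # single bond only


def test_graph_shapes_and_arc_reversal(toy_conformers):
    for name, mol, res in toy_conformers:
        for schema in (BASIC, CUSTOM):
            g = build_graph(mol, 1, schema, conformer=res, graph_id=name)
            assert g.node_matrix.shape == (g.n_nodes, schema.d_node)
            assert g.edge_matrix.shape == (g.n_arcs, schema.d_edge)
            assert g.n_nodes >= 1
            arcs = {tuple(a) for a in g.arcs}
            assert all((j, i) in arcs for i, j in arcs)  # closed under reversal
            assert all(i != j for i, j in arcs)  # no self-arcs
            # edge feature rows equal for an arc and its reverse
            row_of = {tuple(a): r for a, r in zip(g.arcs, g.edge_matrix)}
            for (i, j), r in row_of.items():
                assert np.array_equal(r, row_of[(j, i)])


def test_bond_length_equals_conformer_measurement():
    mol = Chem.MolFromSmiles("CCO")
    res = conformer_pipeline(mol, seed=9)
    g = build_graph(mol, 0, CUSTOM, conformer=res)
    by_pair = {tuple(sorted(b)): l for b, l in zip(res.bonds, res.lengths_after)}
    for arc, row in zip(g.arcs, g.edge_matrix):
        assert abs(row[5] - by_pair[tuple(sorted(arc))]) < 1e-9


def test_atom_permutation_gives_isomorphic_graph():
    """Renumbering input atoms permutes rows but leaves the canonical
    multiset of (node feature, sorted neighbour features) unchanged."""
    mol = Chem.MolFromSmiles("CC(=O)Oc1ccccc1C(=O)O")
    perm = list(range(mol.GetNumAtoms()))[::-1]
    perm_mol = Chem.RenumberAtoms(mol, perm)
    g1 = build_graph(mol, 0, BASIC)
    g2 = build_graph(perm_mol, 0, BASIC)

    def canon(g):
        keys = []
        for i in range(g.n_nodes):
            neigh = sorted(
                tuple(g.node_matrix[j]) for a, j in g.arcs if a == i
            )
            keys.append((tuple(g.node_matrix[i]), tuple(neigh)))
        return sorted(keys)

    assert canon(g1) == canon(g2)


def test_custom_requires_conformer():
    with pytest.raises(ValueError):
        build_graph(Chem.MolFromSmiles("CCO"), 0, CUSTOM, conformer=None)


def test_dataset_roundtrip_bit_exact(tmp_path, toy_conformers):
    graphs = [
        build_graph(mol, i % 2, CUSTOM, conformer=res, graph_id=name)
        for i, (name, mol, res) in enumerate(toy_conformers[:6])
    ]
    ds = GraphDataset(CUSTOM, graphs, provenance={"seed": 11})
    ds.save(tmp_path / "ds")
    back = GraphDataset.load(tmp_path / "ds")
    assert back.schema == ds.schema
    assert back.provenance == ds.provenance
    assert len(back) == len(ds)
    for a, b in zip(ds.graphs, back.graphs):
        assert a.graph_id == b.graph_id and a.label == b.label
        assert np.array_equal(a.node_matrix, b.node_matrix)
        assert np.array_equal(a.arcs, b.arcs)
        assert np.array_equal(a.edge_matrix, b.edge_matrix)
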