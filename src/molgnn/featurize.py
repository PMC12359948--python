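"""Molecular graph construction in two feature schemas.

Graphs are over heavy atoms only: hydrogens are added for 3D embedding but
contribute to the graph solely through the per-atom hydrogen count. Each
chemical bond is stored as two directed arcs carrying identical edge
features, the convention message-passing layers consume.

Two schemas are supported:

* ``basic`` — node: atomic number (one-hot); edge: bond type (one-hot).
* ``custom`` — node: atomic number, degree, formal charge, hybridisation,
  aromaticity, hydrogen count, ring membership, chirality, radical electrons,
  Gasteiger partial charge, total valence, explicit valence; edge: bond type,
  ring flag, and the bond length (Angstrom) measured on the MMFF-optimised
  conformer.

Categorical features are one-hot over fixed vocabularies recorded in the
schema; counts and valences are small integers cast to floats; the Gasteiger
charge and bond length are raw scalars. Non-finite Gasteiger charges (possible
on exotic valence states) are replaced by 0 and flagged on the graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from molgnn.conformers import ConformerResult, conformer_pipeline
from molgnn.records import CompoundRecord
from molgnn.standardize import parse_smiles

# Fixed vocabularies (heavy atoms of the 10-element screen; H is never a node).
ATOMIC_NUMBERS = (6, 7, 8, 9, 15, 16, 17, 35, 53)
HYBRIDIZATIONS = ("SP", "SP2", "SP3", "SP3D", "SP3D2", "other")
BOND_TYPES = ("single", "double", "triple", "aromatic")
CHIRALITIES = ("none", "CW", "CCW", "other")

CUSTOM_NODE_FEATURES = (
    "atomic_number",
    "degree",
    "formal_charge",
    "hybridization",
    "aromaticity",
    "num_hydrogens",
    "in_ring",
    "chirality",
    "radical_electrons",
    "gasteiger_charge",
    "total_valence",
    "explicit_valence",
)
BASIC_NODE_FEATURES = ("atomic_number",)
CUSTOM_EDGE_FEATURES = ("bond_type", "in_ring", "bond_length")
BASIC_EDGE_FEATURES = ("bond_type",)


@dataclass(frozen=True)
class FeatureSchema:
    """Encoding recipe for one of the two graph flavours."""

    mode: Literal["basic", "custom"]

    @property
    def node_features(self) -> tuple[str, ...]:
        return CUSTOM_NODE_FEATURES if self.mode == "custom" else BASIC_NODE_FEATURES

    @property
    def edge_features(self) -> tuple[str, ...]:
        return CUSTOM_EDGE_FEATURES if self.mode == "custom" else BASIC_EDGE_FEATURES

    @property
    def d_node(self) -> int:
        if self.mode == "basic":
            return len(ATOMIC_NUMBERS)
        # one-hots: atomic number 9, hybridisation 6, chirality 4; rest scalar
        return len(ATOMIC_NUMBERS) + 1 + 1 + len(HYBRIDIZATIONS) + 1 + 1 + 1 + len(
            CHIRALITIES
        ) + 1 + 1 + 1 + 1

    @property
    def d_edge(self) -> int:
        return len(BOND_TYPES) + (2 if self.mode == "custom" else 0)

    @property
    def needs_conformer(self) -> bool:
        return self.mode == "custom"

    def header(self) -> dict:
        """Self-describing JSON-serialisable schema description."""
        return {
            "mode": self.mode,
            "node_features": list(self.node_features),
            "edge_features": list(self.edge_features),
            "d_node": self.d_node,
            "d_edge": self.d_edge,
            "vocabularies": {
                "atomic_number": list(ATOMIC_NUMBERS),
                "hybridization": list(HYBRIDIZATIONS),
                "bond_type": list(BOND_TYPES),
                "chirality": list(CHIRALITIES),
            },
        }


@dataclass
class MolecularGraph:
    """A featurised molecule: heavy-atom nodes, directed arcs, label."""

    graph_id: str
    node_matrix: np.ndarray  # (n_nodes, d_node)
    arcs: np.ndarray  # (n_arcs, 2) int, each bond present in both directions
    edge_matrix: np.ndarray  # (n_arcs, d_edge)
    label: int | tuple[int, ...] | None
    charge_warning: bool = False

    @property
    def n_nodes(self) -> int:
        return self.node_matrix.shape[0]

    @property
    def n_arcs(self) -> int:
        return self.arcs.shape[0]


def _one_hot(value, vocab: Sequence) -> np.ndarray:
    vec = np.zeros(len(vocab))
    try:
        vec[list(vocab).index(value)] = 1.0
    except ValueError:
        if vocab[-1] == "other":
            vec[-1] = 1.0
        else:
            raise ValueError(f"value {value!r} not in closed vocabulary {vocab}")
    return vec


def _chirality_tag(atom: Chem.Atom) -> str:
    tag = atom.GetChiralTag()
    if tag == Chem.ChiralType.CHI_UNSPECIFIED:
        return "none"
    if tag == Chem.ChiralType.CHI_TETRAHEDRAL_CW:
        return "CW"
    if tag == Chem.ChiralType.CHI_TETRAHEDRAL_CCW:
        return "CCW"
    return "other"


def compute_gasteiger_charges(mol: Chem.Mol) -> np.ndarray:
    """Per-heavy-atom Gasteiger partial charges (implicit-H contribution kept
    on the heavy atom's own charge as RDKit assigns it)."""
    AllChem.ComputeGasteigerCharges(mol)
    return np.array(
        [float(a.GetDoubleProp("_GasteigerCharge")) for a in mol.GetAtoms()]
    )


def node_feature_vector(
    atom: Chem.Atom, schema: FeatureSchema, gasteiger_charge: float | None = None
) -> np.ndarray:
    """Encode one heavy atom. ``gasteiger_charge`` is required in custom mode."""
    if schema.mode == "basic":
        return _one_hot(atom.GetAtomicNum(), ATOMIC_NUMBERS)
    if gasteiger_charge is None:
        raise ValueError("custom schema requires a Gasteiger charge per atom")
    charge = gasteiger_charge if np.isfinite(gasteiger_charge) else 0.0
    return np.concatenate(
        [
            _one_hot(atom.GetAtomicNum(), ATOMIC_NUMBERS),
            [float(atom.GetDegree())],  # heavy-atom degree
            [float(atom.GetFormalCharge())],
            _one_hot(str(atom.GetHybridization()), HYBRIDIZATIONS),
            [float(atom.GetIsAromatic())],
            [float(atom.GetTotalNumHs())],
            [float(atom.IsInRing())],
            _one_hot(_chirality_tag(atom), CHIRALITIES),
            [float(atom.GetNumRadicalElectrons())],
            [charge],
            [float(atom.GetTotalValence())],
            [float(atom.GetExplicitValence())],
        ]
    )


_BOND_TYPE_NAMES = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


def edge_feature_vector(
    bond: Chem.Bond, schema: FeatureSchema, bond_length: float | None = None
) -> np.ndarray:
    """Encode one bond; ``bond_length`` (Angstrom) is required in custom mode."""
    type_name = _BOND_TYPE_NAMES.get(bond.GetBondType())
    if type_name is None:
        raise ValueError(f"unsupported bond type {bond.GetBondType()}")
    base = _one_hot(type_name, BOND_TYPES)
    if schema.mode == "basic":
        return base
    if bond_length is None:
        raise ValueError("custom schema requires a measured bond length")
    return np.concatenate([base, [float(bond.IsInRing())], [float(bond_length)]])


def build_graph(
    mol: Chem.Mol,
    label: int | tuple[int, ...] | None,
    schema: FeatureSchema,
    *,
    conformer: ConformerResult | None = None,
    graph_id: str = "",
) -> MolecularGraph:
    """Build a molecular graph from a standardised (hydrogen-suppressed)
    molecule.

    In custom mode a successful :class:`ConformerResult` for the same molecule
    must be supplied; bond lengths on arcs come from its optimised geometry.
    A single-atom molecule yields a valid graph with zero arcs.
    """
    n = mol.GetNumAtoms()
    if n < 1:
        raise ValueError("empty molecule")
    charges = None
    lengths_by_bond: dict[tuple[int, int], float] = {}
    if schema.mode == "custom":
        if conformer is None or conformer.optimized is None:
            raise ValueError("custom schema requires an optimised conformer")
        charges = compute_gasteiger_charges(mol)
        # heavy-atom indices coincide between mol and mol_h (Hs appended last)
        for (i, j), length in zip(conformer.bonds, conformer.lengths_after):
            lengths_by_bond[(i, j)] = float(length)
            lengths_by_bond[(j, i)] = float(length)

    node_matrix = np.stack(
        [
            node_feature_vector(
                atom, schema, None if charges is None else charges[atom.GetIdx()]
            )
            for atom in mol.GetAtoms()
        ]
    )
    arcs: list[tuple[int, int]] = []
    edge_rows: list[np.ndarray] = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        length = lengths_by_bond.get((i, j)) if schema.mode == "custom" else None
        row = edge_feature_vector(bond, schema, length)
        arcs.extend([(i, j), (j, i)])
        edge_rows.extend([row, row])
    edge_matrix = (
        np.stack(edge_rows) if edge_rows else np.zeros((0, schema.d_edge))
    )
    charge_warning = bool(
        charges is not None and not np.all(np.isfinite(charges))
    )
    return MolecularGraph(
        graph_id=graph_id,
        node_matrix=node_matrix,
        arcs=np.array(arcs, dtype=np.int64).reshape(-1, 2),
        edge_matrix=edge_matrix,
        label=label,
        charge_warning=charge_warning,
    )


@dataclass
class GraphDataset:
    """A list of featurised graphs sharing one schema, with provenance."""

    schema: FeatureSchema
    graphs: list[MolecularGraph]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.graphs)

    def labels(self) -> np.ndarray:
        return np.array([g.label for g in self.graphs])

    def subset(self, indices: Sequence[int]) -> list[MolecularGraph]:
        return [self.graphs[i] for i in indices]

    def save(self, directory: str | Path) -> None:
        """Serialise as a self-describing container: JSON header + columnar
        arrays. Round-trips bit-exact."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        header = {
            "schema": self.schema.header(),
            "provenance": self.provenance,
            "graph_ids": [g.graph_id for g in self.graphs],
            "labels": [
                list(g.label) if isinstance(g.label, tuple) else g.label
                for g in self.graphs
            ],
            "charge_warnings": [bool(g.charge_warning) for g in self.graphs],
            "n_nodes": [g.n_nodes for g in self.graphs],
            "n_arcs": [g.n_arcs for g in self.graphs],
        }
        (directory / "header.json").write_text(json.dumps(header, indent=1))
        arrays = {}
        if self.graphs:
            arrays["node_matrix"] = np.concatenate([g.node_matrix for g in self.graphs])
            arrays["arcs"] = np.concatenate([g.arcs for g in self.graphs])
            arrays["edge_matrix"] = np.concatenate([g.edge_matrix for g in self.graphs])
        np.savez(directory / "arrays.npz", **arrays)

    @classmethod
    def load(cls, directory: str | Path) -> "GraphDataset":
        directory = Path(directory)
        header = json.loads((directory / "header.json").read_text())
        schema = FeatureSchema(mode=header["schema"]["mode"])
        with np.load(directory / "arrays.npz") as npz:
            arrays = {k: npz[k] for k in npz.files}
        graphs = []
        node_off = arc_off = 0
        for gid, label, warn, n_nodes, n_arcs in zip(
            header["graph_ids"],
            header["labels"],
            header["charge_warnings"],
            header["n_nodes"],
            header["n_arcs"],
        ):
            graphs.append(
                MolecularGraph(
                    graph_id=gid,
                    node_matrix=arrays["node_matrix"][node_off : node_off + n_nodes],
                    arcs=arrays["arcs"][arc_off : arc_off + n_arcs],
                    edge_matrix=arrays["edge_matrix"][arc_off : arc_off + n_arcs],
                    label=tuple(label) if isinstance(label, list) else label,
                    charge_warning=warn,
                )
            )
            node_off += n_nodes
            arc_off += n_arcs
        return cls(schema=schema, graphs=graphs, provenance=header["provenance"])


@dataclass
class FeaturizationFailure:
    graph_id: str
    stage: str
    message: str


def featurize_records(
    records: Sequence[CompoundRecord],
    smiles_list: Sequence[str],
    schema: FeatureSchema,
    *,
    seed: int = 0,
    max_attempts: int = 5000,
) -> tuple[GraphDataset, list[FeaturizationFailure]]:
    """Featurise standardised records (``smiles_list`` aligned with records).

    Conformers are only generated in custom mode; failures (embedding
    exhaustion, missing force-field parameters) are collected, not raised.
    """
    graphs: list[MolecularGraph] = []
    failures: list[FeaturizationFailure] = []
    for k, (record, smi) in enumerate(zip(records, smiles_list)):
        mol = parse_smiles(smi)
        if mol is None:
            failures.append(
                FeaturizationFailure(record.compound_id, "parse", f"bad SMILES {smi!r}")
            )
            continue
        conf: ConformerResult | None = None
        if schema.needs_conformer:
            try:
                conf = conformer_pipeline(
                    mol, seed=(seed * 1000003 + k) % (2**31 - 1), max_attempts=max_attempts
                )
            except ValueError as exc:
                failures.append(
                    FeaturizationFailure(record.compound_id, "mmff", str(exc))
                )
                continue
            if conf.optimized is None:
                failures.append(
                    FeaturizationFailure(
                        record.compound_id, "embed", "embedding exhausted attempts"
                    )
                )
                continue
        graphs.append(
            build_graph(
                mol, record.label, schema, conformer=conf, graph_id=record.compound_id
            )
        )
    dataset = GraphDataset(
        schema=schema,
        graphs=graphs,
        provenance={"seed": seed, "max_attempts": max_attempts},
    )
    return dataset, failures
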