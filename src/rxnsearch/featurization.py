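"""Molecule-set featurization: attributed graphs for the encoder.

A molecule set (one or many "."-separated molecules) becomes a single graph
whose connected components are the molecules. Nodes are heavy atoms
(hydrogens implicit), edges are bonds stored once; the encoder passes
messages in both directions.

Node features: atomic number, formal charge, degree, hybridization, total H
count, chirality (CW/CCW/none), aromatic flag, in-ring flag and a multi-hot
over associated ring sizes {3,4,5,6,7,8+}. Edge features: bond type, bond
direction (end-upright/end-downright/none), stereochemistry (E/Z/none),
in-ring flag, conjugated flag. All categoricals are one-hot over the frozen
vocabularies below with a trailing "other" bucket, so rare species never
crash featurization and feature dimensions are constant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from .reaction_io import ReactionError, ReactionRecord

__all__ = [
    "MolGraph",
    "ReactionGraphTuple",
    "FEATURE_MANIFEST",
    "NODE_FEATURE_DIM",
    "EDGE_FEATURE_DIM",
    "featurize_molecule_set",
    "featurize_record",
    "feature_manifest_json",
]

# frozen categorical vocabularies; last slot of every one-hot is "other"
ATOMIC_NUMS = [5, 6, 7, 8, 9, 14, 15, 16, 17, 35, 53, 3, 11, 12, 19, 20, 29, 30, 46, 26, 50]
FORMAL_CHARGES = [-2, -1, 0, 1, 2]
DEGREES = [0, 1, 2, 3, 4, 5]
HYBRIDIZATIONS = ["S", "SP", "SP2", "SP3", "SP3D", "SP3D2", "UNSPECIFIED"]
NUM_HS = [0, 1, 2, 3, 4]
CHIRALITY = ["CHI_TETRAHEDRAL_CW", "CHI_TETRAHEDRAL_CCW", "none"]
RING_SIZES = [3, 4, 5, 6, 7]  # plus an 8+ bucket
BOND_TYPES = ["SINGLE", "DOUBLE", "TRIPLE", "AROMATIC"]
BOND_DIRS = ["ENDUPRIGHT", "ENDDOWNRIGHT", "none"]
BOND_STEREO = ["STEREOE", "STEREOZ", "none"]

FEATURE_MANIFEST = {
    "version": 1,
    "node": {
        "atomic_number": ATOMIC_NUMS + ["other"],
        "formal_charge": FORMAL_CHARGES + ["other"],
        "degree": DEGREES + ["other"],
        "hybridization": HYBRIDIZATIONS + ["other"],
        "num_hs": NUM_HS + ["other"],
        "chirality": CHIRALITY,
        "flags": ["aromatic", "in_ring"],
        "ring_sizes": RING_SIZES + ["8+"],
    },
    "edge": {
        "bond_type": BOND_TYPES + ["other"],
        "bond_dir": BOND_DIRS,
        "stereo": BOND_STEREO,
        "flags": ["in_ring", "conjugated"],
    },
}


def _onehot(value, vocab: Sequence) -> np.ndarray:
    vec = np.zeros(len(vocab) + 1)
    try:
        vec[vocab.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0  # "other" bucket
    return vec


def _onehot_nofallback(value, vocab: Sequence) -> np.ndarray:
    # vocab already ends in its default class ("none")
    vec = np.zeros(len(vocab))
    vec[vocab.index(value) if value in vocab else len(vocab) - 1] = 1.0
    return vec


NODE_FEATURE_DIM = (
    len(ATOMIC_NUMS) + 1
    + len(FORMAL_CHARGES) + 1
    + len(DEGREES) + 1
    + len(HYBRIDIZATIONS) + 1
    + len(NUM_HS) + 1
    + len(CHIRALITY)
    + 2  # aromatic, in_ring
    + len(RING_SIZES) + 1  # ring-size multi-hot incl. 8+
)
EDGE_FEATURE_DIM = (
    len(BOND_TYPES) + 1 + len(BOND_DIRS) + len(BOND_STEREO) + 2
)


@dataclass
class MolGraph:
    """Attributed graph of one molecule set; components are the molecules."""

    node_features: np.ndarray  # (n_nodes, NODE_FEATURE_DIM)
    edges: np.ndarray  # (n_edges, 2) undirected, stored once per bond
    edge_features: np.ndarray  # (n_edges, EDGE_FEATURE_DIM)
    n_nodes: int

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def n_components(self) -> int:
        # union-find over stored bonds
        parent = list(range(self.n_nodes))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for u, v in self.edges:
            ru, rv = find(int(u)), find(int(v))
            if ru != rv:
                parent[ru] = rv
        return len({find(i) for i in range(self.n_nodes)})


@dataclass
class ReactionGraphTuple:
    product_graph: MolGraph
    reactant_graph: MolGraph
    reagent_graph: MolGraph | None = None


def _atom_features(atom: Chem.Atom, ring_info) -> np.ndarray:
    idx = atom.GetIdx()
    ring_sizes = np.zeros(len(RING_SIZES) + 1)
    for size_slot, size in enumerate(RING_SIZES):
        if ring_info.IsAtomInRingOfSize(idx, size):
            ring_sizes[size_slot] = 1.0
    if atom.IsInRing() and not any(
        ring_info.IsAtomInRingOfSize(idx, s) for s in RING_SIZES
    ):
        ring_sizes[-1] = 1.0  # only rings of size >= 8
    return np.concatenate(
        [
            _onehot(atom.GetAtomicNum(), ATOMIC_NUMS),
            _onehot(atom.GetFormalCharge(), FORMAL_CHARGES),
            _onehot(atom.GetDegree(), DEGREES),
            _onehot(str(atom.GetHybridization()), HYBRIDIZATIONS),
            _onehot(atom.GetTotalNumHs(), NUM_HS),
            _onehot_nofallback(str(atom.GetChiralTag()), CHIRALITY),
            [float(atom.GetIsAromatic()), float(atom.IsInRing())],
            ring_sizes,
        ]
    )


def _bond_features(bond: Chem.Bond) -> np.ndarray:
    return np.concatenate(
        [
            _onehot(str(bond.GetBondType()), BOND_TYPES),
            _onehot_nofallback(str(bond.GetBondDir()), BOND_DIRS),
            _onehot_nofallback(str(bond.GetStereo()), BOND_STEREO),
            [float(bond.IsInRing()), float(bond.GetIsConjugated())],
        ]
    )


def featurize_molecule_set(molecules: Sequence[str]) -> MolGraph:
    """Build one graph for a list of molecule notations.

    An empty list yields the valid 0-node graph (the encoder maps it to a
    zero readout).
    """
    node_rows: list[np.ndarray] = []
    edge_rows: list[np.ndarray] = []
    edges: list[tuple[int, int]] = []
    offset = 0
    for smiles in molecules:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ReactionError(f"unparsable molecule notation: {smiles!r}")
        Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
        ring_info = mol.GetRingInfo()
        for atom in mol.GetAtoms():
            node_rows.append(_atom_features(atom, ring_info))
        for bond in mol.GetBonds():
            edges.append(
                (bond.GetBeginAtomIdx() + offset, bond.GetEndAtomIdx() + offset)
            )
            edge_rows.append(_bond_features(bond))
        offset += mol.GetNumAtoms()
    return MolGraph(
        node_features=(
            np.array(node_rows) if node_rows else np.zeros((0, NODE_FEATURE_DIM))
        ),
        edges=np.array(edges, dtype=np.int64).reshape(-1, 2),
        edge_features=(
            np.array(edge_rows) if edge_rows else np.zeros((0, EDGE_FEATURE_DIM))
        ),
        n_nodes=offset,
    )


def featurize_record(record: ReactionRecord) -> ReactionGraphTuple:
    """Featurize a record into (product, reactants, reagents) graphs.

    The reagent graph is absent (``None``) iff the reagent list is empty,
    which makes the reagent head contribute exactly a zero vector to the
    prediction embedding.
    """
    product_graph = featurize_molecule_set([record.product])
    if product_graph.n_components() != 1:
        raise ReactionError(
            f"record {record.record_id}: product is not a single connected species"
        )
    return ReactionGraphTuple(
        product_graph=product_graph,
        reactant_graph=featurize_molecule_set(record.reactants),
        reagent_graph=(
            featurize_molecule_set(record.reagents) if record.reagents else None
        ),
    )


def feature_manifest_json() -> str:
    return json.dumps(FEATURE_MANIFEST, indent=2)
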