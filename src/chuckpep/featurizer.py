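"""Graph representations of assembled peptides for message-passing models.

The graph of a peptide is the molecular graph of its heavy atoms: a node
feature matrix of shape ``n_atoms x 24`` (27 when stereodescriptor columns
are enabled), an edge feature matrix of shape ``n_bonds x 16``, and an
integer adjacency array of shape ``2 x E`` listing bonded atom-index pairs.
By default every bond is listed in both directions (``E = 2 * n_bonds``),
which is the layout message-passing frameworks such as PyTorch Geometric
expect; an undirected single listing is available via
``directed_duplication=False``.

Residue-level context rides along: the residue index of every atom
(``residue_of_atom``), a ``k x 2`` matrix of per-residue chirality flags
([1,0] L, [0,1] D, [0,0] achiral), and per-bond indicators for backbone
peptide bonds and intra-residue bonds.

Optional chirality columns one-hot the CIP descriptor of each atom as
S / R / not-defined, computed with RDKit's modern CIP labeler so that, for
example, L-cysteine is correctly labeled R.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import Lipinski, rdCIPLabeler

from .assembler import AssembledPeptide
from .library import chirality_flag

__all__ = [
    "PeptideGraph",
    "FeaturizationError",
    "ELEMENT_VOCABULARY",
    "ATOM_FEATURE_NAMES",
    "CHIRALITY_FEATURE_NAMES",
    "BOND_FEATURE_NAMES",
    "build_graph",
    "atom_feature_vector",
    "bond_feature_vector",
    "export_graph",
    "load_graph",
]


class FeaturizationError(ValueError):
    """Raised when a molecule cannot be featurized with the fixed layout."""


ELEMENT_VOCABULARY = ("C", "N", "O", "S", "F", "Cl", "Br", "P", "Se")

ATOM_FEATURE_NAMES = tuple(
    [f"element_{e}" for e in ELEMENT_VOCABULARY] + ["element_other"]
    + [f"degree_{d}" for d in (1, 2, 3, 4)] + ["degree_other"]
    + [f"num_h_{h}" for h in (0, 1, 2, 3)]
    + ["formal_charge", "aromatic", "in_ring",
       "hybridization_sp2", "hybridization_sp3"]
)
assert len(ATOM_FEATURE_NAMES) == 24

CHIRALITY_FEATURE_NAMES = ("cip_S", "cip_R", "cip_not_defined")

BOND_FEATURE_NAMES = (
    "type_single", "type_double", "type_triple", "type_aromatic",
    "conjugated", "in_ring",
    "stereo_none", "stereo_Z", "stereo_E", "stereo_other",
    "peptide_bond", "intra_residue", "rotatable",
    "ring_size_5", "ring_size_6", "ring_size_other",
)
assert len(BOND_FEATURE_NAMES) == 16


@dataclass(frozen=True)
class PeptideGraph:
    """Feature matrices of one peptide, ready for tensor conversion."""

    node_features: np.ndarray  # (n_atoms, 24) or (n_atoms, 27), float
    edge_features: np.ndarray  # (E, 16), float
    adjacency: np.ndarray      # (2, E), int
    residue_of_atom: np.ndarray  # (n_atoms,), int
    residue_flags: np.ndarray    # (k, 2), int
    atom_feature_names: tuple[str, ...] = field(default=ATOM_FEATURE_NAMES)
    bond_feature_names: tuple[str, ...] = field(default=BOND_FEATURE_NAMES)
    directed_duplication: bool = True

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.adjacency.shape[1]

    @property
    def includes_chirality(self) -> bool:
        return self.node_features.shape[1] == 24 + len(CHIRALITY_FEATURE_NAMES)


def _one_hot(value, choices, other: bool = True) -> list[float]:
    vec = [1.0 if value == c else 0.0 for c in choices]
    if other:
        vec.append(0.0 if any(vec) else 1.0)
    return vec


def atom_feature_vector(atom: Chem.Atom, strict_elements: bool = True) -> np.ndarray:
    """24-column feature vector of one atom.

    Layout: element one-hot over the peptide vocabulary plus ``other`` (10),
    heavy-atom degree one-hot 1-4 plus ``other`` (5), total hydrogen count
    one-hot 0-3 (4), formal charge (1), aromatic flag (1), ring flag (1),
    hybridization one-hot sp2/sp3 (2; sp and anything else map to zeros).
    """
    symbol = atom.GetSymbol()
    if strict_elements and symbol not in ELEMENT_VOCABULARY:
        raise FeaturizationError(
            f"element {symbol!r} is outside the feature vocabulary "
            f"{ELEMENT_VOCABULARY}; supply a custom residue library and set "
            "strict_elements=False to featurize it as 'other'")
    features = _one_hot(symbol, ELEMENT_VOCABULARY)
    features += _one_hot(atom.GetDegree(), (1, 2, 3, 4))
    features += _one_hot(atom.GetTotalNumHs(), (0, 1, 2, 3), other=False)
    features.append(float(atom.GetFormalCharge()))
    features.append(1.0 if atom.GetIsAromatic() else 0.0)
    features.append(1.0 if atom.IsInRing() else 0.0)
    hybridization = atom.GetHybridization()
    features.append(1.0 if hybridization == Chem.HybridizationType.SP2 else 0.0)
    features.append(1.0 if hybridization == Chem.HybridizationType.SP3 else 0.0)
    return np.asarray(features, dtype=float)


_BOND_TYPES = (Chem.BondType.SINGLE, Chem.BondType.DOUBLE,
               Chem.BondType.TRIPLE, Chem.BondType.AROMATIC)
_STEREO_Z = (Chem.BondStereo.STEREOZ, Chem.BondStereo.STEREOCIS)
_STEREO_E = (Chem.BondStereo.STEREOE, Chem.BondStereo.STEREOTRANS)


def bond_feature_vector(bond: Chem.Bond, peptide_bond: bool = False,
                        intra_residue: bool = True,
                        rotatable: bool = False) -> np.ndarray:
    """16-column feature vector of one bond.

    Layout: bond type one-hot single/double/triple/aromatic (4), conjugated
    (1), ring membership (1), double-bond stereo one-hot none/Z/E/other (4),
    backbone peptide-bond flag (1), intra-residue flag (1), rotatable flag
    (1), smallest-ring-size one-hot 5/6/other (3, all zero off-ring).
    """
    features = _one_hot(bond.GetBondType(), _BOND_TYPES, other=False)
    features.append(1.0 if bond.GetIsConjugated() else 0.0)
    features.append(1.0 if bond.IsInRing() else 0.0)
    stereo = bond.GetStereo()
    if stereo == Chem.BondStereo.STEREONONE:
        features += [1.0, 0.0, 0.0, 0.0]
    elif stereo in _STEREO_Z:
        features += [0.0, 1.0, 0.0, 0.0]
    elif stereo in _STEREO_E:
        features += [0.0, 0.0, 1.0, 0.0]
    else:
        features += [0.0, 0.0, 0.0, 1.0]
    features.append(1.0 if peptide_bond else 0.0)
    features.append(1.0 if intra_residue else 0.0)
    features.append(1.0 if rotatable else 0.0)
    if bond.IsInRing():
        size = bond.GetOwningMol().GetRingInfo().MinBondRingSize(bond.GetIdx())
        features += [1.0 if size == 5 else 0.0,
                     1.0 if size == 6 else 0.0,
                     1.0 if size not in (5, 6) else 0.0]
    else:
        features += [0.0, 0.0, 0.0]
    return np.asarray(features, dtype=float)


def _chirality_columns(mol: Chem.Mol) -> np.ndarray:
    """One-hot CIP descriptor (S / R / not-defined) per atom."""
    mol = Chem.Mol(mol)
    rdCIPLabeler.AssignCIPLabels(mol)
    columns = np.zeros((mol.GetNumAtoms(), 3), dtype=float)
    for atom in mol.GetAtoms():
        code = atom.GetProp("_CIPCode") if atom.HasProp("_CIPCode") else None
        if code == "S":
            columns[atom.GetIdx(), 0] = 1.0
        elif code == "R":
            columns[atom.GetIdx(), 1] = 1.0
        else:
            columns[atom.GetIdx(), 2] = 1.0
    return columns


def build_graph(peptide: AssembledPeptide, include_chirality: bool = False,
                directed_duplication: bool = True,
                strict_elements: bool = True) -> PeptideGraph:
    """Build the full graph representation of an assembled peptide."""
    mol = peptide.molecule
    nodes = np.stack([
        atom_feature_vector(atom, strict_elements=strict_elements)
        for atom in mol.GetAtoms()
    ]) if mol.GetNumAtoms() else np.zeros((0, 24))
    if include_chirality:
        nodes = np.hstack([nodes, _chirality_columns(mol)])

    peptide_bond_set = {frozenset(pair) for pair in peptide.peptide_bonds}
    rotatable_matches = {
        frozenset(match)
        for match in mol.GetSubstructMatches(Lipinski.RotatableBondSmarts)
    }
    residue_of_atom = peptide.residue_of_atom

    edge_rows: list[np.ndarray] = []
    pairs: list[tuple[int, int]] = []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        key = frozenset((u, v))
        row = bond_feature_vector(
            bond,
            peptide_bond=key in peptide_bond_set,
            intra_residue=residue_of_atom[u] == residue_of_atom[v],
            rotatable=key in rotatable_matches)
        edge_rows.append(row)
        pairs.append((u, v))
        if directed_duplication:
            edge_rows.append(row.copy())
            pairs.append((v, u))

    edges = np.stack(edge_rows) if edge_rows else np.zeros((0, 16))
    adjacency = (np.asarray(pairs, dtype=int).T if pairs
                 else np.zeros((2, 0), dtype=int))

    flags = np.asarray(
        [chirality_flag(c) for c in peptide.residue_chirality], dtype=int
    ).reshape(peptide.n_residues, 2)

    names = ATOM_FEATURE_NAMES + (CHIRALITY_FEATURE_NAMES if include_chirality
                                  else ())
    return PeptideGraph(
        node_features=nodes, edge_features=edges, adjacency=adjacency,
        residue_of_atom=residue_of_atom.copy(), residue_flags=flags,
        atom_feature_names=names, bond_feature_names=BOND_FEATURE_NAMES,
        directed_duplication=directed_duplication)


def export_graph(graph: PeptideGraph, path: str | Path) -> Path:
    """Write a graph to an ``.npz`` container loadable with plain NumPy.

    The container stores the five arrays under their field names plus a JSON
    metadata block with the feature column names, so downstream consumers do
    not need this package to interpret the file.
    """
    path = Path(path)
    metadata = json.dumps({
        "atom_feature_names": list(graph.atom_feature_names),
        "bond_feature_names": list(graph.bond_feature_names),
        "directed_duplication": graph.directed_duplication,
    })
    np.savez(
        path,
        node_features=graph.node_features,
        edge_features=graph.edge_features,
        adjacency=graph.adjacency,
        residue_of_atom=graph.residue_of_atom,
        residue_flags=graph.residue_flags,
        metadata=np.array(metadata))
    # np.savez appends .npz when absent; report the real path
    return path if path.suffix == ".npz" else path.with_name(path.name + ".npz")


def load_graph(path: str | Path) -> PeptideGraph:
    """Round-trip counterpart of :func:`export_graph`."""
    with np.load(path) as data:
        metadata = json.loads(str(data["metadata"]))
        return PeptideGraph(
            node_features=data["node_features"],
            edge_features=data["edge_features"],
            adjacency=data["adjacency"],
            residue_of_atom=data["residue_of_atom"],
            residue_flags=data["residue_flags"],
            atom_feature_names=tuple(metadata["atom_feature_names"]),
            bond_feature_names=tuple(metadata["bond_feature_names"]),
            directed_duplication=metadata["directed_duplication"])
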