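"""Graph featurization: matrix shapes, one-hot structure, stereo columns."""

import numpy as np
import pytest

from chuckpep import (
    ATOM_FEATURE_NAMES,
    BOND_FEATURE_NAMES,
    CHIRALITY_FEATURE_NAMES,
    FeaturizationError,
    assemble,
    atom_feature_vector,
    bond_feature_vector,
    build_graph,
    export_graph,
    load_graph,
    tokenize,
)
from chuckpep.library import ResidueEntry, ResidueLibrary


@pytest.fixture(scope="module")
def dipeptide(library):
    return assemble(tokenize("AF", library), library)


def col(names, name):
    return list(names).index(name)


class TestShapes:
    def test_node_width_24_without_chirality(self, dipeptide):
        graph = build_graph(dipeptide)
        assert graph.node_features.shape == \
            (dipeptide.molecule.GetNumAtoms(), 24)

    def test_node_width_27_with_chirality(self, dipeptide):
        graph = build_graph(dipeptide, include_chirality=True)
        assert graph.node_features.shape[1] == 27
        assert graph.atom_feature_names == \
            ATOM_FEATURE_NAMES + CHIRALITY_FEATURE_NAMES

    def test_edge_width_16(self, dipeptide):
        graph = build_graph(dipeptide)
        assert graph.edge_features.shape == \
            (2 * dipeptide.molecule.GetNumBonds(), 16)

    def test_adjacency_first_dimension_2(self, dipeptide):
        graph = build_graph(dipeptide)
        assert graph.adjacency.shape[0] == 2
        assert graph.adjacency.shape[1] == graph.edge_features.shape[0]

    def test_undirected_halves_edge_count(self, dipeptide):
        directed = build_graph(dipeptide, directed_duplication=True)
        undirected = build_graph(dipeptide, directed_duplication=False)
        assert directed.n_edges == 2 * undirected.n_edges


class TestOneHotStructure:
    @pytest.mark.parametrize("sequence,cyclic", [
        ("AF", False), ("GWK", False), ("CMY{Aib}", False), ("PFG", True),
    ])
    def test_one_hot_blocks_sum_to_one_per_row(self, library, sequence, cyclic):
        pep = assemble(tokenize(sequence, library, cyclic=cyclic), library)
        graph = build_graph(pep, include_chirality=True)
        names = graph.atom_feature_names
        blocks = {
            "element": [i for i, n in enumerate(names) if n.startswith("element")],
            "degree": [i for i, n in enumerate(names) if n.startswith("degree")],
            "num_h": [i for i, n in enumerate(names) if n.startswith("num_h")],
            "cip": [i for i, n in enumerate(names) if n.startswith("cip")],
        }
        for block, indices in blocks.items():
            sums = graph.node_features[:, indices].sum(axis=1)
            assert (sums == 1).all(), block
        bond_type = [i for i, n in enumerate(BOND_FEATURE_NAMES)
                     if n.startswith("type")]
        stereo = [i for i, n in enumerate(BOND_FEATURE_NAMES)
                  if n.startswith("stereo")]
        for indices in (bond_type, stereo):
            assert (graph.edge_features[:, indices].sum(axis=1) == 1).all()

    def test_adjacency_symmetric_as_edge_set(self, library):
        pep = assemble(tokenize("GWK", library, cyclic=True), library)
        graph = build_graph(pep, directed_duplication=True)
        edges = {tuple(edge) for edge in graph.adjacency.T}
        assert edges == {(v, u) for u, v in edges}

    def test_graph_is_connected(self, library):
        import networkx as nx
        pep = assemble(tokenize("{ac}AGHK{am}", library), library)
        graph = build_graph(pep)
        g = nx.Graph(list(map(tuple, graph.adjacency.T)))
        assert nx.is_connected(g)
        assert g.number_of_nodes() == graph.n_atoms


class TestAtomFeatures:
    def test_alanine_alpha_carbon(self, library):
        pep = assemble(tokenize("A", library), library)
        vec = atom_feature_vector(pep.molecule.GetAtomWithIdx(1))
        assert vec[col(ATOM_FEATURE_NAMES, "element_C")] == 1
        assert vec[col(ATOM_FEATURE_NAMES, "aromatic")] == 0
        assert vec[col(ATOM_FEATURE_NAMES, "in_ring")] == 0
        assert vec[col(ATOM_FEATURE_NAMES, "hybridization_sp3")] == 1

    def test_backbone_amide_nitrogen(self, library):
        pep = assemble(tokenize("GG", library), library)
        n_idx = pep.peptide_bonds[0][1]
        vec = atom_feature_vector(pep.molecule.GetAtomWithIdx(n_idx))
        assert vec[col(ATOM_FEATURE_NAMES, "element_N")] == 1
        assert vec[col(ATOM_FEATURE_NAMES, "degree_2")] == 1

    def test_phenylalanine_ring_carbon_aromatic(self, library):
        pep = assemble(tokenize("F", library), library)
        ring_atoms = [a for a in pep.molecule.GetAtoms() if a.GetIsAromatic()]
        assert len(ring_atoms) == 6
        vec = atom_feature_vector(ring_atoms[0])
        assert vec[col(ATOM_FEATURE_NAMES, "aromatic")] == 1
        assert vec[col(ATOM_FEATURE_NAMES, "in_ring")] == 1
        assert vec[col(ATOM_FEATURE_NAMES, "hybridization_sp2")] == 1

    def test_out_of_vocabulary_element_raises(self):
        entry = ResidueEntry("{Sil}", "silicon test residue",
                             "[NH2:1]C([SiH3])[C:2](=O)O")
        library = ResidueLibrary([entry], validate=False)
        pep = assemble(tokenize("{Sil}", library), library)
        with pytest.raises(FeaturizationError, match="Si"):
            build_graph(pep)
        graph = build_graph(pep, strict_elements=False)
        assert graph.node_features[:, col(ATOM_FEATURE_NAMES,
                                          "element_other")].sum() == 1


class TestBondFeatures:
    def test_backbone_amide_bond(self, library):
        pep = assemble(tokenize("GG", library), library)
        graph = build_graph(pep, directed_duplication=False)
        c_idx, n_idx = pep.peptide_bonds[0]
        bond = pep.molecule.GetBondBetweenAtoms(c_idx, n_idx)
        row = graph.edge_features[bond.GetIdx()]
        assert row[col(BOND_FEATURE_NAMES, "type_single")] == 1
        assert row[col(BOND_FEATURE_NAMES, "conjugated")] == 1
        assert row[col(BOND_FEATURE_NAMES, "peptide_bond")] == 1
        assert row[col(BOND_FEATURE_NAMES, "intra_residue")] == 0

    def test_peptide_bond_flag_marks_exactly_the_backbone(self, library):
        pep = assemble(tokenize("AGFK", library, cyclic=True), library)
        graph = build_graph(pep, directed_duplication=False)
        flag = graph.edge_features[:, col(BOND_FEATURE_NAMES, "peptide_bond")]
        assert flag.sum() == len(pep.peptide_bonds) == 4

    def test_aromatic_ring_bond(self, library):
        pep = assemble(tokenize("F", library), library)
        mol = pep.molecule
        bond = next(b for b in mol.GetBonds() if b.GetIsAromatic())
        vec = bond_feature_vector(bond)
        assert vec[col(BOND_FEATURE_NAMES, "type_aromatic")] == 1
        assert vec[col(BOND_FEATURE_NAMES, "in_ring")] == 1
        assert vec[col(BOND_FEATURE_NAMES, "ring_size_6")] == 1

    def test_alanine_side_chain_bond_plain_single(self, library):
        pep = assemble(tokenize("A", library), library)
        bond = pep.molecule.GetBondBetweenAtoms(1, 2)  # C-alpha to C-beta
        vec = bond_feature_vector(bond)
        assert vec[col(BOND_FEATURE_NAMES, "type_single")] == 1
        assert vec[col(BOND_FEATURE_NAMES, "in_ring")] == 0
        assert vec[col(BOND_FEATURE_NAMES, "peptide_bond")] == 0


class TestChiralityColumns:
    def test_glycine_all_not_defined(self, library):
        pep = assemble(tokenize("G", library), library)
        graph = build_graph(pep, include_chirality=True)
        nd = col(graph.atom_feature_names, "cip_not_defined")
        assert (graph.node_features[:, nd] == 1).all()

    def test_l_and_d_swap_s_and_r_columns(self, library):
        rng = np.random.default_rng(23)
        letters = list("ARNDCEQHILKMFPSTWYV")
        for _ in range(10):
            seq = "".join(rng.choice(letters, size=rng.integers(2, 7)))
            l_graph = build_graph(
                assemble(tokenize(seq, library), library),
                include_chirality=True)
            d_graph = build_graph(
                assemble(tokenize(seq.lower(), library), library),
                include_chirality=True)
            s_col = col(l_graph.atom_feature_names, "cip_S")
            r_col = col(l_graph.atom_feature_names, "cip_R")
            assert np.array_equal(l_graph.node_features[:, :24],
                                  d_graph.node_features[:, :24])
            assert np.array_equal(l_graph.node_features[:, s_col],
                                  d_graph.node_features[:, r_col])
            assert np.array_equal(l_graph.node_features[:, r_col],
                                  d_graph.node_features[:, s_col])

    def test_residue_flags_match_token_case(self, library):
        pep = assemble(tokenize("Af{NPhe}", library), library)
        graph = build_graph(pep)
        assert graph.residue_flags.tolist() == [[1, 0], [0, 1], [0, 0]]


class TestExport:
    def test_round_trip_bit_identical(self, library, tmp_path):
        pep = assemble(tokenize("AFk{Aib}", library), library)
        graph = build_graph(pep, include_chirality=True)
        path = export_graph(graph, tmp_path / "graph.npz")
        loaded = load_graph(path)
        for attr in ("node_features", "edge_features", "adjacency",
                     "residue_of_atom", "residue_flags"):
            assert np.array_equal(getattr(graph, attr), getattr(loaded, attr))
        assert loaded.atom_feature_names == graph.atom_feature_names

    def test_metadata_lists_feature_names_in_order(self, library, tmp_path):
        import json
        pep = assemble(tokenize("AG", library), library)
        path = export_graph(build_graph(pep), tmp_path / "g.npz")
        with np.load(path) as data:
            metadata = json.loads(str(data["metadata"]))
        assert metadata["atom_feature_names"] == list(ATOM_FEATURE_NAMES)
        assert len(metadata["atom_feature_names"]) == 24
        assert metadata["bond_feature_names"] == list(BOND_FEATURE_NAMES)
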