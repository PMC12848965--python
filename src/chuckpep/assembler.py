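"""CHUCKLES concatenation: token lists to atom-mapped peptide molecules.

Peptide bond formation is a condensation: the C-terminal hydroxyl oxygen of
the upstream residue and one hydrogen of the downstream residue's backbone
nitrogen leave as water.  Because CHUCKLES strings start at the backbone
nitrogen (written as a bracket atom with an explicit H count) and end with
the C-terminal ``(=O)O`` tail, both removals are local string edits:

* drop the final ``O`` of the upstream ``(=O)O`` tail, and
* decrement the bracket H count of the downstream ``[NH2:1]``-style nitrogen
  (``[NH2:1]`` -> ``[NH:1]``, ``[NH:1]`` -> ``[N:1]``).

Concatenating the edited fragments yields the peptide SMILES.  Head-to-tail
macrocycles additionally bond the first residue's nitrogen to the last
residue's carbonyl carbon with a two-digit ``%NN`` ring-closure label, so
the label cannot collide with single-digit ring labels inside side chains.

Atom maps 1 and 2 are retained on the backbone termini of every residue.
Residue membership is nevertheless recovered structurally: the bonds joining
a map-2 carbon to a map-1 nitrogen are the peptide bonds, and cutting them
partitions the atoms into one fragment per residue.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .library import ResidueLibrary
from .tokenizer import TokenizedSequence

__all__ = [
    "AssembledPeptide",
    "AssemblyError",
    "assemble",
    "assemble_linear",
    "assemble_cyclic",
    "residue_mapping",
    "canonical_smiles",
]


class AssemblyError(ValueError):
    """Raised when a token list cannot be joined into a valid molecule."""


_HYDROXYL_TAIL = "(=O)O"
_CARBONYL_TAIL = "(=O)"
_NTERM_RE = re.compile(r"^\[(?P<core>NH?(?P<count>\d?))(?P<map>:1)\]")


@dataclass(frozen=True)
class AssembledPeptide:
    """An assembled peptide: SMILES, molecule and residue bookkeeping.

    ``residue_of_atom[i]`` is the 0-based index (in sequence order) of the
    residue owning atom ``i``; terminal caps count as residues.
    ``peptide_bonds`` lists ``(carbonyl_C, amide_N)`` atom-index pairs in
    sequence order, ``k - 1`` bonds for a linear ``k``-mer and ``k`` for a
    head-to-tail macrocycle.
    """

    smiles: str
    molecule: Chem.Mol = field(repr=False)
    residue_of_atom: np.ndarray = field(repr=False)
    peptide_bonds: tuple[tuple[int, int], ...]
    topology: str
    tokens: tuple[str, ...]
    residue_chirality: tuple[str, ...]

    @property
    def n_residues(self) -> int:
        return len(self.tokens)

    @property
    def canonical_smiles(self) -> str:
        """Canonical SMILES with atom maps stripped (molecule identity)."""
        return canonical_smiles(self.molecule)

    @property
    def formula(self) -> str:
        return rdMolDescriptors.CalcMolFormula(self.molecule)


def canonical_smiles(mol_or_smiles: Chem.Mol | str) -> str:
    """Canonical isomeric SMILES with atom map numbers removed."""
    if isinstance(mol_or_smiles, str):
        mol = Chem.MolFromSmiles(mol_or_smiles)
        if mol is None:
            raise AssemblyError(f"unparseable SMILES {mol_or_smiles!r}")
    else:
        mol = Chem.Mol(mol_or_smiles)
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(mol)


def _strip_hydroxyl(fragment: str, token: str) -> str:
    if not fragment.endswith(_HYDROXYL_TAIL):
        raise AssemblyError(
            f"residue {token!r} cannot donate a carbonyl: its CHUCKLES "
            f"string does not end with {_HYDROXYL_TAIL!r} (is a C-terminal "
            "cap in a non-terminal position?)")
    return fragment[:-1]


def _decrement_nterm_h(fragment: str, token: str) -> str:
    match = _NTERM_RE.match(fragment)
    if match is None:
        raise AssemblyError(
            f"residue {token!r} cannot accept a peptide bond: its CHUCKLES "
            "string does not start with a map-1 nitrogen bracket (is an "
            "N-terminal cap in a non-initial position?)")
    count = int(match.group("count") or (1 if "H" in match.group("core") else 0))
    if count == 0:
        raise AssemblyError(
            f"residue {token!r} has no N-terminal hydrogen left to remove")
    count -= 1
    core = "N" if count == 0 else ("NH" if count == 1 else f"NH{count}")
    return f"[{core}:1]" + fragment[match.end():]


def _free_ring_label(fragments: list[str]) -> str:
    joined = "".join(fragments)
    for label in range(99, 9, -1):
        if f"%{label}" not in joined:
            return f"%{label}"
    raise AssemblyError("no free two-digit ring-closure label in %10-%99")


def _parse(fragments: list[str], tokens: tuple[str, ...]) -> Chem.Mol:
    smiles = "".join(fragments)
    mol = Chem.MolFromSmiles(smiles)
    if mol is not None:
        return mol
    # locate the first failing junction for the error message
    for j in range(1, len(fragments) + 1):
        if Chem.MolFromSmiles("".join(fragments[:j])) is None:
            raise AssemblyError(
                f"assembled SMILES does not parse; first failure at junction "
                f"{j - 1} (token {tokens[j - 1]!r}): {smiles!r}")
    raise AssemblyError(f"assembled SMILES does not parse: {smiles!r}")


def _peptide_bonds_and_residues(
        mol: Chem.Mol, k: int,
) -> tuple[tuple[tuple[int, int], ...], np.ndarray]:
    """Recover peptide bonds and the residue index of every atom.

    Peptide bonds are identified structurally as bonds joining a map-2
    carbon to a map-1 nitrogen; cutting them splits the molecule into one
    fragment per residue, numbered in sequence order (which equals SMILES
    writing order, hence ascending atom index).
    """
    bonds: list[tuple[int, int]] = []
    bond_ids: list[int] = []
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        pair = {a.GetAtomMapNum(): a, b.GetAtomMapNum(): b}
        if set(pair) == {1, 2} and pair[2].GetSymbol() == "C" \
                and pair[1].GetSymbol() == "N":
            bonds.append((pair[2].GetIdx(), pair[1].GetIdx()))
            bond_ids.append(bond.GetIdx())

    residue_of_atom = np.zeros(mol.GetNumAtoms(), dtype=int)
    if bond_ids:
        cut = Chem.FragmentOnBonds(mol, bond_ids, addDummies=False)
        frags = Chem.GetMolFrags(cut, asMols=False)
        # fragments appear in residue order because atom indices do
        for res_index, atom_ids in enumerate(sorted(frags, key=min)):
            residue_of_atom[list(atom_ids)] = res_index
    if len(set(residue_of_atom)) != k:
        raise AssemblyError(
            f"expected {k} residues but the peptide-bond cut produced "
            f"{len(set(residue_of_atom))} fragments")
    # order bonds along the backbone: by the residue of the carbonyl carbon
    ordered = sorted(bonds, key=lambda cn: residue_of_atom[cn[0]])
    return tuple(ordered), residue_of_atom


def _edited_fragments(seq: TokenizedSequence, library: ResidueLibrary,
                      cyclic: bool) -> list[str]:
    fragments = []
    k = len(seq.tokens)
    for i, token in enumerate(seq.tokens):
        fragment = library[token].chuckles_smiles
        if i < k - 1 or cyclic:
            fragment = _strip_hydroxyl(fragment, token)
        if i > 0 or cyclic:
            fragment = _decrement_nterm_h(fragment, token)
        fragments.append(fragment)
    return fragments


def assemble_linear(seq: TokenizedSequence,
                    library: ResidueLibrary) -> AssembledPeptide:
    """Join a linear token list into an atom-mapped peptide."""
    if seq.topology != "linear":
        raise AssemblyError("assemble_linear requires a linear sequence")
    fragments = _edited_fragments(seq, library, cyclic=False)
    mol = _parse(fragments, seq.tokens)
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    bonds, residue_of_atom = _peptide_bonds_and_residues(mol, len(seq.tokens))
    if len(bonds) != len(seq.tokens) - 1:
        raise AssemblyError(
            f"expected {len(seq.tokens) - 1} peptide bonds, found {len(bonds)}")
    return AssembledPeptide(
        smiles="".join(fragments), molecule=mol,
        residue_of_atom=residue_of_atom, peptide_bonds=bonds,
        topology="linear", tokens=seq.tokens,
        residue_chirality=tuple(library[t].chirality for t in seq.tokens))


def assemble_cyclic(seq: TokenizedSequence,
                    library: ResidueLibrary) -> AssembledPeptide:
    """Join a token list head-to-tail into a macrocyclic peptide.

    On top of the linear edits, the last residue also loses its hydroxyl and
    the first residue's nitrogen also loses a hydrogen; the closing amide
    bond is written as a ``%NN`` ring closure on the first nitrogen and the
    last carbonyl carbon.
    """
    if seq.topology != "head_to_tail_cyclic":
        raise AssemblyError("assemble_cyclic requires a head-to-tail cyclic sequence")
    if len(seq.tokens) < 2:
        raise AssemblyError("head-to-tail cycles need at least 2 residues")
    fragments = _edited_fragments(seq, library, cyclic=True)

    label = _free_ring_label(fragments)
    head = fragments[0]
    match = _NTERM_RE.match(head)
    if match is None:  # _edited_fragments already decremented, so this holds
        raise AssemblyError("first residue lost its N-terminal bracket")
    fragments[0] = head[:match.end()] + label + head[match.end():]
    tail = fragments[-1]
    if not tail.endswith(_CARBONYL_TAIL):
        raise AssemblyError("last residue lost its carbonyl tail")
    fragments[-1] = tail[:-len(_CARBONYL_TAIL)] + label + _CARBONYL_TAIL

    mol = _parse(fragments, seq.tokens)
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    bonds, residue_of_atom = _peptide_bonds_and_residues(mol, len(seq.tokens))
    if len(bonds) != len(seq.tokens):
        raise AssemblyError(
            f"expected {len(seq.tokens)} peptide bonds, found {len(bonds)}")
    return AssembledPeptide(
        smiles="".join(fragments), molecule=mol,
        residue_of_atom=residue_of_atom, peptide_bonds=bonds,
        topology="head_to_tail_cyclic", tokens=seq.tokens,
        residue_chirality=tuple(library[t].chirality for t in seq.tokens))


def assemble(seq: TokenizedSequence, library: ResidueLibrary) -> AssembledPeptide:
    """Dispatch on topology."""
    if seq.topology == "head_to_tail_cyclic":
        return assemble_cyclic(seq, library)
    return assemble_linear(seq, library)


def residue_mapping(peptide: AssembledPeptide) -> np.ndarray:
    """Residue index of every atom, aligned with the molecule's atom order."""
    return peptide.residue_of_atom.copy()
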