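"""Regenerate the packaged default residue library (src/chuckpep/data/residues.csv).

The default library is constructed programmatically from a curated set of
side-chain definitions so that related entries stay mutually consistent:
D-isomers are exact mirror images of their L parents (every stereo tag
inverted), peptoid analogs move the side chain from the alpha carbon to the
backbone nitrogen, and N-methyl variants methylate the backbone nitrogen.
Every generated entry is checked before being written: the CHUCKLES string
must parse, the 20 canonical entries must match RDKit's own one-letter
sequence parser, each L/D pair must canonicalize to enantiomers, and each
peptoid analog must preserve the parent's molecular formula.

Run from the repository root:  python scripts/build_default_library.py
"""

from __future__ import annotations

import csv
import pathlib

from rdkit import Chem
from rdkit.Chem import rdCIPLabeler, rdMolDescriptors

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "chuckpep" / "data" / "residues.csv"

# Side chains of the canonical residues, written as the branch attached to the
# alpha carbon (Gly and Pro are handled as special cases).
SIDE_CHAINS = {
    "A": "C",
    "R": "CCCNC(=N)N",
    "N": "CC(N)=O",
    "D": "CC(=O)O",
    "C": "CS",
    "E": "CCC(=O)O",
    "Q": "CCC(N)=O",
    "H": "Cc1c[nH]cn1",
    "I": "[C@@H](C)CC",
    "L": "CC(C)C",
    "K": "CCCCN",
    "M": "CCSC",
    "F": "Cc1ccccc1",
    "S": "CO",
    "T": "[C@H](O)C",
    "W": "Cc1c[nH]c2ccccc12",
    "Y": "Cc1ccc(O)cc1",
    "V": "C(C)C",
}

AA_NAMES = {
    "A": "alanine", "R": "arginine", "N": "asparagine", "D": "aspartic acid",
    "C": "cysteine", "E": "glutamic acid", "Q": "glutamine", "G": "glycine",
    "H": "histidine", "I": "isoleucine", "L": "leucine", "K": "lysine",
    "M": "methionine", "F": "phenylalanine", "P": "proline", "S": "serine",
    "T": "threonine", "W": "tryptophan", "Y": "tyrosine", "V": "valine",
}

AA_CAS = {
    "A": "56-41-7", "R": "74-79-3", "N": "70-47-3", "D": "56-84-8",
    "C": "52-90-4", "E": "56-86-0", "Q": "56-85-9", "G": "56-40-6",
    "H": "71-00-1", "I": "73-32-5", "L": "61-90-5", "K": "56-87-1",
    "M": "63-68-3", "F": "63-91-2", "P": "147-85-3", "S": "56-45-1",
    "T": "72-19-5", "W": "73-22-3", "Y": "60-18-4", "V": "72-18-4",
}

THREE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "E": "Glu",
    "Q": "Gln", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys", "M": "Met",
    "F": "Phe", "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

# Curated noncanonical residues in L (or achiral) form. Entries written with
# the standard alpha-amino template get a D mirror-image counterpart.
NCAA_ALPHA = [
    # token body, name, side chain on the alpha carbon
    ("Orn", "ornithine", "CCCN"),
    ("Dab", "2,4-diaminobutyric acid", "CCN"),
    ("Dap", "2,3-diaminopropionic acid", "CN"),
    ("Cit", "citrulline", "CCCNC(N)=O"),
    ("Hcy", "homocysteine", "CCS"),
    ("Hse", "homoserine", "CCO"),
    ("Nle", "norleucine", "CCCC"),
    ("Nva", "norvaline", "CCC"),
    ("Abu", "2-aminobutyric acid", "CC"),
    ("Tle", "tert-leucine", "C(C)(C)C"),
    ("Cha", "cyclohexylalanine", "CC1CCCCC1"),
    ("Chg", "cyclohexylglycine", "C1CCCCC1"),
    ("Phg", "phenylglycine", "c1ccccc1"),
    ("hPh", "homophenylalanine", "CCc1ccccc1"),
    ("1Nal", "1-naphthylalanine", "Cc1cccc2ccccc12"),
    ("2Nal", "2-naphthylalanine", "Cc1ccc2ccccc2c1"),
    ("4FPhe", "4-fluorophenylalanine", "Cc1ccc(F)cc1"),
    ("4ClPhe", "4-chlorophenylalanine", "Cc1ccc(Cl)cc1"),
    ("4BrPhe", "4-bromophenylalanine", "Cc1ccc(Br)cc1"),
    ("4NO2Phe", "4-nitrophenylalanine", "Cc1ccc([N+](=O)[O-])cc1"),
    ("4NH2Phe", "4-aminophenylalanine", "Cc1ccc(N)cc1"),
    ("3MePhe", "3-methylphenylalanine", "Cc1cccc(C)c1"),
    ("OMeTyr", "O-methyltyrosine", "Cc1ccc(OC)cc1"),
    ("DOPA", "3,4-dihydroxyphenylalanine", "Cc1ccc(O)c(O)c1"),
    ("2Pal", "2-pyridylalanine", "Cc1ccccn1"),
    ("3Pal", "3-pyridylalanine", "Cc1cccnc1"),
    ("4Pal", "4-pyridylalanine", "Cc1ccncc1"),
    ("Thi", "2-thienylalanine", "Cc1cccs1"),
    ("Alg", "allylglycine", "CC=C"),
    ("Prg", "propargylglycine", "CC#C"),
    ("Aha", "azidohomoalanine", "CCN=[N+]=[N-]"),
]

# Cyclic secondary-amine backbones need the full CHUCKLES string.
NCAA_CYCLIC = [
    ("Hyp", "trans-4-hydroxyproline", "[NH:1]1C[C@H](O)C[C@H]1[C:2](=O)O"),
    ("Pip", "pipecolic acid", "[NH:1]1CCCC[C@H]1[C:2](=O)O"),
    ("Aze", "azetidine-2-carboxylic acid", "[NH:1]1CC[C@H]1[C:2](=O)O"),
]

NCAA_ACHIRAL = [
    ("Aib", "2-aminoisobutyric acid", "[NH2:1]C(C)(C)[C:2](=O)O"),
    ("Sar", "sarcosine", "[NH:1](C)C[C:2](=O)O"),
    ("bAla", "beta-alanine", "[NH2:1]CC[C:2](=O)O"),
    ("GABA", "4-aminobutyric acid", "[NH2:1]CCC[C:2](=O)O"),
    ("5Ava", "5-aminovaleric acid", "[NH2:1]CCCC[C:2](=O)O"),
    ("Ahx", "6-aminohexanoic acid", "[NH2:1]CCCCC[C:2](=O)O"),
]


def invert_stereo(smiles: str) -> str:
    """Mirror a SMILES string by flipping every tetrahedral tag."""
    return smiles.replace("@@", "\0").replace("@", "@@").replace("\0", "@")


def canonical_nomap(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles}")
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(mol)


def alpha_cip(smiles: str) -> str:
    """CIP code of the backbone stereocenter adjacent to the map-1 nitrogen."""
    mol = Chem.MolFromSmiles(smiles)
    rdCIPLabeler.AssignCIPLabels(mol)
    for atom in mol.GetAtoms():
        if atom.GetAtomMapNum() == 1:
            for nbr in atom.GetNeighbors():
                if nbr.GetSymbol() == "C" and nbr.HasProp("_CIPCode"):
                    return nbr.GetProp("_CIPCode")
    return "none"


def formula(smiles: str) -> str:
    return rdMolDescriptors.CalcMolFormula(Chem.MolFromSmiles(smiles))


def l_chuckles(letter: str) -> str:
    if letter == "G":
        return "[NH2:1]C[C:2](=O)O"
    if letter == "P":
        return "[NH:1]1CCC[C@H]1[C:2](=O)O"
    return f"[NH2:1][C@@H]({SIDE_CHAINS[letter]})[C:2](=O)O"


def build() -> list[dict]:
    rows: list[dict] = []

    def add(token, name, smiles, chirality, rclass, cas=""):
        cip = alpha_cip(smiles) if chirality in ("L", "D") else "none"
        rows.append({
            "Token": token, "Name": name, "SMILES (CHUCKLES)": smiles,
            "Chirality": chirality, "Class": rclass, "CAS": cas,
            "AlphaCIP": cip,
        })

    # --- 20 canonical L residues -------------------------------------------
    for letter in "ARNDCEQGHILKMFPSTWYV":
        smiles = l_chuckles(letter)
        assert canonical_nomap(smiles) == Chem.MolToSmiles(Chem.MolFromSequence(letter)), letter
        chirality = "achiral" if letter == "G" else "L"
        add(letter, f"L-{AA_NAMES[letter]}" if letter != "G" else "glycine",
            smiles, chirality, "canonical", AA_CAS[letter])

    # --- 19 D isomers (glycine has none) -----------------------------------
    for letter in "ARNDCEQHILKMFPSTWYV":
        smiles = invert_stereo(l_chuckles(letter))
        add(letter.lower(), f"D-{AA_NAMES[letter]}", smiles, "D", "d_isomer")

    # --- 18 peptoid analogs (no Pro/Gly analog) ----------------------------
    for letter in "ARNDCEQHILKMFSTWYV":
        smiles = f"[NH:1]({SIDE_CHAINS[letter]})C[C:2](=O)O"
        assert formula(smiles) == formula(l_chuckles(letter)), letter
        add("{N%s}" % THREE_LETTER[letter], f"N-{AA_NAMES[letter]} peptoid",
            smiles, "achiral", "peptoid")

    # --- noncanonical amino acids ------------------------------------------
    for body, name, sc in NCAA_ALPHA:
        add("{%s}" % body, f"L-{name}", f"[NH2:1][C@@H]({sc})[C:2](=O)O", "L", "ncaa")
    for body, name, smiles in NCAA_CYCLIC:
        add("{%s}" % body, f"L-{name}", smiles, "L", "ncaa")
    for body, name, smiles in NCAA_ACHIRAL:
        add("{%s}" % body, name, smiles, "achiral", "ncaa")
    # D mirror images of the chiral noncanonicals
    for body, name, sc in NCAA_ALPHA:
        smiles = invert_stereo(f"[NH2:1][C@@H]({sc})[C:2](=O)O")
        add("{d%s}" % body, f"D-{name}", smiles, "D", "ncaa")
    for body, name, smiles in NCAA_CYCLIC:
        add("{d%s}" % body, f"D-{name}", invert_stereo(smiles), "D", "ncaa")
    # N-methylated canonical residues (Gly and Pro excluded)
    for letter in "ARNDCEQHILKMFSTWYV":
        smiles = f"[NH:1](C)[C@@H]({SIDE_CHAINS[letter]})[C:2](=O)O"
        add("{me%s}" % letter, f"N-methyl-L-{AA_NAMES[letter]}", smiles, "L", "ncaa")

    # --- end caps -----------------------------------------------------------
    add("{ac}", "acetyl (N-terminal cap)", "C[C:2](=O)O", "achiral", "n_cap", "64-19-7")
    add("{am}", "amide (C-terminal cap)", "[NH3:1]", "achiral", "c_cap")

    # --- PEG spacer units ----------------------------------------------------
    for n in range(1, 7):
        smiles = "[NH2:1]" + "CCO" * n + "C[C:2](=O)O"
        add("{PEG%d}" % n, f"amino-PEG{n}-acid spacer", smiles, "achiral", "polymer")

    return rows


def check(rows: list[dict]) -> None:
    tokens = [r["Token"] for r in rows]
    assert len(tokens) == len(set(tokens)), "duplicate tokens"
    assert len(rows) == 157, f"library has {len(rows)} entries, expected 157"
    by_token = {r["Token"]: r for r in rows}
    # every entry parses; L/D pairs are enantiomers
    for r in rows:
        assert Chem.MolFromSmiles(r["SMILES (CHUCKLES)"]) is not None, r["Token"]
    for r in rows:
        if r["Chirality"] != "D":
            continue
        tok = r["Token"]
        partner = tok.upper() if len(tok) == 1 else "{%s}" % tok[2:-1]
        ref = by_token[partner]["SMILES (CHUCKLES)"]
        assert canonical_nomap(invert_stereo(r["SMILES (CHUCKLES)"])) == canonical_nomap(ref), tok
        assert formula(r["SMILES (CHUCKLES)"]) == formula(ref), tok


def main() -> None:
    rows = build()
    check(rows)
    OUT.parent.mkdir(parents=True, exist_ok=True)
    with OUT.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    print(f"wrote {len(rows)} entries to {OUT}")


if __name__ == "__main__":
    main()
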