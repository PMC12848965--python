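"""Residue libraries in CHUCKLES format.

A residue library maps short tokens (one-letter codes or ``{...}`` symbols)
to monomer definitions written in the CHUCKLES convention: a SMILES string
whose atoms are ordered N-terminus, alpha carbon, C-terminus, with atom map
number 1 on the backbone nitrogen and 2 on the carbonyl carbon.  Because the
termini sit at the string ends, monomers concatenate into valid peptide
SMILES by simple string surgery (see :mod:`chuckpep.assembler`).

The packaged default library holds 157 entries: the 20 canonical L residues,
their 19 D isomers, peptoid analogs of the canonical side chains (Pro and
Gly have none), a curated set of noncanonical amino acids in L and D form,
N-methylated residues, acetyl/amide end caps and amino-PEG-acid spacers.
Users supply their own CSV/XLSX table to extend or replace it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional

import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdCIPLabeler, rdMolDescriptors

__all__ = [
    "ResidueEntry",
    "ResidueLibrary",
    "ValidationReport",
    "LibraryError",
    "load_default",
    "load_custom",
    "validate_entry",
    "residue_flag",
]

CHIRALITIES = ("L", "D", "achiral")
RESIDUE_CLASSES = (
    "canonical", "d_isomer", "ncaa", "peptoid", "n_cap", "c_cap", "polymer",
)

#: token grammar: one uppercase letter (L residue), one lowercase letter
#: (D residue), or a nonempty brace symbol with no nested braces.
TOKEN_RE = re.compile(r"^(?:[A-Z]|[a-z]|\{[^{}]+\})$")

#: the N-terminal bracket atom carrying map 1, with an explicit H count the
#: assembler can decrement, e.g. "[NH2:1]", "[NH:1]", "[NH3:1]".
_NTERM_BRACKET_RE = re.compile(r"^\[(?:NH(?P<count>\d?)|N):1\]")

_CTERM_TAIL = "(=O)O"


class LibraryError(ValueError):
    """Raised for malformed library files or invalid entries."""


@dataclass(frozen=True)
class ResidueEntry:
    """A single monomer definition in CHUCKLES format."""

    token: str
    name: str
    chuckles_smiles: str
    chirality: str = "achiral"
    residue_class: str = "ncaa"
    cas: Optional[str] = None
    expected_alpha_cip: Optional[str] = None

    def __post_init__(self) -> None:
        if self.chirality not in CHIRALITIES:
            raise LibraryError(
                f"token {self.token!r}: chirality must be one of {CHIRALITIES}, "
                f"got {self.chirality!r}")
        if self.residue_class not in RESIDUE_CLASSES:
            raise LibraryError(
                f"token {self.token!r}: residue class must be one of "
                f"{RESIDUE_CLASSES}, got {self.residue_class!r}")

    @property
    def mol(self) -> Chem.Mol:
        """Sanitized RDKit molecule of the free monomer."""
        mol = Chem.MolFromSmiles(self.chuckles_smiles)
        if mol is None:
            raise LibraryError(
                f"token {self.token!r}: unparseable SMILES "
                f"{self.chuckles_smiles!r}")
        return mol

    @property
    def formula(self) -> str:
        return rdMolDescriptors.CalcMolFormula(self.mol)


@dataclass(frozen=True)
class ValidationCheck:
    name: str
    passed: bool
    message: str = ""


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of the per-entry contract checks (failures reported, not raised)."""

    token: str
    checks: tuple[ValidationCheck, ...]

    @property
    def ok(self) -> bool:
        return all(c.passed for c in self.checks)

    @property
    def failures(self) -> tuple[ValidationCheck, ...]:
        return tuple(c for c in self.checks if not c.passed)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"entry {self.token!r}: " + ("OK" if self.ok else "FAILED")]
        for c in self.checks:
            status = "pass" if c.passed else "FAIL"
            lines.append(f"  [{status}] {c.name}" + (f": {c.message}" if c.message else ""))
        return "\n".join(lines)


def _mapped_atoms(mol: Chem.Mol, mapnum: int) -> list[Chem.Atom]:
    return [a for a in mol.GetAtoms() if a.GetAtomMapNum() == mapnum]


def _alpha_cip(mol: Chem.Mol) -> Optional[str]:
    """CIP code of the carbon stereocenter adjacent to the map-1 nitrogen."""
    mol = Chem.Mol(mol)
    rdCIPLabeler.AssignCIPLabels(mol)
    for atom in mol.GetAtoms():
        if atom.GetAtomMapNum() == 1:
            for nbr in atom.GetNeighbors():
                if nbr.GetSymbol() == "C" and nbr.HasProp("_CIPCode"):
                    return nbr.GetProp("_CIPCode")
    return None


def validate_entry(entry: ResidueEntry) -> ValidationReport:
    """Check one entry against the CHUCKLES library contract.

    The contract per residue class:

    * every class: the token matches the closed grammar and the SMILES parses;
    * ordinary residues (everything except caps): map 1 on the first-written
      nitrogen with an explicit bracket H count, map 2 on the carbonyl
      carbon, and the string ends in ``(=O)O`` so the assembler can strip the
      C-terminal hydroxyl;
    * ``n_cap``: map 2 and the ``(=O)O`` tail only (a cap donates its
      carbonyl to the following residue's nitrogen);
    * ``c_cap``: map 1 only (it accepts the preceding residue's carbonyl).

    When ``expected_alpha_cip`` is set, the CIP descriptor recomputed for the
    alpha carbon must agree — this is how L/D bookkeeping errors (including
    the cysteine R/S inversion) are caught without hard-coding exceptions.
    """
    checks: list[ValidationCheck] = []

    def check(name: str, passed: bool, message: str = "") -> bool:
        checks.append(ValidationCheck(name, bool(passed), message))
        return bool(passed)

    check("token-grammar", TOKEN_RE.match(entry.token) is not None,
          f"token {entry.token!r} is not a single letter or {{...}} symbol")

    smiles = entry.chuckles_smiles
    mol = Chem.MolFromSmiles(smiles)
    if not check("parseable", mol is not None, f"unparseable SMILES {smiles!r}"):
        return ValidationReport(entry.token, tuple(checks))

    map1 = _mapped_atoms(mol, 1)
    map2 = _mapped_atoms(mol, 2)
    needs_map1 = entry.residue_class != "n_cap"
    needs_map2 = entry.residue_class != "c_cap"

    if needs_map1:
        ok = (len(map1) == 1 and map1[0].GetSymbol() == "N"
              and map1[0].GetIdx() == 0
              and _NTERM_BRACKET_RE.match(smiles) is not None)
        check("n-terminus-map", ok,
              "expected exactly one map-1 nitrogen written first as a bracket "
              "atom with explicit H count")
    else:
        check("n-terminus-map", len(map1) == 0,
              "n_cap entries must not carry atom map 1")

    if needs_map2:
        ok = len(map2) == 1 and map2[0].GetSymbol() == "C" and any(
            b.GetBondType() == Chem.BondType.DOUBLE
            and b.GetOtherAtom(map2[0]).GetSymbol() == "O"
            for b in map2[0].GetBonds())
        check("c-terminus-map", ok,
              "expected exactly one map-2 carbonyl carbon")
        check("hydroxyl-tail", smiles.endswith(_CTERM_TAIL),
              f"SMILES must end with {_CTERM_TAIL!r}")
    else:
        check("c-terminus-map", len(map2) == 0,
              "c_cap entries must not carry atom map 2")

    if entry.expected_alpha_cip and entry.expected_alpha_cip != "none":
        cip = _alpha_cip(mol)
        check("alpha-cip", cip == entry.expected_alpha_cip,
              f"alpha carbon CIP is {cip}, expected {entry.expected_alpha_cip}")

    # stereo round trip: parse -> write -> parse must be stable
    rewritten = Chem.MolToSmiles(mol)
    reparsed = Chem.MolFromSmiles(rewritten)
    check("stereo-round-trip",
          reparsed is not None and Chem.MolToSmiles(reparsed) == rewritten,
          "canonical SMILES is not stable under re-parsing")

    return ValidationReport(entry.token, tuple(checks))


def chirality_flag(chirality: str) -> tuple[int, int]:
    """Chirality as a two-bit flag: L -> (1, 0), D -> (0, 1), achiral -> (0, 0).

    The zero vector keeps the flag two-dimensional for residues that have no
    alpha stereocenter (glycine, peptoid units, caps, polymer spacers).
    """
    if chirality == "L":
        return (1, 0)
    if chirality == "D":
        return (0, 1)
    return (0, 0)


def residue_flag(entry: ResidueEntry) -> tuple[int, int]:
    """Residue-level chirality flag of one library entry."""
    return chirality_flag(entry.chirality)


class ResidueLibrary:
    """Validated, ordered token -> :class:`ResidueEntry` map."""

    def __init__(self, entries: list[ResidueEntry], source: str = "custom",
                 validate: bool = True) -> None:
        self._entries: dict[str, ResidueEntry] = {}
        self.source = source
        for i, entry in enumerate(entries):
            if entry.token in self._entries:
                raise LibraryError(f"row {i}: duplicate token {entry.token!r}")
            if validate:
                report = validate_entry(entry)
                if not report.ok:
                    reasons = "; ".join(
                        f"{c.name} ({c.message})" for c in report.failures)
                    raise LibraryError(
                        f"row {i} (token {entry.token!r}): {reasons}")
            self._entries[entry.token] = entry

    def __getitem__(self, token: str) -> ResidueEntry:
        try:
            return self._entries[token]
        except KeyError:
            raise KeyError(
                f"token {token!r} is not in the residue library; add it to a "
                "custom library table") from None

    def __contains__(self, token: str) -> bool:
        return token in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResidueLibrary):
            return NotImplemented
        return list(self._entries.items()) == list(other._entries.items())

    @property
    def tokens(self) -> list[str]:
        return list(self._entries)

    @property
    def entries(self) -> list[ResidueEntry]:
        return list(self._entries.values())

    def peptoid_analog(self, token: str) -> Optional[str]:
        """Token of the peptoid analog of a canonical residue, if present."""
        candidate = "{N%s}" % _THREE_LETTER.get(token, "")
        return candidate if candidate in self._entries else None

    def to_frame(self) -> pd.DataFrame:
        """Library as a table with the on-disk column layout."""
        return pd.DataFrame([
            {
                "Token": e.token,
                "Name": e.name,
                "SMILES (CHUCKLES)": e.chuckles_smiles,
                "Chirality": e.chirality,
                "Class": e.residue_class,
                "CAS": e.cas or "",
                "AlphaCIP": e.expected_alpha_cip or "none",
            }
            for e in self.entries
        ])

    def write(self, path: str | Path) -> Path:
        """Write the library to CSV or XLSX (by file extension)."""
        path = Path(path)
        frame = self.to_frame()
        if path.suffix.lower() in (".xlsx", ".xls"):
            frame.to_excel(path, index=False)
        else:
            frame.to_csv(path, index=False)
        return path


_THREE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "E": "Glu",
    "Q": "Gln", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys", "M": "Met",
    "F": "Phe", "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

# accepted (normalized) header spellings for the two required columns
_TOKEN_HEADERS = {"token", "symbol"}
_SMILES_HEADERS = {"smiles (chuckles)", "chuckles smiles", "chuckles_smiles",
                   "smiles", "chuckles"}
_OPTIONAL_HEADERS = {
    "name": "name",
    "chirality": "chirality",
    "class": "residue_class",
    "residue class": "residue_class",
    "residue_class": "residue_class",
    "cas": "cas",
    "alphacip": "expected_alpha_cip",
    "alpha cip": "expected_alpha_cip",
    "expected_alpha_cip": "expected_alpha_cip",
}


def _infer_chirality(token: str, smiles: str) -> str:
    if len(token) == 1:
        if token.isupper():
            return "L" if "@" in smiles else "achiral"
        return "D"
    return "achiral"


def _infer_class(token: str, smiles: str) -> str:
    has_map1 = re.search(r":1\]", smiles) is not None
    has_map2 = re.search(r":2\]", smiles) is not None
    if has_map2 and not has_map1:
        return "n_cap"
    if has_map1 and not has_map2:
        return "c_cap"
    if len(token) == 1:
        return "canonical" if token.isupper() else "d_isomer"
    return "ncaa"


def _rows_to_entries(frame: pd.DataFrame) -> list[ResidueEntry]:
    normalized = {str(c).strip().lower(): c for c in frame.columns}
    token_col = next((normalized[h] for h in _TOKEN_HEADERS if h in normalized), None)
    smiles_col = next((normalized[h] for h in _SMILES_HEADERS if h in normalized), None)
    if token_col is None or smiles_col is None:
        raise LibraryError(
            "library table must contain 'Token' and 'SMILES (CHUCKLES)' "
            f"columns; found {list(frame.columns)!r}")
    optional = {
        field_name: normalized[h]
        for h, field_name in _OPTIONAL_HEADERS.items() if h in normalized
    }

    def cell(row: pd.Series, col: Optional[str]) -> Optional[str]:
        if col is None:
            return None
        value = row[col]
        if pd.isna(value) or str(value).strip() in ("", "none"):
            return None
        return str(value).strip()

    entries: list[ResidueEntry] = []
    for i, (_, row) in enumerate(frame.iterrows()):
        token = cell(row, token_col)
        smiles = cell(row, smiles_col)
        if token is None or smiles is None:
            raise LibraryError(f"row {i}: missing token or SMILES")
        kwargs: dict = {}
        for field_name, col in optional.items():
            value = cell(row, col)
            if value is not None:
                kwargs[field_name] = value
        kwargs.setdefault("name", token)
        kwargs.setdefault("chirality", _infer_chirality(token, smiles))
        kwargs.setdefault("residue_class", _infer_class(token, smiles))
        entries.append(ResidueEntry(token=token, chuckles_smiles=smiles, **kwargs))
    return entries


def load_custom(table_path: str | Path) -> ResidueLibrary:
    """Load and validate a user residue table (CSV or XLSX, first sheet).

    Only ``Token`` and ``SMILES (CHUCKLES)`` columns are required; headers
    are matched case-insensitively after trimming.  Chirality, when absent,
    is inferred from token case (uppercase L, lowercase D, brace symbols
    achiral).  Row order is preserved.
    """
    path = Path(table_path)
    if not path.exists():
        raise LibraryError(f"library file not found: {path}")
    if path.suffix.lower() in (".xlsx", ".xls"):
        frame = pd.read_excel(path, sheet_name=0)
    else:
        frame = pd.read_csv(path)
    return ResidueLibrary(_rows_to_entries(frame), source="custom")


def load_default() -> ResidueLibrary:
    """Load the packaged 157-entry default library."""
    with resources.as_file(
            resources.files("chuckpep").joinpath("data/residues.csv")) as path:
        frame = pd.read_csv(path)
    try:
        library = ResidueLibrary(_rows_to_entries(frame), source="default")
    except LibraryError as exc:
        raise LibraryError(f"packaged default library is corrupted: {exc}") from exc
    if len(library) != 157:
        raise LibraryError(
            f"packaged default library has {len(library)} entries, expected 157")
    return library
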