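"""Molecule-level fingerprints and the sequence-level one-hot baseline.

Morgan (circular) fingerprints and MACCS structural keys are computed from
the assembled molecule with RDKit, so two assemblies of the same molecule —
whatever SMILES writing produced them — give identical bit vectors.  The
one-hot encoder is the sequence-level baseline: a ``max_len x |alphabet|``
indicator matrix, zero-padded past the sequence end and flattened.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .assembler import AssembledPeptide
from .tokenizer import TokenizedSequence

__all__ = [
    "FingerprintConfig",
    "FingerprintError",
    "morgan",
    "maccs",
    "MACCS_N_BITS",
    "onehot",
]


class FingerprintError(ValueError):
    """Raised for invalid fingerprint configurations or inputs."""


#: length of RDKit's MACCS key vector (166 keys plus the unused bit 0)
MACCS_N_BITS = 167


@dataclass(frozen=True)
class FingerprintConfig:
    """Configuration shared by the fingerprint front ends.

    ``n_bits`` and ``radius`` apply to Morgan fingerprints (defaults 2048
    and 2, the ECFP4-equivalent); ``alphabet`` applies to the one-hot
    encoder and must contain unique tokens.
    """

    kind: str = "morgan"  # "morgan" | "maccs" | "onehot"
    n_bits: int = 2048
    radius: int = 2
    alphabet: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.kind not in ("morgan", "maccs", "onehot"):
            raise FingerprintError(f"unknown fingerprint kind {self.kind!r}")
        if self.n_bits < 1:
            raise FingerprintError("n_bits must be >= 1")
        if self.radius < 1:
            raise FingerprintError("radius must be >= 1")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise FingerprintError("alphabet tokens must be unique")


def _mol_of(peptide: AssembledPeptide | Chem.Mol) -> Chem.Mol:
    return peptide.molecule if isinstance(peptide, AssembledPeptide) else peptide


def morgan(peptide: AssembledPeptide | Chem.Mol,
           config: FingerprintConfig | None = None) -> np.ndarray:
    """Morgan fingerprint as a 0/1 integer vector of length ``n_bits``."""
    config = config or FingerprintConfig(kind="morgan")
    generator = rdFingerprintGenerator.GetMorganGenerator(
        radius=config.radius, fpSize=config.n_bits)
    fingerprint = generator.GetFingerprint(_mol_of(peptide))
    return np.array(fingerprint, dtype=np.int8)


def maccs(peptide: AssembledPeptide | Chem.Mol) -> np.ndarray:
    """MACCS keys as a 0/1 integer vector of length :data:`MACCS_N_BITS`."""
    fingerprint = MACCSkeys.GenMACCSKeys(_mol_of(peptide))
    return np.array(fingerprint, dtype=np.int8)


def onehot(seq: TokenizedSequence | Sequence[str], alphabet: Sequence[str],
           max_len: int) -> np.ndarray:
    """Flattened ``max_len x |alphabet|`` one-hot encoding of a token list.

    Row ``t`` is the indicator of token ``t``; rows past the sequence end
    are zero padding.
    """
    tokens = seq.tokens if isinstance(seq, TokenizedSequence) else tuple(seq)
    if not alphabet:
        raise FingerprintError("one-hot alphabet must be nonempty")
    if len(set(alphabet)) != len(alphabet):
        raise FingerprintError("one-hot alphabet tokens must be unique")
    if len(tokens) > max_len:
        raise FingerprintError(
            f"sequence of length {len(tokens)} exceeds max_len={max_len}")
    index = {token: i for i, token in enumerate(alphabet)}
    matrix = np.zeros((max_len, len(alphabet)), dtype=np.int8)
    for t, token in enumerate(tokens):
        if token not in index:
            raise FingerprintError(
                f"token {token!r} at position {t} is outside the one-hot "
                "alphabet")
        matrix[t, index[token]] = 1
    return matrix.reshape(-1)
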