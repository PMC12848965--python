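"""L / D / peptoid analog sequence triples.

An L-peptide maps to its all-D analog by lowercasing every token (the
mirror image) and to its peptoid analog by replacing each residue with the
N-substituted-glycine unit carrying the same side chain (an isomerization:
the side chain moves from the alpha carbon to the backbone nitrogen, so all
three analogs share one molecular formula).  Proline and glycine have no
peptoid analog — proline's side chain is already fused to its nitrogen and
glycine has no side chain — so they are excluded from the random-sequence
alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .library import ResidueLibrary
from .tokenizer import split_tokens

__all__ = [
    "AnalogTriple",
    "AnalogError",
    "CANONICAL_TOKENS",
    "PEPTOID_ALPHABET",
    "random_l_sequences",
    "to_d",
    "to_peptoid",
    "analog_triples",
]


class AnalogError(ValueError):
    """Raised when a residue has no requested analog."""


CANONICAL_TOKENS = tuple("ARNDCEQGHILKMFPSTWYV")

#: canonical residues with peptoid analogs (all but proline and glycine)
PEPTOID_ALPHABET = tuple(t for t in CANONICAL_TOKENS if t not in ("P", "G"))


@dataclass(frozen=True)
class AnalogTriple:
    """Matched L-peptide, D-peptide and peptoid sequence strings."""

    l_seq: str
    d_seq: str
    peptoid_seq: str


def random_l_sequences(n: int, min_len: int = 5, max_len: int = 30,
                       seed: int | None = None) -> list[str]:
    """Draw ``n`` random all-L sequences over the 18-letter peptoid-capable
    alphabet, lengths uniform on ``[min_len, max_len]``.

    Deterministic for a fixed ``seed``.
    """
    if n <= 0:
        raise AnalogError("n must be positive")
    if min_len > max_len or min_len < 1:
        raise AnalogError("need 1 <= min_len <= max_len")
    rng = np.random.default_rng(seed)
    alphabet = np.array(PEPTOID_ALPHABET)
    sequences = []
    for length in rng.integers(min_len, max_len + 1, size=n):
        sequences.append("".join(rng.choice(alphabet, size=length)))
    return sequences


def to_d(seq: str) -> str:
    """All-D analog: lowercase every canonical one-letter token."""
    tokens = split_tokens(seq)
    for pos, token in enumerate(tokens):
        if token not in CANONICAL_TOKENS:
            raise AnalogError(
                f"token {token!r} at position {pos} is not a canonical "
                "uppercase residue")
    return seq.lower()


def to_peptoid(seq: str, library: ResidueLibrary) -> str:
    """Peptoid analog: replace each residue with its ``{N...}`` unit."""
    tokens = split_tokens(seq)
    out = []
    for pos, token in enumerate(tokens):
        analog = library.peptoid_analog(token)
        if analog is None:
            raise AnalogError(
                f"residue {token!r} at position {pos} has no peptoid analog "
                "in the library")
        out.append(analog)
    return "".join(out)


def analog_triples(sequences: list[str],
                   library: ResidueLibrary) -> list[AnalogTriple]:
    """Build the matched L/D/peptoid triple for each input L sequence."""
    return [
        AnalogTriple(seq, to_d(seq), to_peptoid(seq, library))
        for seq in sequences
    ]
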