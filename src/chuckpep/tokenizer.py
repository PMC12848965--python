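"""Parsing peptide sequence strings into residue tokens.

The sequence grammar is the one used throughout the residue library:
a ``{`` opens a multi-character token closed by the next ``}``; any other
character is a one-character token.  Tokenization is lossless — joining the
emitted tokens reproduces the input string exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .library import ResidueLibrary

__all__ = ["TokenizedSequence", "TokenizationError", "tokenize", "split_tokens"]


class TokenizationError(ValueError):
    """Raised for malformed sequences or tokens missing from the library."""


@dataclass(frozen=True)
class TokenizedSequence:
    """An ordered residue-token list plus topology.

    ``n_cap``/``c_cap`` record terminal cap tokens when present (they also
    appear in ``tokens``, at the first/last position); head-to-tail cyclic
    sequences cannot carry caps because both termini are consumed by the
    closing peptide bond.
    """

    tokens: tuple[str, ...]
    topology: str = "linear"  # "linear" | "head_to_tail_cyclic"
    n_cap: Optional[str] = None
    c_cap: Optional[str] = None

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "head_to_tail_cyclic"):
            raise TokenizationError(f"unknown topology {self.topology!r}")
        if not self.tokens:
            raise TokenizationError("token list must be nonempty")

    @property
    def cyclic(self) -> bool:
        return self.topology == "head_to_tail_cyclic"

    def __len__(self) -> int:
        return len(self.tokens)

    def __str__(self) -> str:
        return "".join(self.tokens)


def split_tokens(sequence: str) -> list[str]:
    """Split a sequence string into tokens without consulting a library."""
    tokens: list[str] = []
    i = 0
    while i < len(sequence):
        char = sequence[i]
        if char == "{":
            end = sequence.find("}", i + 1)
            if end == -1:
                raise TokenizationError(
                    f"unbalanced brace at position {i} in {sequence!r}")
            body = sequence[i + 1:end]
            if not body:
                raise TokenizationError(
                    f"empty braces at position {i} in {sequence!r}")
            if "{" in body:
                raise TokenizationError(
                    f"nested brace inside token at position {i} in {sequence!r}")
            tokens.append(sequence[i:end + 1])
            i = end + 1
        elif char == "}":
            raise TokenizationError(
                f"unmatched closing brace at position {i} in {sequence!r}")
        elif char.isspace():
            raise TokenizationError(
                f"whitespace at position {i} in {sequence!r}; sequences must "
                "not contain whitespace")
        else:
            tokens.append(char)
            i += 1
    return tokens


def tokenize(sequence: str, library: ResidueLibrary,
             cyclic: bool = False) -> TokenizedSequence:
    """Parse ``sequence`` against ``library``.

    Cap tokens (``n_cap``/``c_cap`` residue classes) are only legal at the
    first/last position of a linear sequence; cyclic sequences must contain
    at least two residues and no caps.
    """
    if not sequence:
        raise TokenizationError("sequence must be nonempty")
    tokens = split_tokens(sequence)

    for pos, token in enumerate(tokens):
        if token not in library:
            raise TokenizationError(
                f"token {token!r} at position {pos} is not in the residue "
                "library")

    n_cap = c_cap = None
    last = len(tokens) - 1
    for pos, token in enumerate(tokens):
        rclass = library[token].residue_class
        if rclass == "n_cap":
            if pos != 0:
                raise TokenizationError(
                    f"N-terminal cap {token!r} at interior position {pos}")
            n_cap = token
        elif rclass == "c_cap":
            if pos != last:
                raise TokenizationError(
                    f"C-terminal cap {token!r} at interior position {pos}")
            c_cap = token

    if cyclic:
        if len(tokens) < 2:
            raise TokenizationError(
                "head-to-tail cyclic sequences need at least 2 residues")
        if n_cap or c_cap:
            raise TokenizationError(
                "cyclic sequences cannot carry terminal caps")
        return TokenizedSequence(tuple(tokens), "head_to_tail_cyclic")
    return TokenizedSequence(tuple(tokens), "linear", n_cap=n_cap, c_cap=c_cap)
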