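import re
from collections import Counter

import pytest
from rdkit import Chem

from chuckpep import load_default


@pytest.fixture(scope="session")
def library():
    return load_default()


def formula_counts(formula: str) -> Counter:
    """Element counts of a Hill-order molecular formula, charge ignored."""
    counts = Counter()
    for element, number in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if element:
            counts[element] += int(number or 1)
    return Counter({k: v for k, v in counts.items() if v})


def mirror_canonical(smiles: str) -> str:
    """Canonical SMILES of the mirror image (every tetrahedral tag flipped)."""
    canonical = Chem.MolToSmiles(Chem.MolFromSmiles(smiles))
    inverted = canonical.replace("@@", "\0").replace("@", "@@").replace("\0", "@")
    return Chem.MolToSmiles(Chem.MolFromSmiles(inverted))
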