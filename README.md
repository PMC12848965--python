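# chuckpep

Peptide drug candidates increasingly contain chemistry that one-letter
sequence tools cannot express: D-amino acids, noncanonical side chains,
N-substituted-glycine (peptoid) backbones, terminal caps, PEG spacers and
head-to-tail macrocycles. Standard sequence descriptors treat every such
residue as an opaque new symbol — or cannot represent it at all — which
blocks machine-learning work on exactly the molecules that matter most in
modern peptide design.

`chuckpep` converts sequence strings for these nonstandard peptides into
atom-level, ML-ready representations: atom-mapped SMILES, sanitized RDKit
molecules, molecular graphs with fixed-width feature matrices, Morgan and
MACCS fingerprints, and a one-hot sequence baseline. It is aimed at
computational chemists and ML practitioners building property-prediction or
generative models over nonstandard peptide libraries.

## How it works

Every residue is stored in **CHUCKLES** form: a SMILES string whose atoms
are written in the order *N-terminus → α-carbon → C-terminus*, with atom
map 1 on the backbone nitrogen (a bracket atom with an explicit hydrogen
count, e.g. `[NH2:1]`) and map 2 on the carbonyl carbon of the terminal
`(=O)O` tail. Peptide-bond formation is then a condensation realized as two
local string edits — drop the C-terminal hydroxyl `O` of the upstream
residue and decrement the bracket H count of the downstream nitrogen
(`[NH2:1] → [NH:1]`) — after which the fragments simply concatenate:

```
G + G:  [NH2:1]C[C:2](=O)O  +  [NH2:1]C[C:2](=O)O
   ->   [NH2:1]C[C:2](=O)[NH:1]C[C:2](=O)O        (glycylglycine)
```

Head-to-tail macrocycles additionally apply both edits at the chain ends and
close the ring with a two-digit `%NN` ring-closure label, which cannot
collide with single-digit ring labels inside side chains. The retained atom
maps identify every backbone junction, so the bonds joining a map-2 carbon
to a map-1 nitrogen are exactly the peptide bonds; cutting them partitions
the atoms into residues, giving the residue-membership vector that
hierarchical (atom → residue) graph models need.

Tokens follow the library convention: uppercase letters for L residues,
lowercase for their D isomers, and `{...}` symbols (e.g. `{Aib}`, `{NPhe}`,
`{ac}`, `{PEG2}`) for everything else. The packaged default library has 157
validated entries; any CSV/XLSX table with `Token` and `SMILES (CHUCKLES)`
columns can extend or replace it.

Graphs use a fixed layout: node features are *n*<sub>atoms</sub> × 24
(element, degree, hydrogen-count one-hots, charge, aromaticity, ring
membership, hybridization), optionally 27 with a one-hot CIP
stereodescriptor block (S / R / not defined); edge features are
*n*<sub>bonds</sub> × 16 (bond type, conjugation, ring context, stereo,
backbone/intra-residue/rotatable flags); the adjacency array is 2 × *E*
with every bond listed in both directions by default. Per-residue chirality
flags ([1,0] L, [0,1] D, [0,0] achiral) ride along for residue-level
message passing.

## Worked example

```python
import chuckpep

library = chuckpep.load_default()
seq = chuckpep.tokenize("{ac}A{Aib}kW", library)   # acetyl-Ala-Aib-D-Lys-Trp
pep = chuckpep.assemble(seq, library)
print(pep.canonical_smiles)
print(pep.formula, pep.peptide_bonds)
graph = chuckpep.build_graph(pep, include_chirality=True)
print(graph.node_features.shape, graph.edge_features.shape, graph.adjacency.shape)
print(graph.residue_flags.tolist())
```

prints

```
CC(=O)N[C@@H](C)C(=O)NC(C)(C)C(=O)N[C@H](CCCCN)C(=O)N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O
C26H38N6O6 ((1, 3), (6, 8), (12, 14), (21, 23))
(38, 27) (78, 16) (2, 78)
[[0, 0], [1, 0], [0, 0], [0, 1], [1, 0]]
```

The canonical SMILES is the acetyl-capped tetrapeptide with the D-lysine
stereocenter inverted; the four `(carbonyl C, amide N)` atom-index pairs
are the backbone amides; the graph has 38 heavy atoms with 27 features each
(24 structural + 3 chirality columns) and 78 directed edges; the residue
flags mark cap/achiral ([0,0]), L ([1,0]) and D ([0,1]) units in sequence
order. A head-to-tail macrocycle needs only `cyclic=True`:

```python
cyc = chuckpep.assemble(chuckpep.tokenize("GG", library, cyclic=True), library)
print(cyc.smiles, "->", cyc.canonical_smiles)
# [NH:1]%99C[C:2](=O)[NH:1]C[C:2]%99(=O) -> O=C1CNC(=O)CN1
```

— cyclo(Gly-Gly), the 2,5-diketopiperazine.

The same operations are available from the shell for batch CSV inputs:

```bash
chuckpep convert sequences.csv out/            # atom-mapped + canonical SMILES
chuckpep featurize sequences.csv out/ --chirality
chuckpep fingerprint sequences.csv out/ --kind morgan --bits 2048
chuckpep validate-library my_residues.xlsx
chuckpep make-analogs triples.csv --n 100 --seed 1
```

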