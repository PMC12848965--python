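# Methods

## The CHUCKLES monomer convention

A canonical SMILES orders atoms for string uniqueness, not for chemistry:
the N-terminus, α-carbon and C-terminus of an amino acid can land anywhere
in the string, so two monomer strings cannot be joined textually. The
CHUCKLES convention fixes the atom order — backbone nitrogen first, then
the α-carbon (with the side chain as a branch), then the carbonyl carbon
and its `(=O)O` tail — at the cost of sometimes flipping the tetrahedral
tag at the α-carbon relative to the canonical writing (the `@`/`@@`
descriptor is defined by written neighbor order, so reordering the string
must adjust it to preserve the molecule).

Each library entry additionally carries atom map 1 on the backbone
nitrogen and map 2 on the carbonyl carbon. Maps survive parsing, so after
assembly the backbone junctions remain identifiable in the molecule object
itself, not just in the string.

### Library contract

Per residue class:

| class | map 1 (N, first atom) | map 2 (carbonyl C) | `(=O)O` tail |
|---|---|---|---|
| canonical, d_isomer, ncaa, peptoid, polymer | required | required | required |
| n_cap (e.g. acetyl) | absent | required | required |
| c_cap (e.g. amide) | required | absent | absent |

The backbone nitrogen is always written as a bracket atom with an explicit
hydrogen count (`[NH2:1]`, `[NH:1]` for proline/peptoids, `[NH3:1]` for the
free amide cap). Bracket atoms carry no implicit hydrogens, so "remove one
N-terminal hydrogen" is implementable as a deterministic count decrement
rather than a graph edit; an entry whose count is already zero (a secondary
amine already bonded twice) correctly fails to accept a bond.

Validation recomputes, rather than trusts, the stereochemistry: each chiral
entry stores the expected CIP descriptor of its α-carbon, and the check
recomputes it with RDKit's modern CIP labeler (`rdCIPLabeler`). Storing the
code per entry handles the cysteine-type inversion (L-Cys is *R* because
sulfur outranks the carboxyl oxygen) without any hard-coded exception
list; the legacy perception routine gets this case wrong, which is why the
modern labeler is used throughout (validation and the graph chirality
columns).

### Default library composition

The packaged table (157 entries) is generated by
`scripts/build_default_library.py` from curated side-chain definitions:

* 20 canonical L residues — each checked against `Chem.MolFromSequence`;
* 19 D isomers (glycine is achiral) — derived by inverting every
  tetrahedral tag of the L string, and checked to be exact enantiomers
  with identical formulas;
* 18 peptoid analogs `{NXxx}` — the side chain moved from the α-carbon to
  the nitrogen (an isomerization, so the formula is preserved by
  construction); proline (side chain already fused to N) and glycine (no
  side chain) have none;
* 40 curated noncanonical residues (homologated and substituted side
  chains, ring-contracted/expanded prolines, β/γ/δ/ε-amino acids,
  sarcosine, Aib) plus the 34 D mirror images of the chiral ones;
* 18 N-methylated canonical residues `{meX}`;
* acetyl `{ac}` and amide `{am}` end caps;
* 6 amino-PEG-acid spacers `{PEG1}`–`{PEG6}`.

Derived families (D, peptoid, N-methyl) are generated programmatically so
that related entries cannot drift apart. Entry identities beyond the class
structure are a curation choice of this package.

## Assembly

Linear assembly edits each residue string locally — every residue but the
last loses the final `O` of its `(=O)O` tail, every residue but the first
has its N-bracket H count decremented — and concatenates. The α-carbon
stereo tags need no adjustment: the written neighbor order of the α-carbon
is unchanged by either edit, since bonding happens at the preceding
carbonyl carbon and the following nitrogen.

Head-to-tail cyclization applies both edits at the free ends too, then
inserts an unused ring-closure label directly after the first residue's
nitrogen bracket and directly after the last residue's map-2 carbon bracket
(before its `(=O)` branch). Labels are searched in two-digit `%99 … %10`
form, descending: side chains use single-digit ring labels, so the first
probe virtually always succeeds, and the scan guards against pathological
custom libraries. Caps are rejected on cycles (both termini are consumed by
the closing bond), and a 1-residue cycle is an error rather than a lactam
guess.

After parsing, stereo perception is re-run on the assembled molecule.
Original maps 1/2 are retained on every residue's termini rather than
renumbered; residue membership is computed structurally by cutting the
(map-2 C)–(map-1 N) bonds and numbering the resulting fragments in atom
order, which equals sequence order because RDKit preserves SMILES writing
order. This keeps the mapping correct even if a future caller renumbers
maps.

Error handling names the offending token and position: unknown tokens at
tokenization, interior caps at tokenization (and again, structurally, at
assembly for hand-built token lists), and the first failing junction when a
concatenation fails to parse.

## Graph featurization

Node features (24 columns): element one-hot over {C, N, O, S, F, Cl, Br,
P, Se} + *other* (10), heavy-atom degree one-hot {1, 2, 3, 4, other} (5),
total-hydrogen one-hot {0, 1, 2, 3} (4), formal charge as a signed scalar
(1), aromatic flag (1), ring flag (1), hybridization one-hot {sp², sp³}
(2; sp and everything else map to zeros). This covers the valence space of
peptide chemistry; the exact layout is recorded in the export metadata so
downstream models are never coupled to positional guesses. By default an
element outside the vocabulary raises an error directing the user to a
custom library (`strict_elements=False` downgrades it to the *other*
column).

Optional chirality columns (3): one-hot CIP descriptor S / R / not-defined
per atom, computed with the modern CIP labeler after stereo perception.
Unassignable or undefined centers fall in the third column. L- and
D-peptides therefore share identical 24-column blocks and have their S and
R columns exactly swapped — the property that makes enantiomers
distinguishable to a 2-D graph model.

Edge features (16 columns): bond type one-hot {single, double, triple,
aromatic} (4), conjugation (1), ring membership (1), double-bond stereo
one-hot {none, Z, E, other} (4), backbone peptide-bond flag (1; set exactly
for the assembler's recorded amides), intra-residue flag (1), rotatable
flag (1; RDKit's rotatable-bond SMARTS), smallest-ring-size one-hot {5, 6,
other} (3; all zero off-ring, so this block is intentionally not a proper
one-hot).

The adjacency array is 2 × *E*. `directed_duplication=True` (default)
lists each bond in both directions with duplicated edge rows, the layout
message-passing frameworks consume; `False` gives one row per bond.
Feature matrices are dense float64; adjacency and residue vectors are
integer. Graph export uses NumPy `.npz` with a JSON metadata entry naming
every column, so files are loadable without this package and round-trip
bit-identically.

## Fingerprints and baseline

Morgan fingerprints default to radius 2 (the ECFP4 equivalent) and 2048
bits, both configurable; MACCS keys use RDKit's standard 167-bit vector,
and the length is exported in metadata rather than assumed by consumers.
Both are functions of the molecule: assemblies that canonicalize equally
fingerprint equally. Default Morgan invariants ignore stereocenters, so
enantiomeric peptides hash identically — a documented, regression-tested
behavior; stereo-aware modeling should use the graph chirality columns.
The one-hot encoder is the deliberately weak sequence-level baseline: a
padded `max_len × |alphabet|` indicator matrix, flattened.

## Analog triples

`random_l_sequences` draws lengths uniformly on [5, 30] and residues
uniformly over the 18 canonical letters excluding proline and glycine
(no peptoid analogs exist for them), with a seeded NumPy generator; the
defaults mirror the 100-sequence random-translation experiment this
feature supports. Uniform distributions are the neutral choice absent a
stated alternative. `to_d` lowercases (mirror image), `to_peptoid`
substitutes `{NXxx}` tokens (constitutional isomer); each triple shares
one molecular formula, L/D are enantiomers, and the peptoid differs from
both as a constitutional isomer.

## Batch runner

The CLI isolates faults per row: a bad sequence is recorded in
`report.json` with its row index and error and does not abort the batch;
the exit status is nonzero iff any row failed. Outputs are plain CSV plus
one `.npz` per graph with an index CSV. For fixed inputs and seeds, reruns
are byte-identical.

## Problem sizes and numerical choices

The test suite and the acceptance script use 200 random canonical
sequences (lengths 1–10) for the independent-converter check, 200
full-library draws (linear and cyclic alternating) for formula
conservation, 50 L/D pairs for mirror symmetry, 50 randomized partitions,
and 100 analog triples at lengths 5–30 — sizes at which every check is
exhaustive enough to catch systematic errors while the whole suite runs in
seconds on one CPU. Canonical-SMILES string equality (maps stripped) is
the molecule-identity oracle throughout; no numerical tolerances are
involved anywhere in the pipeline.

## Known limitations

* Only head-to-tail cyclization is modeled; disulfide, side-chain-to-side-
  chain and side-chain-to-terminus (stapled, lanthipeptide) topologies are
  out of scope.
* No 3-D: conformers, geometry-dependent features and GPU batch
  construction are not provided.
* The synthetic inputs used by the tests (uniform random sequences over
  the library) probe correctness of the representation, not biological
  realism; passing them says nothing about predictive performance on real
  peptide datasets.
* Double-bond stereo inside side chains is encoded if present in the
  library entry but no entry in the default library currently defines any.
* The peptoid-analog token map covers the canonical side chains; custom
  NCAAs need their own `{N...}` entries before `to_peptoid` can translate
  them.
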