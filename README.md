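# molkit

A compact, tested cheminformatics toolkit for small-molecule work:
molecular graphs with relative stereochemistry, declarative atom typing,
ring perception, pluggable aromaticity with mandatory kekulization of
aromatic SMILES, molecular formulas with accurate-mass decomposition,
substructure matching, and hashed/key fingerprints — plus a streaming
command-line interface over SMILES and SDF files.

It is aimed at people who need the algorithmic core of a cheminformatics
library — metabolomics formula annotation, substructure screening,
canonical identifiers, fingerprint similarity — in pure Python, with
every algorithm small enough to read.

## What is inside

- **Molecular graph** (`molkit.model`): indexed atoms/bonds plus
  `StereoElement(type, focus, carriers, configuration)` records.  Only the
  type and focus are absolute; reordering the carriers by an odd
  permutation while flipping the configuration label describes the same
  geometry, so equality of stereo descriptors reduces to a permutation
  parity: two descriptors match iff their configurations agree after
  multiplying by the parity of the carrier permutation.
- **Atom typing** (`molkit.typing`): a packaged table of atom types
  (element, hybridization, charge, lone pairs, bond-order multiset);
  perception is a pure lookup on each atom's environment and doubles as a
  per-atom validator.  Implicit hydrogens fill to the smallest legal
  valence ≥ the bond-order sum.
- **Rings** (`molkit.rings`): linear ring-bond marking (bridge finding),
  circuit rank `|E| − |V| + components`, SSSR as a minimum cycle basis
  (Horton candidates + greedy GF(2) independence, deterministic
  tie-break), and all simple cycles up to size 12 with a
  machine-independent escape counter instead of a timeout.
- **Aromaticity** (`molkit.aromaticity`): per-atom electron donation in
  {−1, 0, 1, 2} under three models (`daylight_like`, `cdk_like`,
  `cdk_exocyclic`), Hückel's 4n+2 over a chosen cycle set (minimum cycle
  basis or all rings ≤ 12), and kekulization via a maximum (blossom)
  matching — inputs whose aromatic claim cannot be met are rejected.
- **SMILES** (`molkit.smiles`): full reader (bracket atoms, charges,
  isotopes, `%nn` ring closures, directional bonds, `@`/`@@`) with
  mandatory kekulization and valence checking, and a writer with
  `generic`, `isomeric`, `unique`, and `absolute` flavours.  `unique` and
  `absolute` use refinement-based canonical ranks and are invariant under
  input atom renumbering.
- **Formulas** (`molkit.formula`): monoisotopic mass (electron-corrected
  for charge), isotope patterns by convolution, RDBE filtering, and mass
  decomposition: a Round Robin integer-knapsack solver over an extended
  residue table for ordinary queries, with an exhaustive enumeration
  fallback for masses above 400,000 Da or windows wider than 1 Da.  Both
  return identical, mass-sorted formula lists.
- **Matching & fingerprints** (`molkit.match`, `molkit.fingerprints`):
  immutable compiled patterns with lazy match iteration and stereo-aware
  comparison; hashed path (depth 0–7), ECFP-style circular (bit folded to
  1024 / counts unfolded), and 166-key MACCS-like fingerprints with
  Tanimoto similarity.
- **I/O & CLI** (`molkit.io`, `molkit.cli`): streaming molfile/SDF V2000
  and SMILES-file readers/writers, chemfp-compatible FPS output, and a
  `molkit` command with `countheavy`, `rings`, `cansmi`, `convert`,
  `fpgen`, `massdecomp` subcommands.

## Worked example

```python
>>> from molkit.smiles import parse, write
>>> from molkit.rings import all_rings, sssr
>>> from molkit.formula import formula_of, exact_mass, DecompositionQuery, decompose

>>> indole = parse("c1ccc2[nH]ccc2c1")     # kekulized on read
>>> sorted(r.size for r in all_rings(indole).rings)
[5, 6, 9]
>>> [r.size for r in sssr(indole)]
[5, 6]
>>> write(indole, "unique")
'C1=CC=C2C(=C1)C=CN2'
>>> f = formula_of(indole); str(f), round(exact_mass(f), 6)
('C8H7N', 117.057849)
```

The all-rings search sees three rings: the pyrrole (5), the benzene (6),
and their fused 9-membered envelope; the SSSR keeps only the two
independent small rings (circuit rank 2).  Decomposing indole's own
monoisotopic mass at ±0.001 Da over C,H,N,O,P,S recovers it among the
five formulas in that window, sorted by mass:

```python
>>> q = DecompositionQuery(117.057849, 0.001, {s: (0, 100) for s in "CHNOPS"})
>>> for f in decompose(q): print(f, round(exact_mass(f), 6))
H11N3O2S 117.057198
C8H7N 117.057849
C4H10N2P 117.05816
H13N3P2 117.058471
C2H13O3S 117.058541
```

The same tasks from the shell:

```sh
$ echo 'c1ccc2[nH]ccc2c1 indole' | molkit rings --all
5,6,9
$ molkit massdecomp -m 117.057849 -t 0.001
H11N3O2S 117.057198
C8H7N 117.057849
...
$ molkit fpgen --type circ -i molecules.smi -o molecules.fps
```

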