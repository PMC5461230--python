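# Methods

This note records the models and procedures molkit implements, the
numerical and design choices behind them, and what the tests do and do
not establish.

## Molecular graph and relative stereochemistry

A molecule is an indexed atom/bond graph with a symmetric adjacency.
Stereochemistry is stored as `StereoElement(type, focus, carriers,
configuration)` records.  The representation is deliberately *relative*:
for a tetrahedral centre, the four carriers may be listed in any order,
and an odd permutation of the carriers combined with flipping the
configuration label (1 = anticlockwise, 2 = clockwise, viewed from the
first carrier) denotes the same geometry.  Two descriptors with the same
focus are therefore equivalent iff their configurations agree after
multiplying by the permutation parity of the carrier mapping.  When a
stereocentre's hydrogen is suppressed, the focus index is reused inside
the carrier list as a positional placeholder; parity computation treats
each occurrence as a distinct item resolved by position.  Exhaustive
enumeration of all 4!×2 representations of one centre yields exactly two
classes of 24, which the tests assert.

Double-bond stereo uses two carriers (one reference neighbour per end)
with configurations together/opposite.  Extended tetrahedral (allene)
descriptors are representable — carriers are the two neighbours of each
terminal, terminals ordered by atom index — and obey the same parity
algebra, but the SMILES layer currently emits only tetrahedral and
double-bond elements.  Square-planar, trigonal-bipyramidal and
octahedral types are reserved enum values; every algorithm rejects them.

## Atom typing

Atom types are a declarative packaged table
(`molkit/data/atom_types.tsv`): one record per (element, charge,
bond-order multiset), carrying hybridization and lone-pair counts, with
implicit hydrogens counted as single bonds.  Perception is an exact
lookup on the atom's local environment, so it is trivially
order-independent and doubles as validation: an atom whose environment
matches no record produces a diagnostic (`atom <i> (<symbol>):
<message>`).  Coverage is the common-organic subset (H, B, C, N, O, P,
S, halogens; charges −1/0/+1; hypervalent S and P entries such as
sulfoxide/sulfone/phosphate are tagged with hybridization `unset` so the
pinned consistency rule — sp3 ⇒ no π bonds, sp2 ⇒ one double, sp1 ⇒ one
triple or two doubles — holds across the table).  Lone-pair counts for
charged species follow octet bookkeeping.

Implicit hydrogen inference uses a standard valence table (H 1; B 3;
C 4; N 3, N⁺ 4, N⁻ 2; O 2, O⁺ 3, O⁻ 1; P 3,5; S 2,4,6; halogens 1,
halide anions 0): each unset atom receives `smallest legal valence ≥
bond-order sum` hydrogens; an atom exceeding every legal valence raises
a typing error naming the atom.  Hybridization-only perception (double
bond positions left undefined) is not supported: inputs must carry bond
orders or aromatic flags.  Radicals are out of scope.

## Ring perception

*Marking.* A bond lies on a ring iff it is not a bridge; bridges come
from a linear DFS (networkx), so marking is O(|V|+|E|).

*SSSR.* The smallest set of smallest rings is a minimum cycle basis:
exactly `circuit_rank = |E| − |V| + c` rings whose total size is
minimal.  Candidates are generated Horton-style (per vertex, BFS
shortest-path trees; per edge, the candidate cycle through the vertex)
and admitted greedily, smallest first, under GF(2) linear independence
of edge-incidence vectors (big-integer XOR elimination).  Because the
SSSR is not unique, ties between equal-size candidates are broken by
lexicographic atom order, and each ring is canonicalized (smallest atom
first, smaller neighbour second), pinning a deterministic output.  On
every fixture molecule the basis size equals the circuit rank, and on
molecules ≤ 10 atoms its weight equals networkx's independent
minimum-cycle-basis weight.

*All rings.* All simple cycles of size ≤ 12 (default) are enumerated by
a DFS rooted at each cycle's smallest vertex, with orientation fixed so
each cycle is reported once.  The search counts edges explored; when the
counter exceeds the escape threshold (default 1,000,000, chosen so the
fixture suite never truncates) the result is returned truncated — a
machine-independent alternative to a wall-clock timeout.  Already-found
rings remain valid in a truncated result.

## Aromaticity and kekulization

Aromaticity is a model choice with two axes: an electron-donation rule
and a candidate cycle set.  The donation rule maps each atom to −1
("cannot be aromatic") or 0/1/2 π electrons:

- in-ring atom of {B, C, N, O, P, S, Se} only; triple bonds and multiple
  double bonds disqualify;
- one double bond to another ring atom → 1 (this covers fusion-bond
  doubles, needed for the naphthalene/azulene envelopes);
- no double bond: pyrrole-type N/P (3 connections) → 2, O/S → 2,
  anionic C → 2, cationic C → 0, boron → 0;
- one exocyclic double bond: 0 under `daylight_like` and `cdk_like`; the
  `cdk_exocyclic` variant donates 0 only for C=O/C=S and −1 otherwise.
  The split between the two CDK-flavoured models is an interpretation —
  the three models differ only on exocyclic-carbonyl ring systems, and
  targeted tests cover exactly those.

Charged-atom counts follow the OpenSMILES table (cyclopentadienyl C⁻ →
2, tropylium C⁺ → 0).  A candidate cycle is aromatic iff no member is −1
and the donation sum is 4n+2 (n ≥ 0); flags are iterated to closure over
fused systems.  The cycle set is either the minimum cycle basis (`mcb`)
or all rings ≤ 12 (`all_bounded`); azulene is the canonical case where
only the 10-membered envelope (sum 10) makes the molecule aromatic, so
`mcb ⊆ all_bounded` always holds and is property-tested.

Kekulization assigns orders to aromatic (unset-order) bonds.  Each
aromatic atom that must realize its donated electron as a π bond —
carbons, pyridine-type N, protonated/quaternized aromatic N⁺, cationic
O⁺/S⁺, but not lone-pair donors — enters a matching problem over the
aromatic bonds; a maximum (blossom, not bipartite) matching must be
perfect on that set, matched bonds become double, the rest single.
After assignment, hydrogens are inferred and the claimed aromatic atoms
are re-perceived under `daylight_like`/`all_bounded`; any atom whose
claim no Hückel cycle supports makes the whole input invalid.  This is
why `c1ccc1` is rejected even though the 4-cycle has a perfect matching:
the kekulized cyclobutadiene fails 4n+2.

## SMILES

The reader covers the organic subset, bracket atoms (isotope, symbol,
`@`/`@@`, H count, ±n charge, atom class), bonds `- = # : / \`,
branches, ring closures incl. `%nn`, and dot-disconnection.  Aromatic
input is always kekulized as above; bracket atoms are then
valence-checked (so `[CH5]` and radical-like `[CH3]` are rejected;
elements outside the valence table are exempt).  Ring-closure order
conflicts are errors, including an order symbol present only at the
closing digit.  Tetrahedral carriers are collected in OpenSMILES
neighbour order (preceding atom, bracket hydrogen as placeholder, ring
closures in digit order, then branch atoms); directional bonds around
each explicitly written double bond are normalized into together/opposite
descriptors and the raw symbols discarded.  An empty string parses to an
empty molecule.  CXSMILES layers are not interpreted; the line-oriented
reader keeps anything after the first whitespace — including a `|...|`
block — as the opaque title.

The writer supports `generic` (connectivity only), `isomeric` (stereo +
isotopes), `unique` (canonical, stereo/isotopes stripped) and `absolute`
(canonical with stereo), plus an aromatic-output mode once perception
has run.  Canonical ranks come from iterated refinement over (element,
charge, degree, ring membership, attached hydrogens) with
neighbour-rank multisets; remaining ties are individualized one atom at
a time, choosing the atom with the smallest rooted graph signature, so
the final discrete order is independent of input numbering (atoms tied
even then are automorphic in molecular graphs, where any choice yields
the same string; pathological regular graphs outside chemical space are
not guaranteed).  Emission is a two-pass DFS (plan tree + back edges,
then write), with ring digits managed by a free list.  Stereo tokens are
computed from the written neighbour order by the same parity algebra the
reader uses; directional bond symbols are solved as a ±1 constraint
system anchored to canonical ranks — both the anchoring and the
processing order are rank-based so that `unique`/`absolute` output is
renumbering-invariant, and an unsatisfiable constraint system (stereo
that cannot be expressed consistently) is an error rather than a silent
mis-encoding.  No attempt is made to match any other toolkit's canonical
string byte-for-byte; the contract is self-consistency, which the tests
check with RDKit as an independent semantic oracle (my string parsed by
RDKit must canonicalize to the same molecule as the input).

## Formulas and mass decomposition

Exact mass is the sum of each element's most abundant isotope mass
(packaged table, six decimals) minus 0.000549 Da per unit positive
charge.  Isotope patterns are built by per-element convolution
(exponentiation by squaring), merging peaks within 1e−5 Da and pruning
below 1e−12 absolute abundance before normalizing the tallest peak to 1.

Decomposition answers "which element-count vectors have mass within
[m−t, m+t]".  The Round Robin path discretizes at 1e−5 Da per integer
unit with floor weights and builds an extended residue table: for the
k lightest elements, the minimal achievable integer mass in each residue
class modulo the lightest element's weight (~100,782 entries per row for
H — a few hundred kilobytes as Python floats, and bounded by #elements ×
anchor weight entries as required).  The table is filled with the
round-robin update along gcd cycles starting at each cycle's minimum.
Backtracking then runs once over the whole integer target window,
choosing counts heaviest-element first and pruning any branch whose
remaining interval is unreachable per the table (an exact bound for
unbounded counts, hence lossless under per-element caps).  Floor weights
only under-estimate — by less than one unit per atom — so the window's
lower edge is slacked by the maximal atom count and a final real-valued
mass filter restores exactness; results are sorted by ascending exact
mass, ties by Hill-order counts.  Enumeration is a bounded DFS over real
masses with the same output contract and serves queries outside the
Round Robin operating range (mass > 400,000 Da or window span > 1 Da).
Cross-algorithm equality on hundreds of random CHNOPS queries, and
equality of both with an exhaustive bounded-count oracle, are the
module's central tests.  Boundary inclusion is a closed interval; the
RDBE filter uses `1 + Σ nᵢ(vᵢ−2)/2` with standard valences (P 3, S 2).

## Matching and fingerprints

A `Pattern` is compiled once (from a molecule, optionally with per-atom
predicate overrides: element, aromatic, ring membership, charge, degree,
H count, wildcard) and is immutable; compilation records which target
invariants the predicates need (ring flags, aromaticity) and only those
are computed per target.  Matching is VF2-style backtracking, candidates
ordered rarest-predicate-first, yielded lazily so the k-th match does no
work beyond itself (asserted with a node-visit counter).  Query stereo,
when enforced, is checked per complete mapping by translating each query
descriptor through the mapping and comparing with the target descriptor
under permutation parity; a query descriptor with no target counterpart
fails the mapping.  Aliphatic query bonds match on kekulé order without
constraining aromaticity — SMARTS-style "single-or-aromatic" semantics
are intentionally not reproduced.

All fingerprints hash with 32-bit FNV-1a over integer invariant streams,
fixed seed, for bit-reproducibility.  The path fingerprint enumerates
simple paths of 0–7 bonds; the invariant alphabet is (element, charge,
aromatic flag) per atom and (order | aromatic) per bond — deliberately
degree- and H-free so that the bits of any substructure are a subset of
its superstructure's bits (the screening property, property-tested on
nested pairs).  Each path is read in its lexicographically smaller
direction and folded modulo 1024.  The circular fingerprint is
ECFP-like: initial invariant (element, degree, total H, charge, ring,
aromatic), then radius rounds (default 2) of sorted
(bond-invariant, neighbour-hash) combination; features are deduplicated
on (hash, covered atom set); the bit form folds to 1024, the count form
keeps unfolded 32-bit indices with occurrence counts.  The MACCS-like
fingerprint is always 166 bits wide; 51 keys are expressed in the
predicate language (element counts, H-count predicates, two-atom
fragments, ring sizes, heteroatom rings, aromatic atoms/rings, charge,
isotope, component count, heteroatom-heteroatom bonds) and the rest are
permanently 0 and marked unsupported in `molkit/data/maccs_keys.tsv` —
similarity values are therefore not comparable with other toolkits'
MACCS implementations, only the width and set-monotone behaviour are
contractual.  Tanimoto is |A∩B|/|A∪B| with 1.0 for two empty prints.

## I/O

Molfile V2000: fixed-column reader (symbols, bond orders 1–3; order 4 is
aromatic and triggers kekulization; orders 5–8 are CTfile query features
and rejected; V3000 rejected), `M  CHG`/`M  ISO` properties; legacy
atom-block charge columns are ignored on read and never written.  The
writer emits zero coordinates, 1-based numbering, and charges only as
`M  CHG`.  SDF reading is streaming (constant memory in record count);
a record missing its `$$$$` at EOF is accepted with a warning; a
tolerant variant skips unparsable records, mirroring skip-and-continue
batch processing.  FPS output is chemfp-style: `#FPS1`, `#num_bits`,
`#type` headers and little-endian hex per record (bit 0 = LSB of byte 0).

## Fixture generator

`molkit.fixtures.generate_fixtures` produces deterministic random
molecules (default 3–18 heavy atoms) by grafting chain atoms (palette
weighted towards C, N, O) and ring templates (cyclo-C3–C6, THF,
pyrrolidine, benzene, pyridine, pyrrole, furan, thiophene, naphthalene;
ring probability 0.35) at atoms with spare hydrogens, then promoting
single bonds to double/triple (probability 0.25), charging O⁻/N⁺
(probability 0.08), and adding stereo descriptors (probability 0.5) only
at centres whose carriers have pairwise distinct canonical ranks, i.e.
genuine stereocentres.  Every decoration is committed only if the
touched atoms still match the atom-type table, so generated molecules
pass validation by construction — that property is itself a test, not
an assumption.  The generator emulates connectivity, valence, charge,
aromaticity and stereo diversity at drug-like size; it does not emulate
real structural distributions (functional-group frequencies, ring-system
statistics, tautomers, isotope labelling, macrocycles), so passing tests
demonstrate algorithmic correctness on valence-legal chemical graphs,
not performance or coverage on any particular compound collection.
Problem sizes used by the deepest suites: 200 decomposition queries at
50–600 Da, 1000 fixtures for the SSSR/circuit-rank identity, 500
fixtures × 20 renumberings for canonical invariance, 100 query/target
pairs against the brute-force matcher oracle.

## Known limitations

- No 2D/3D coordinates anywhere: stereo comes only from explicit
  descriptors, wedge/projection perception is out of scope.
- SMARTS text is not parsed; queries are built programmatically or from
  SMILES with overrides.  Recursive/logical SMARTS cannot be expressed,
  which is why 115 MACCS keys are permanently unset.
- Canonicalization guarantees self-consistency, not cross-toolkit string
  equality; tautomers are distinct molecules.
- Radicals, unusual valences, and elements outside the packaged tables
  are either rejected or typed as "no match"; CXSMILES layers are
  carried opaquely, never interpreted.
- The aromaticity models are local-graph approximations; systems whose
  aromaticity depends on perceived atom types beyond the local
  environment may classify differently than in other toolkits.
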