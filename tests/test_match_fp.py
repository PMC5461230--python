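"""Substructure matching (vs a brute-force injection oracle) and
fingerprints (screening subset property, invariance, widths)."""

import itertools
import random

import pytest

from molkit.errors import MolkitError
from molkit.fingerprints import (
    BitFingerprint,
    CountFingerprint,
    MACCS_WIDTH,
    circular_fingerprint,
    maccs_fingerprint,
    maccs_supported_keys,
    path_fingerprint,
    tanimoto,
)
from molkit.match import Pattern, QueryAtom
from molkit.model import Atom, BondOrder, Molecule
from molkit.smiles import parse, write


def brute_force_mappings(pattern, target):
    """Oracle: check every injective assignment of query to target atoms."""
    nq = len(pattern._atoms)
    out = []
    for perm in itertools.permutations(range(len(target)), nq):
        mapping = dict(enumerate(perm))
        if any(
            not pattern._atoms[q].matches(target, t) for q, t in mapping.items()
        ):
            continue
        ok = True
        for (a, b), qb in pattern._bonds.items():
            if not qb.matches(target, mapping[a], mapping[b]):
                ok = False
                break
        if ok and pattern._stereo_ok(target, mapping):
            out.append(mapping)
    return out


class TestPattern:
    def test_benzene_pattern_needs_aromaticity(self):
        assert Pattern.from_smiles("c1ccccc1").required_invariants == {"aromaticity"}

    def test_ethane_pattern_needs_nothing(self):
        assert Pattern.from_smiles("CC").required_invariants == frozenset()

    def test_ring_query_needs_ring_flags(self):
        query = parse("CC")
        pattern = Pattern.compile(
            query, overrides={0: QueryAtom(element=6, in_ring=True)}
        )
        assert "ring_flags" in pattern.required_invariants

    def test_empty_query_rejected(self):
        with pytest.raises(MolkitError):
            Pattern.compile(Molecule())

    def test_benzene_in_toluene_has_twelve_mappings(self):
        pattern = Pattern.from_smiles("c1ccccc1")
        assert pattern.count(parse("Cc1ccccc1")) == 12

    def test_benzene_not_in_cyclohexane(self):
        assert not Pattern.from_smiles("c1ccccc1").matches(parse("C1CCCCC1"))

    def test_wildcard_matches_anything(self):
        query = parse("CC")
        pattern = Pattern.compile(
            query, overrides={0: QueryAtom(wildcard=True), 1: QueryAtom(wildcard=True)}
        )
        assert pattern.count(parse("CO")) == 2  # both directions

    def test_matches_brute_force_oracle(self, small_fixture_molecules):
        queries = ["CC", "CCO", "C=O", "CN", "C(C)O", "c1ccccc1"]
        rng = random.Random(13)
        for target in small_fixture_molecules[:25]:
            q = rng.choice(queries)
            pattern = Pattern.from_smiles(q)
            got = sorted(
                tuple(sorted(m.items())) for m in pattern.match_iter(target)
            )
            expected = sorted(
                tuple(sorted(m.items())) for m in brute_force_mappings(pattern, target)
            )
            assert got == expected, (q, write(target, "generic"))

    def test_lazy_first_match_cheaper_than_full_enumeration(self):
        target = parse("C" * 24)  # long chain: many chain matches
        pattern = Pattern.from_smiles("CCCC")
        first = [0]
        next(pattern.match_iter(target, counter=first))
        full = [0]
        list(pattern.match_iter(target, counter=full))
        assert 0 < first[0] < full[0]

    def test_stereo_enforced_vs_agnostic(self):
        r_center = parse("N[C@@H](C)C(=O)O")
        s_center = parse("N[C@H](C)C(=O)O")
        strict = Pattern.compile(r_center, enforce_stereo=True)
        assert strict.matches(r_center)
        assert not strict.matches(s_center)
        loose = Pattern.compile(r_center, enforce_stereo=False)
        assert loose.matches(s_center)

    def test_double_bond_stereo_enforced(self):
        trans = parse("F/C=C/F")
        cis = parse("F/C=C\\F")
        pattern = Pattern.compile(trans, enforce_stereo=True)
        assert pattern.matches(trans)
        assert not pattern.matches(cis)

    def test_pattern_reusable_across_targets(self):
        pattern = Pattern.from_smiles("C=O")
        assert pattern.matches(parse("CC=O"))
        assert not pattern.matches(parse("CCO"))
        assert pattern.matches(parse("O=C(C)C"))


def grow_superstructure(mol, extra, rng):
    """Return a copy of ``mol`` with ``extra`` carbons grafted on."""
    out = mol.copy()
    for _ in range(extra):
        hosts = [
            i for i in range(len(out)) if (out.atoms[i].implicit_h or 0) >= 1
        ]
        if not hosts:
            break
        host = rng.choice(hosts)
        new = out.add_atom(Atom(6, implicit_h=3))
        out.add_bond(host, new, BondOrder.SINGLE)
        out.atoms[host].implicit_h -= 1
    return out


class TestPathFingerprint:
    def test_single_atom_one_bit(self):
        assert len(path_fingerprint(parse("C"))) == 1

    def test_empty_molecule_no_bits(self):
        assert len(path_fingerprint(Molecule())) == 0

    def test_substructure_bits_are_subset(self, fixture_molecules):
        rng = random.Random(31)
        for mol in fixture_molecules[:40]:
            sub_bits = path_fingerprint(mol).bits
            super_mol = grow_superstructure(mol, rng.randint(1, 4), rng)
            super_bits = path_fingerprint(super_mol).bits
            assert sub_bits <= super_bits

    def test_depth_window_is_zero_to_seven_bonds(self):
        chains = {n: path_fingerprint(parse("C" * n)) for n in (7, 8, 9)}
        # the 7-bond path first appears in the 8-carbon chain...
        assert chains[7].bits < chains[8].bits
        # ...and an 8-bond path is beyond the window: no new bits
        assert chains[8].bits == chains[9].bits

    def test_permutation_invariant(self, fixture_molecules):
        rng = random.Random(17)
        for mol in fixture_molecules[:20]:
            ref = path_fingerprint(mol)
            perm = list(range(len(mol)))
            rng.shuffle(perm)
            assert path_fingerprint(mol.permuted(perm)).bits == ref.bits


class TestCircularFingerprint:
    def test_methane_radius_zero_single_feature(self):
        fp = circular_fingerprint(parse("C"), radius=0, counted=True)
        assert len(fp.entries) == 1 and fp.entries[0][1] == 1

    def test_benzene_one_feature_per_round_count_six(self):
        fp = circular_fingerprint(parse("c1ccccc1"), radius=2, counted=True)
        assert len(fp.entries) == 3  # one distinct environment per round
        assert all(count == 6 for _, count in fp.entries)
        bits = circular_fingerprint(parse("c1ccccc1"), radius=2)
        assert bits.width == 1024 and len(bits) == 3

    def test_disconnected_duplicate_doubles_counts(self):
        single = circular_fingerprint(parse("CCO"), counted=True)
        double = circular_fingerprint(parse("CCO.CCO"), counted=True)
        assert double.as_dict == {k: 2 * v for k, v in single.as_dict.items()}
        assert (
            circular_fingerprint(parse("CCO.CCO")).bits
            == circular_fingerprint(parse("CCO")).bits
        )

    def test_permutation_invariant(self, fixture_molecules):
        rng = random.Random(19)
        for mol in fixture_molecules[:20]:
            ref = circular_fingerprint(mol, counted=True)
            perm = list(range(len(mol)))
            rng.shuffle(perm)
            assert circular_fingerprint(mol.permuted(perm), counted=True) == ref


class TestMaccs:
    def test_width_always_166(self, fixture_molecules):
        for mol in fixture_molecules[:10]:
            assert maccs_fingerprint(mol).width == MACCS_WIDTH

    def test_benzene_sets_aromatic_key_ethane_does_not(self):
        aromatic_key = 162  # "any aromatic atom" in the packaged table
        assert (aromatic_key - 1) in maccs_fingerprint(parse("c1ccccc1")).bits
        assert (aromatic_key - 1) not in maccs_fingerprint(parse("CC")).bits

    def test_bits_confined_to_supported_keys(self, fixture_molecules):
        supported = {k - 1 for k in maccs_supported_keys()}
        for mol in fixture_molecules[:25]:
            assert maccs_fingerprint(mol).bits <= supported

    def test_permutation_invariant(self, fixture_molecules):
        rng = random.Random(29)
        for mol in fixture_molecules[:10]:
            ref = maccs_fingerprint(mol).bits
            perm = list(range(len(mol)))
            rng.shuffle(perm)
            assert maccs_fingerprint(mol.permuted(perm)).bits == ref


class TestTanimoto:
    def test_examples(self):
        a = BitFingerprint(8, frozenset({0, 1}))
        b = BitFingerprint(8, frozenset({1, 4}))
        assert tanimoto(a, a) == 1.0
        assert tanimoto(a, b) == pytest.approx(1 / 3)
        disjoint = BitFingerprint(8, frozenset({6}))
        assert tanimoto(a, disjoint) == 0.0
        empty = BitFingerprint(8, frozenset())
        assert tanimoto(empty, empty) == 1.0
        assert tanimoto(BitFingerprint(8, frozenset({0, 1})), BitFingerprint(8, frozenset({1}))) == 0.5

    def test_width_mismatch(self):
        with pytest.raises(MolkitError):
            tanimoto(BitFingerprint(8, frozenset()), BitFingerprint(16, frozenset()))

    def test_count_fingerprint_contract(self):
        with pytest.raises(ValueError):
            CountFingerprint.from_dict({1: 0})
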