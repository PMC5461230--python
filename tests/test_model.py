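"""Core data model: parity algebra, stereo equivalence, basic counts."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from molkit.model import (
    Atom,
    BondOrder,
    Molecule,
    StereoElement,
    StereoType,
    heavy_atom_count,
    permutation_parity,
    stereo_equivalent,
)
from molkit.smiles import parse


def brute_force_parity(a, b):
    """Independent oracle: count inversions of the index mapping."""
    pos = {item: i for i, item in enumerate(a)}
    mapping = [pos[item] for item in b]
    inversions = sum(
        1
        for i in range(len(mapping))
        for j in range(i + 1, len(mapping))
        if mapping[i] > mapping[j]
    )
    return 1 if inversions % 2 == 0 else -1


class TestPermutationParity:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((1, 2, 3, 4), (1, 2, 3, 4), 1),
            ((1, 2, 3, 4), (2, 1, 3, 4), -1),
            ((1, 2, 3, 4), (2, 3, 1, 4), 1),  # frozen from the oracle
        ],
    )
    def test_examples(self, a, b, expected):
        assert permutation_parity(a, b) == expected
        assert brute_force_parity(a, b) == expected

    def test_matches_oracle_exhaustively(self):
        base = (10, 20, 30, 40)
        for perm in itertools.permutations(base):
            assert permutation_parity(base, perm) == brute_force_parity(base, perm)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_group_property(self, seed):
        rng = random.Random(seed)
        n = rng.randint(2, 8)
        a = list(range(n))
        b = rng.sample(a, n)
        c = rng.sample(a, n)
        assert (
            permutation_parity(a, b) * permutation_parity(b, c)
            == permutation_parity(a, c)
        )

    def test_not_a_permutation(self):
        with pytest.raises(ValueError):
            permutation_parity((1, 2, 3), (1, 2, 4))
        with pytest.raises(ValueError):
            permutation_parity((1, 1, 2), (1, 2, 1))


class TestStereoEquivalence:
    def make(self, carriers, cfg):
        return StereoElement(StereoType.TETRAHEDRAL, 99, tuple(carriers), cfg)

    @pytest.mark.parametrize(
        "c1, k1, c2, k2, expected",
        [
            ("abcd", 1, "abcd", 1, True),
            ("abcd", 1, "bacd", 2, True),   # odd permutation flips config
            ("abcd", 1, "bcad", 2, False),  # even permutation must match
        ],
    )
    def test_examples(self, c1, k1, c2, k2, expected):
        assert stereo_equivalent(self.make(c1, k1), self.make(c2, k2)) is expected

    def test_exhaustive_partition_two_classes_of_24(self):
        """All 4! carrier orders x 2 configurations of one tetrahedral
        centre fall into exactly 2 equivalence classes of 24 each."""
        reps = [
            self.make(perm, cfg)
            for perm in itertools.permutations("abcd")
            for cfg in (1, 2)
        ]
        reference = reps[0]
        classes = {True: 0, False: 0}
        for rep in reps:
            classes[stereo_equivalent(reference, rep)] += 1
        assert classes == {True: 24, False: 24}

    def test_equivalence_relation(self):
        reps = [
            self.make(perm, cfg)
            for perm in itertools.permutations("abcd")
            for cfg in (1, 2)
        ]
        rng = random.Random(3)
        for _ in range(200):
            x, y, z = rng.choice(reps), rng.choice(reps), rng.choice(reps)
            assert stereo_equivalent(x, x)
            assert stereo_equivalent(x, y) == stereo_equivalent(y, x)
            if stereo_equivalent(x, y) and stereo_equivalent(y, z):
                assert stereo_equivalent(x, z)

    def test_placeholder_hydrogen_is_positional(self):
        e1 = StereoElement(StereoType.TETRAHEDRAL, 5, (1, 5, 2, 3), 1)
        e2 = StereoElement(StereoType.TETRAHEDRAL, 5, (5, 1, 2, 3), 2)
        assert stereo_equivalent(e1, e2)

    def test_mismatched_focus_raises(self):
        e1 = self.make("abcd", 1)
        e2 = StereoElement(StereoType.TETRAHEDRAL, 98, tuple("abcd"), 1)
        with pytest.raises(ValueError):
            stereo_equivalent(e1, e2)


class TestMolecule:
    def test_heavy_atom_count(self):
        assert heavy_atom_count(parse("CCO")) == 3
        assert heavy_atom_count(Molecule()) == 0
        methane = Molecule()
        c = methane.add_atom(Atom(6, implicit_h=0))
        for _ in range(4):
            h = methane.add_atom(Atom(1, implicit_h=0))
            methane.add_bond(c, h)
        assert heavy_atom_count(methane) == 1

    def test_adjacency_symmetric(self):
        mol = parse("CC(C)C(=O)O")
        for bond in mol.bonds:
            assert bond.end in mol.neighbors(bond.begin)
            assert bond.begin in mol.neighbors(bond.end)

    def test_duplicate_and_self_bonds_rejected(self):
        mol = Molecule()
        a = mol.add_atom(Atom(6))
        b = mol.add_atom(Atom(6))
        mol.add_bond(a, b)
        with pytest.raises(ValueError):
            mol.add_bond(b, a)
        with pytest.raises(ValueError):
            mol.add_bond(a, a)

    def test_permuted_preserves_structure(self, fixture_molecules):
        rng = random.Random(0)
        for mol in fixture_molecules[:20]:
            perm = list(range(len(mol)))
            rng.shuffle(perm)
            out = mol.permuted(perm)
            assert len(out) == len(mol)
            assert len(out.bonds) == len(mol.bonds)
            for bond in mol.bonds:
                assert out.bond(perm[bond.begin], perm[bond.end]) is not None

    def test_unset_order_rejected_outside_kekulization(self):
        mol = Molecule()
        a = mol.add_atom(Atom(6))
        b = mol.add_atom(Atom(6))
        mol.add_bond(a, b, BondOrder.UNSET)
        with pytest.raises(ValueError):
            mol.bond_order_sum(a)

    def test_reserved_stereo_types_representable(self):
        el = StereoElement(StereoType.SQUARE_PLANAR, 0, (1, 2, 3, 4), 1)
        assert el.stype is StereoType.SQUARE_PLANAR
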