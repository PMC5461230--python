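"""SMILES reader/writer: grammar coverage, stereo semantics, canonical
invariance, and round trips (with RDKit as an independent oracle)."""

import random
import re

import pytest
from rdkit import Chem, RDLogger

from molkit.errors import KekulizationError, SmilesParseError, TypingError
from molkit.match import Pattern
from molkit.model import OPPOSITE, TOGETHER, StereoType, heavy_atom_count
from molkit.smiles import canonical_ranks, parse, write

RDLogger.DisableLog("rdApp.*")

STEREO_CASES = [
    "N[C@@H](C)C(=O)O",
    "N[C@H](C)C(=O)O",
    "[C@](N)(C)(O)CC",
    "O[C@@H]1CC[C@H](N)CC1",
    "F/C=C/F",
    "F/C=C\\F",
    "C(/F)=C/F",
    "C/C=C/C=C/C",
    "C/C=C\\C=C/C",
    "CC(=O)O[C@@H]1C[NH+]2CCC1CC2",
]


def count_atom_tokens(smiles):
    """Tokenizer oracle: number of atom tokens in a SMILES string."""
    body = re.sub(r"\[[^\]]*\]", "X", smiles)
    return len(re.findall(r"Cl|Br|[BCNOPSFIbcnops]|X", body))


class TestParser:
    def test_ethanol(self):
        mol = parse("CCO")
        assert heavy_atom_count(mol) == 3
        assert [a.implicit_h for a in mol.atoms] == [3, 2, 1]

    def test_empty_string_is_empty_molecule(self):
        assert len(parse("")) == 0

    def test_bracket_properties(self):
        mol = parse("[13CH3][O-]")
        assert mol.atoms[0].isotope == 13
        assert mol.atoms[0].implicit_h == 3
        assert mol.atoms[1].charge == -1

    def test_multi_digit_charge(self):
        assert parse("[O-][S+2]([O-])([O-])[O-]").atoms[1].charge == 2

    def test_percent_ring_closure(self):
        mol = parse("C%10CCCCC%10")
        assert len(mol.bonds) == 6

    def test_dot_disconnection(self):
        mol = parse("[Na+].[Cl-]")
        assert len(mol) == 2 and mol.bond(0, 1) is None

    def test_triple_and_double_bonds(self):
        mol = parse("N#CC=O")
        assert int(mol.bond(0, 1).order) == 3
        assert int(mol.bond(2, 3).order) == 2

    def test_alanine_stereo_element(self):
        mol = parse("N[C@@H](C)C(=O)O")
        (el,) = mol.stereo
        assert el.stype is StereoType.TETRAHEDRAL
        assert el.focus == 1
        # implicit H placeholder: focus reused in carriers after the parent
        assert el.carriers == (0, 1, 2, 3)

    def test_cis_trans_configurations(self):
        (trans,) = parse("F/C=C/F").stereo
        assert trans.configuration == OPPOSITE
        (cis,) = parse("F/C=C\\F").stereo
        assert cis.configuration == TOGETHER

    @pytest.mark.parametrize(
        "bad",
        [
            "C(",            # unclosed branch
            "C)",            # stray close
            "C1CC",          # unclosed ring bond
            "C=",            # dangling bond symbol
            "C=#C",          # two bond symbols
            "C1CC=1",        # closure order conflict
            "C/C=C(/F)/F",   # conflicting directional bonds
            "%1C",           # malformed percent closure
            "[CH4",          # unterminated bracket
            "C..C",          # empty component between dots is a parse error
        ],
    )
    def test_syntax_errors_have_positions(self, bad):
        with pytest.raises(SmilesParseError) as exc:
            parse(bad)
        assert 0 <= exc.value.position <= len(bad)

    def test_invalid_aromatic_rejected(self):
        with pytest.raises(KekulizationError):
            parse("c1ccc1")

    def test_valence_violations_rejected(self):
        with pytest.raises(TypingError):
            parse("[CH5]")
        with pytest.raises(TypingError):
            parse("O(C)(C)C")

    def test_heavy_atoms_equal_atom_tokens(self, fixture_molecules):
        for mol in fixture_molecules[:50]:
            smiles = write(mol, "absolute")
            assert count_atom_tokens(smiles) == heavy_atom_count(mol)


class TestCanonicalRanks:
    def test_ethanol_three_ranks(self):
        assert len(set(canonical_ranks(parse("CCO")))) == 3

    def test_benzene_single_orbit(self):
        assert len(set(canonical_ranks(parse("c1ccccc1")))) == 1

    def test_invariant_under_renumbering(self, fixture_molecules):
        rng = random.Random(11)
        for mol in fixture_molecules[:25]:
            ranks = canonical_ranks(mol)
            perm = list(range(len(mol)))
            rng.shuffle(perm)
            permuted_ranks = canonical_ranks(mol.permuted(perm))
            for old, new in enumerate(perm):
                assert ranks[old] == permuted_ranks[new]


class TestWriter:
    def test_kekule_round_trip_is_isomorphic(self):
        mol = parse("c1ccccc1")
        again = parse(write(mol, "generic"))
        assert write(again, "unique") == write(mol, "unique")

    def test_unique_is_entry_order_independent(self):
        assert write(parse("OCC"), "unique") == write(parse("CCO"), "unique")

    def test_unique_strips_stereo_absolute_keeps_it(self):
        r = parse("N[C@@H](C)C(=O)O")
        s = parse("N[C@H](C)C(=O)O")
        assert write(r, "unique") == write(s, "unique")
        assert write(r, "absolute") != write(s, "absolute")

    def test_permutation_invariance(self, fixture_molecules):
        rng = random.Random(23)
        for mol in fixture_molecules[:40]:
            ref = write(mol, "unique")
            for _ in range(5):
                perm = list(range(len(mol)))
                rng.shuffle(perm)
                assert write(mol.permuted(perm), "unique") == ref

    def test_absolute_round_trip_preserves_graph_and_stereo(self, fixture_molecules):
        for mol in fixture_molecules[:40]:
            again = parse(write(mol, "absolute"))
            assert write(again, "absolute") == write(mol, "absolute")
            pattern = Pattern.compile(mol, enforce_stereo=True)
            assert pattern.matches(again)

    def test_stereo_against_rdkit(self):
        for smiles in STEREO_CASES:
            mine = write(parse(smiles), "absolute")
            assert Chem.CanonSmiles(mine) == Chem.CanonSmiles(smiles), smiles

    def test_renumbered_stereo_against_rdkit(self):
        rng = random.Random(2)
        for smiles in STEREO_CASES:
            mol = parse(smiles)
            for _ in range(5):
                perm = list(range(len(mol)))
                rng.shuffle(perm)
                out = write(mol.permuted(perm), "absolute")
                assert Chem.CanonSmiles(out) == Chem.CanonSmiles(smiles), smiles

    def test_fixture_smiles_accepted_by_rdkit(self, fixture_molecules):
        parsed = 0
        for mol in fixture_molecules[:60]:
            rd = Chem.MolFromSmiles(write(mol, "absolute"))
            if rd is not None:
                parsed += 1
                assert rd.GetNumAtoms() == heavy_atom_count(mol)
        assert parsed >= 55  # the corpus must be overwhelmingly standard

    def test_aromatic_output_round_trips(self):
        for smiles in ["c1ccccc1", "c1cc[nH]c1", "c1ccncc1", "Cc1ccccc1"]:
            mol = parse(smiles)
            from molkit.aromaticity import find_aromatic

            find_aromatic(mol)
            from molkit.smiles import SmilesFlavor

            out = write(mol, SmilesFlavor(aromatic_output=True))
            assert out.islower() or "c" in out
            assert write(parse(out), "unique") == write(mol, "unique")
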