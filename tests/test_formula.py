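"""Formulas, exact mass, decomposition (Round Robin vs enumeration vs a
brute-force oracle), isotope patterns, and RDBE filtering."""

import itertools
import math
import random

import pytest

from molkit.errors import MolkitError
from molkit.formula import (
    DecompositionQuery,
    MolecularFormula,
    choose_algorithm,
    decompose,
    decompose_enumerate,
    decompose_round_robin,
    exact_mass,
    filter_rdbe,
    formula_of,
    isotope_distribution,
    isotope_pattern,
    load_isotopes,
    monoisotopic,
    rdbe,
)
from molkit.smiles import parse

CHNOPS = {s: (0, 10_000) for s in ("C", "H", "N", "O", "P", "S")}


def oracle_decompose(query):
    """Independent brute-force oracle: nested loops over capped counts."""
    lo = query.target_mass - query.tolerance
    hi = query.target_mass + query.tolerance
    syms = sorted(query.bounds)
    masses = [monoisotopic(s).exact_mass for s in syms]
    caps = [
        min(query.bounds[s][1], math.floor(hi / m))
        for s, m in zip(syms, masses)
    ]
    found = []
    for counts in itertools.product(*(range(c + 1) for c in caps)):
        if any(c < query.bounds[s][0] for c, s in zip(counts, syms)):
            continue
        mass = sum(c * m for c, m in zip(counts, masses))
        if lo - 1e-12 <= mass <= hi + 1e-12:
            found.append(MolecularFormula.from_counts(dict(zip(syms, counts))))
    return set(found)


class TestFormulaBasics:
    def test_formula_of_counts_implicit_hydrogens(self):
        assert str(formula_of(parse("CCO"))) == "C2H6O"
        assert str(formula_of(parse("c1ccccc1"))) == "C6H6"

    def test_formula_of_acetate_has_charge(self):
        f = formula_of(parse("CC(=O)[O-]"))
        assert f.counts == {"C": 2, "H": 3, "O": 2}
        assert f.charge == -1

    def test_hill_order(self):
        f = MolecularFormula.from_counts({"O": 1, "C": 2, "H": 6, "N": 1})
        assert str(f) == "C2H6NO"
        no_carbon = MolecularFormula.from_counts({"O": 1, "H": 2})
        assert str(no_carbon) == "H2O"

    def test_exact_mass_examples(self):
        assert exact_mass(MolecularFormula.from_counts({})) == 0.0
        water = MolecularFormula.from_counts({"H": 2, "O": 1})
        assert exact_mass(water) == pytest.approx(18.010565, abs=1e-5)
        glucose = MolecularFormula.from_counts({"C": 6, "H": 12, "O": 6})
        assert exact_mass(glucose) == pytest.approx(180.063388, abs=1e-4)

    def test_charge_applies_electron_mass(self):
        cation = MolecularFormula.from_counts({"H": 1}, charge=1)
        neutral = MolecularFormula.from_counts({"H": 1})
        assert exact_mass(neutral) - exact_mass(cation) == pytest.approx(
            0.000549, abs=1e-6
        )

    def test_unknown_element_raises(self):
        with pytest.raises(MolkitError):
            exact_mass(MolecularFormula.from_counts({"Xx": 1}))


class TestDecomposition:
    def test_water_mass_unique(self):
        q = DecompositionQuery(18.010565, 0.001, CHNOPS)
        assert [str(f) for f in decompose(q)] == ["H2O"]

    def test_exact_tolerance_carbon_only_empty(self):
        q = DecompositionQuery(18.010565, 0.0, {"C": (0, 100)})
        assert decompose_round_robin(q) == []

    def test_small_mass_single_element_empty(self):
        q = DecompositionQuery(10.0, 0.001, {"C": (0, 100)})
        assert decompose(q) == []

    def test_both_algorithms_match_oracle(self):
        rng = random.Random(42)
        for _ in range(8):
            mass = rng.uniform(40, 150)
            tol = rng.choice([0.001, 0.01])
            q = DecompositionQuery(mass, tol, CHNOPS)
            expected = oracle_decompose(q)
            assert set(decompose_round_robin(q)) == expected
            assert set(decompose_enumerate(q)) == expected

    def test_round_robin_equals_enumeration_order_and_set(self):
        rng = random.Random(9)
        for _ in range(10):
            q = DecompositionQuery(
                rng.uniform(50, 400), rng.choice([0.001, 0.01]), CHNOPS
            )
            assert decompose_round_robin(q) == decompose_enumerate(q)

    def test_results_sorted_by_mass(self):
        q = DecompositionQuery(120.0, 0.05, CHNOPS)
        masses = [exact_mass(f) for f in decompose(q)]
        assert masses == sorted(masses)

    def test_bounds_respected(self):
        q = DecompositionQuery(
            59.013305, 0.001, {"C": (0, 1), "H": (0, 100), "O": (0, 100)}
        )
        assert decompose(q) == []  # C2H3O2 needs two carbons

    def test_minimum_counts_respected(self):
        q = DecompositionQuery(18.010565, 0.001, {**CHNOPS, "C": (1, 100)})
        assert decompose(q) == []

    def test_dispatch_rules(self):
        assert choose_algorithm(DecompositionQuery(100.0, 0.001, CHNOPS)) == "round_robin"
        assert choose_algorithm(DecompositionQuery(500_000.0, 0.001, CHNOPS)) == "enumerate"
        assert choose_algorithm(DecompositionQuery(100.0, 0.6, CHNOPS)) == "enumerate"

    def test_round_robin_refuses_wide_span(self):
        with pytest.raises(MolkitError):
            decompose_round_robin(DecompositionQuery(100.0, 0.75, CHNOPS))

    def test_wide_span_answered_by_enumeration(self):
        q = DecompositionQuery(100.0, 0.75, {"C": (0, 20), "H": (0, 40)})
        assert len(decompose(q)) > 0

    def test_empty_element_set_raises(self):
        with pytest.raises(MolkitError):
            decompose(DecompositionQuery(100.0, 0.001, {}))

    def test_residue_table_is_small(self):
        from molkit.formula import _PRECISION, _residue_table

        weights = tuple(
            math.floor(monoisotopic(s).exact_mass / _PRECISION)
            for s in ("S", "P", "O", "N", "C", "H")
        )
        tables = _residue_table(weights)
        assert len(tables) == len(weights)
        assert all(len(t) == weights[-1] for t in tables)


class TestIsotopePatterns:
    def test_carbon_ratio(self):
        pattern = isotope_pattern(MolecularFormula.from_counts({"C": 1}), 1e-4)
        assert len(pattern.peaks) == 2
        iso = load_isotopes()["C"]
        expected = iso[1].abundance / iso[0].abundance
        assert pattern.peaks[1][1] == pytest.approx(expected, rel=1e-6)

    def test_h2_has_three_isotopologues(self):
        pattern = isotope_pattern(MolecularFormula.from_counts({"H": 2}), 1e-10)
        assert len(pattern.peaks) == 3
        d = load_isotopes()["H"][1].abundance
        h = load_isotopes()["H"][0].abundance
        dd_over_hh = pattern.peaks[2][1]
        assert dd_over_hh == pytest.approx((d / h) ** 2, rel=1e-6)

    def test_cl2_binomial(self):
        pattern = isotope_pattern(MolecularFormula.from_counts({"Cl": 2}), 1e-6)
        assert len(pattern.peaks) == 3  # M, M+2, M+4
        ratio = pattern.peaks[1][1]
        assert ratio == pytest.approx(2 * 0.2424 / 0.7576, rel=1e-4)

    def test_distribution_probability_bounded(self):
        f = MolecularFormula.from_counts({"C": 10, "H": 14, "Cl": 2, "S": 1})
        dist = isotope_distribution(f)
        total = sum(x for _, x in dist)
        assert total <= 1 + 1e-9

    def test_normalization_max_is_one(self):
        pattern = isotope_pattern(MolecularFormula.from_counts({"C": 20, "Br": 2}))
        assert max(x for _, x in pattern.peaks) == 1.0
        masses = [m for m, _ in pattern.peaks]
        assert masses == sorted(masses)

    def test_bad_min_abundance(self):
        with pytest.raises(ValueError):
            isotope_pattern(MolecularFormula.from_counts({"C": 1}), 0.0)


class TestRdbe:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({"C": 6, "H": 6}, 4.0),
            ({"C": 1, "H": 4}, 0.0),
            ({"H": 2}, 0.0),
            ({"C": 2, "H": 5, "N": 1, "O": 1}, 1.0),  # acetamide: 1 DBE
        ],
    )
    def test_values(self, counts, expected):
        assert rdbe(MolecularFormula.from_counts(counts)) == expected

    def test_filter(self):
        fs = [
            MolecularFormula.from_counts({"C": 6, "H": 6}),
            MolecularFormula.from_counts({"H": 2}),
        ]
        assert filter_rdbe(fs, 0, 20) == fs
        assert filter_rdbe(fs, 1, 20) == fs[:1]
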