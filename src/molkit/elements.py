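"""Element symbols, atomic numbers and the standard valence table.

The valence table drives implicit-hydrogen inference: for an element in a
given charge state it lists the legal total bond-order sums, smallest
first.  The smallest legal valence that is >= the current bond-order sum
wins, matching common SMILES implicit-hydrogen semantics.
"""

from __future__ import annotations

SYMBOLS: dict[int, str] = {
    1: "H", 2: "He", 3: "Li", 4: "Be", 5: "B", 6: "C", 7: "N", 8: "O",
    9: "F", 10: "Ne", 11: "Na", 12: "Mg", 13: "Al", 14: "Si", 15: "P",
    16: "S", 17: "Cl", 18: "Ar", 19: "K", 20: "Ca", 26: "Fe", 29: "Cu",
    30: "Zn", 33: "As", 34: "Se", 35: "Br", 50: "Sn", 53: "I", 78: "Pt",
    79: "Au", 80: "Hg", 82: "Pb",
}

ATOMIC_NUMBERS: dict[str, int] = {s: z for z, s in SYMBOLS.items()}

#: Elements allowed without brackets in SMILES (the "organic subset").
ORGANIC_SUBSET = {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}

#: Elements that may carry an aromatic (lowercase) flag in SMILES.
AROMATIC_ELEMENTS = {5, 6, 7, 8, 15, 16, 33, 34}

# (atomic number, formal charge) -> ascending list of legal valences.
_VALENCES: dict[tuple[int, int], list[int]] = {
    (1, 0): [1],
    (1, 1): [0],
    (5, 0): [3],
    (5, -1): [4],
    (6, 0): [4],
    (6, 1): [3],
    (6, -1): [3],
    (7, 0): [3],
    (7, 1): [4],
    (7, -1): [2],
    (8, 0): [2],
    (8, 1): [3],
    (8, -1): [1],
    (15, 0): [3, 5],
    (15, 1): [4],
    (15, -1): [2],
    (16, 0): [2, 4, 6],
    (16, 1): [3, 5],
    (16, -1): [1],
    (14, 0): [4],
    (9, 0): [1],
    (9, -1): [0],
    (17, 0): [1],
    (17, -1): [0],
    (35, 0): [1],
    (35, -1): [0],
    (53, 0): [1],
    (53, -1): [0],
    (11, 0): [1],
    (11, 1): [0],
    (19, 0): [1],
    (19, 1): [0],
}


def legal_valences(element: int, charge: int) -> list[int] | None:
    """Legal bond-order sums for an element/charge pair, or None if the
    pair is outside the table (e.g. transition metals)."""
    return _VALENCES.get((element, charge))


def symbol(element: int) -> str:
    try:
        return SYMBOLS[element]
    except KeyError:
        raise ValueError(f"unknown atomic number {element}") from None


def atomic_number(sym: str) -> int:
    try:
        return ATOMIC_NUMBERS[sym]
    except KeyError:
        raise ValueError(f"unknown element symbol {sym!r}") from None
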