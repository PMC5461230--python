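"""Declarative atom typing.

Atom types are perceived against a packaged table that records, per type,
the element, hybridization, formal charge, lone-pair count and the
multiset of bond orders (implicit hydrogens counted as single bonds).
Perception is a pure lookup on the atom's local environment and is run in
atom order, so the i-th perceived type corresponds to atom i.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

from .elements import atomic_number, legal_valences, symbol
from .errors import FormatError, TypingError
from .model import Atom, BondOrder, Molecule

__all__ = [
    "AtomTypeDef",
    "TypeTable",
    "load_type_table",
    "infer_implicit_hydrogens",
    "perceive_type",
    "perceive_all",
    "validate_types",
]

_ORDER_CODES = {"s": BondOrder.SINGLE, "d": BondOrder.DOUBLE, "t": BondOrder.TRIPLE}


@dataclass(frozen=True)
class AtomTypeDef:
    """One record of the atom-type table."""

    name: str
    element: int
    hybridization: str  # s, sp1, sp2, sp3, planar3 or unset
    formal_charge: int
    lone_pairs: int
    bond_orders: tuple[int, ...]  # sorted bond-order values, H as single

    @property
    def neighbor_count(self) -> int:
        return len(self.bond_orders)

    @property
    def pi_bond_count(self) -> int:
        return sum(o - 1 for o in self.bond_orders if o > 1)


class TypeTable:
    """Atom-type records indexed by (element, charge, environment)."""

    def __init__(self, entries: list[AtomTypeDef]) -> None:
        self.entries = entries
        self._index: dict[tuple[int, int, tuple[int, ...]], AtomTypeDef] = {}
        for entry in entries:
            key = (entry.element, entry.formal_charge, entry.bond_orders)
            if key in self._index:
                raise FormatError(
                    f"duplicate atom-type environment for {entry.name!r}"
                )
            self._index[key] = entry

    def lookup(
        self, element: int, charge: int, bond_orders: tuple[int, ...]
    ) -> Optional[AtomTypeDef]:
        return self._index.get((element, charge, tuple(sorted(bond_orders))))


_HYBRIDIZATIONS = {"s", "sp1", "sp2", "sp3", "planar3", "unset"}
_table_cache: TypeTable | None = None


def load_type_table() -> TypeTable:
    """Load (and cache) the packaged atom-type table."""
    global _table_cache
    if _table_cache is not None:
        return _table_cache
    text = resources.files("molkit.data").joinpath("atom_types.tsv").read_text()
    entries = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise FormatError(f"atom_types.tsv line {lineno}: expected 6 fields")
        name, sym, charge_s, hyb, lp_s, orders_s = parts
        try:
            charge = int(charge_s)
            lone_pairs = int(lp_s)
            element = atomic_number(sym)
            if hyb not in _HYBRIDIZATIONS:
                raise ValueError(f"unknown hybridization {hyb!r}")
            if orders_s == "-":
                orders: tuple[int, ...] = ()
            else:
                orders = tuple(
                    sorted(int(_ORDER_CODES[c]) for c in orders_s.split(","))
                )
        except (ValueError, KeyError) as exc:
            raise FormatError(f"atom_types.tsv line {lineno}: {exc}") from None
        entries.append(AtomTypeDef(name, element, hyb, charge, lone_pairs, orders))
    _table_cache = TypeTable(entries)
    return _table_cache


def _environment(mol: Molecule, index: int) -> tuple[int, ...]:
    """Sorted bond-order multiset of an atom, implicit H as single bonds."""
    atom = mol.atoms[index]
    orders = []
    for bond in mol.bonds_of(index):
        if bond.order is BondOrder.UNSET:
            raise TypingError(
                f"atom {index} has a bond with unset order; kekulize first", index
            )
        orders.append(int(bond.order))
    orders.extend([1] * (atom.implicit_h or 0))
    return tuple(sorted(orders))


def infer_implicit_hydrogens(mol: Molecule) -> Molecule:
    """Fill in implicit hydrogen counts from the standard valence table.

    Each atom with an unset count receives ``smallest legal valence -
    bond-order sum`` hydrogens; atoms already carrying a count are left
    untouched.  Requires kekulized (fully ordered) bonds.
    """
    for i, atom in enumerate(mol.atoms):
        if atom.implicit_h is not None:
            continue
        valences = legal_valences(atom.element, atom.charge)
        total = mol.bond_order_sum(i)
        if valences is None:
            # Outside the valence table (metals etc.): no implicit H.
            atom.implicit_h = 0
            continue
        for v in valences:
            if v >= total:
                atom.implicit_h = v - total
                break
        else:
            raise TypingError(
                f"atom {i} ({atom.symbol}{_charge_suffix(atom.charge)}) has bond "
                f"order sum {total} exceeding every legal valence {valences}",
                i,
            )
    return mol


def _charge_suffix(charge: int) -> str:
    if charge == 0:
        return ""
    sign = "+" if charge > 0 else "-"
    return sign if abs(charge) == 1 else f"{sign}{abs(charge)}"


def perceive_type(mol: Molecule, index: int) -> Optional[AtomTypeDef]:
    """The unique table entry matching an atom's environment, or None."""
    table = load_type_table()
    atom = mol.atoms[index]
    return table.lookup(atom.element, atom.charge, _environment(mol, index))


def perceive_all(mol: Molecule) -> list[Optional[AtomTypeDef]]:
    """Perceive every atom; results are ordered like the atoms."""
    return [perceive_type(mol, i) for i in range(len(mol))]


def validate_types(mol: Molecule) -> list[str]:
    """One diagnostic line per atom whose environment matches no type.

    Diagnostics are rendered as ``atom <i> (<symbol>): <message>``.
    """
    diagnostics = []
    for i, atom in enumerate(mol.atoms):
        label = f"atom {i} ({atom.symbol}{_charge_suffix(atom.charge)})"
        try:
            env = _environment(mol, i)
        except TypingError as exc:
            diagnostics.append(f"{label}: {exc}")
            continue
        if atom.implicit_h is None:
            diagnostics.append(f"{label}: implicit hydrogen count not inferred")
            continue
        entry = load_type_table().lookup(atom.element, atom.charge, env)
        if entry is None:
            orders = ",".join("-sdt"[o] for o in env) or "-"
            diagnostics.append(f"{label}: no atom type matches environment [{orders}]")
    return diagnostics
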