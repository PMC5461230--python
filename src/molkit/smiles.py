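"""SMILES reading and writing.

The reader covers the organic subset, bracket atoms (isotope, charge,
hydrogen count, atom class), single/double/triple/aromatic bonds,
directional bonds, branches, ring closures (including ``%nn``),
dot-disconnection, lowercase aromatic atoms and tetrahedral ``@``/``@@``
tags.  Aromatic input is always kekulized; if no alternating single/double
assignment supports the claimed aromatic atoms the SMILES is rejected.
Implicit hydrogens are inferred from the standard valence table and
bracket-atom valences are validated.

The writer produces several flavours: ``generic`` (plain connectivity),
``isomeric`` (stereo and isotopes), ``unique`` (canonical order, stereo
and isotopes stripped) and ``absolute`` (canonical order with stereo and
isotopes).  Canonical ordering is refinement-based; the contract is
self-consistency under renumbering, not string equality with any other
toolkit.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

from .elements import (
    AROMATIC_ELEMENTS,
    ATOMIC_NUMBERS,
    ORGANIC_SUBSET,
    atomic_number,
    legal_valences,
    symbol,
)
from .errors import MolkitError, SmilesParseError, TypingError
from .model import (
    ANTICLOCKWISE,
    CLOCKWISE,
    OPPOSITE,
    TOGETHER,
    Atom,
    BondOrder,
    Molecule,
    StereoElement,
    StereoType,
    permutation_parity,
)
from .aromaticity import kekulize
from .rings import mark_rings
from .typing import infer_implicit_hydrogens

__all__ = ["parse", "write", "canonical_ranks", "SmilesFlavor"]

_AROMATIC_ORGANIC = {"b", "c", "n", "o", "p", "s"}
_AROMATIC_BRACKET = {"b", "c", "n", "o", "p", "s", "se", "as"}
_BOND_ORDERS = {"-": BondOrder.SINGLE, "=": BondOrder.DOUBLE, "#": BondOrder.TRIPLE}


@dataclass(frozen=True)
class SmilesFlavor:
    """Output flavour flags."""

    canonical: bool = False
    stereo: bool = True
    isotopes: bool = True
    aromatic_output: bool = False

    @staticmethod
    def named(name: str) -> "SmilesFlavor":
        try:
            return _FLAVORS[name]
        except KeyError:
            raise ValueError(
                f"unknown flavor {name!r}; expected one of {sorted(_FLAVORS)}"
            ) from None


_FLAVORS = {
    "generic": SmilesFlavor(canonical=False, stereo=False, isotopes=False),
    "isomeric": SmilesFlavor(canonical=False, stereo=True, isotopes=True),
    "unique": SmilesFlavor(canonical=True, stereo=False, isotopes=False),
    "absolute": SmilesFlavor(canonical=True, stereo=True, isotopes=True),
}


# ----------------------------------------------------------------------
# Parser
# ----------------------------------------------------------------------


class _RingSlot:
    """Placeholder in an atom's neighbour-order list for a ring bond."""

    __slots__ = ("partner",)

    def __init__(self) -> None:
        self.partner: int | None = None


class _Parser:
    def __init__(self, text: str) -> None:
        self.text = text
        self.i = 0
        self.mol = Molecule()
        self.prev: int | None = None
        self.stack: list[int | None] = []
        self.pending: str | None = None  # bond symbol awaiting the next atom
        self.pending_pos = 0
        self.rings: dict[int, tuple[int, str | None, _RingSlot, int]] = {}
        # neighbour appearance order per atom; entries: int, 'H', or _RingSlot
        self.slots: dict[int, list] = {}
        self.chiral: dict[int, int] = {}  # atom -> configuration
        self.explicit_h: set[int] = set()
        self.explicit_double: set[frozenset[int]] = set()
        # directional bonds: bond key -> list of (from_atom, symbol, position)
        self.directions: dict[frozenset[int], list[tuple[int, str, int]]] = {}

    def error(self, message: str, pos: int | None = None) -> SmilesParseError:
        return SmilesParseError(message, self.i if pos is None else pos)

    # -- scanning helpers --------------------------------------------

    def peek(self) -> str:
        return self.text[self.i] if self.i < len(self.text) else ""

    def take(self) -> str:
        ch = self.peek()
        self.i += 1
        return ch

    def digits(self) -> str:
        start = self.i
        while self.peek().isdigit():
            self.i += 1
        return self.text[start : self.i]

    # -- graph building ----------------------------------------------

    def add_atom(self, atom: Atom, h_placeholder: bool) -> None:
        idx = self.mol.add_atom(atom)
        self.slots[idx] = []
        if self.prev is not None:
            self.bond(self.prev, idx, self.pending, self.pending_pos)
        elif self.pending is not None:
            raise self.error("bond symbol must be followed by an atom", self.pending_pos)
        self.pending = None
        if h_placeholder:
            self.slots[idx].append("H")
        self.prev = idx

    def bond(self, a: int, b: int, sym: str | None, pos: int) -> None:
        order, aromatic = self.resolve_bond(a, b, sym, pos)
        try:
            self.mol.add_bond(a, b, order, aromatic)
        except ValueError as exc:
            raise self.error(str(exc), pos)
        self.slots[a].append(b)
        self.slots[b].append(a)
        self.record_direction(a, b, sym, pos)
        if order is BondOrder.DOUBLE:
            self.explicit_double.add(frozenset((a, b)))

    def resolve_bond(
        self, a: int, b: int, sym: str | None, pos: int
    ) -> tuple[BondOrder, bool]:
        atoms = self.mol.atoms
        if sym is None:
            if atoms[a].aromatic and atoms[b].aromatic:
                return BondOrder.UNSET, True
            return BondOrder.SINGLE, False
        if sym == ":":
            if not (atoms[a].aromatic and atoms[b].aromatic):
                raise self.error("aromatic bond between non-aromatic atoms", pos)
            return BondOrder.UNSET, True
        if sym in ("/", "\\"):
            return BondOrder.SINGLE, False
        return _BOND_ORDERS[sym], False

    def record_direction(self, a: int, b: int, sym: str | None, pos: int) -> None:
        if sym in ("/", "\\"):
            self.directions.setdefault(frozenset((a, b)), []).append((a, sym, pos))

    # -- token parsing -----------------------------------------------

    def parse(self) -> Molecule:
        text = self.text
        while self.i < len(text):
            ch = self.peek()
            if ch in "-=#:/\\":
                if self.pending is not None:
                    raise self.error("two consecutive bond symbols")
                self.pending = ch
                self.pending_pos = self.i
                self.take()
            elif ch == "(":
                if self.prev is None:
                    raise self.error("branch cannot start a SMILES")
                self.stack.append(self.prev)
                self.take()
            elif ch == ")":
                if not self.stack:
                    raise self.error("unmatched ')'")
                if self.pending is not None:
                    raise self.error("dangling bond symbol before ')'")
                self.prev = self.stack.pop()
                self.take()
            elif ch == ".":
                if self.pending is not None:
                    raise self.error("bond symbol before '.'")
                if self.prev is None:
                    raise self.error("'.' must follow an atom")
                self.prev = None
                self.take()
            elif ch.isdigit() or ch == "%":
                self.ring_closure()
            elif ch == "[":
                self.bracket_atom()
            else:
                self.organic_atom()
        if self.stack:
            raise self.error("unclosed '('")
        if self.pending is not None:
            raise self.error("dangling bond symbol at end of input", self.pending_pos)
        if self.rings:
            nums = ", ".join(str(n) for n in sorted(self.rings))
            raise self.error(f"unclosed ring closure(s): {nums}")
        return self.finish()

    def ring_closure(self) -> None:
        pos = self.i
        if self.prev is None:
            raise self.error("ring closure digit with no preceding atom")
        if self.peek() == "%":
            self.take()
            num_s = self.text[self.i : self.i + 2]
            if len(num_s) != 2 or not num_s.isdigit():
                raise self.error("'%' must be followed by two digits")
            self.i += 2
        else:
            num_s = self.take()
        num = int(num_s)
        sym = self.pending
        self.pending = None
        if num not in self.rings:
            slot = _RingSlot()
            self.slots[self.prev].append(slot)
            self.rings[num] = (self.prev, sym, slot, pos if sym is None else self.pending_pos)
            if sym in ("/", "\\"):
                # direction recorded once the partner is known
                pass
        else:
            a, open_sym, slot, open_pos = self.rings.pop(num)
            b = self.prev
            if a == b:
                raise self.error(f"ring closure {num} bonds an atom to itself", pos)
            use = open_sym if sym is None else sym
            if sym in ("=", "#", ":") and open_sym != sym:
                # strict: an order-bearing symbol at the closure must have
                # been announced at the opening (rejects "C1CC=1")
                raise self.error(
                    f"conflicting bond orders on ring closure {num}", pos
                )
            if open_sym is not None and sym is not None:
                same_order = {open_sym, sym} <= {"-", "/", "\\"} or open_sym == sym
                if not same_order:
                    raise self.error(
                        f"conflicting bond orders on ring closure {num}", pos
                    )
            order, aromatic = self.resolve_bond(a, b, use, pos)
            try:
                self.mol.add_bond(a, b, order, aromatic)
            except ValueError as exc:
                raise self.error(str(exc), pos)
            if order is BondOrder.DOUBLE:
                self.explicit_double.add(frozenset((a, b)))
            slot.partner = b
            self.slots[b].append(a)
            if open_sym in ("/", "\\"):
                self.record_direction(a, b, open_sym, open_pos)
            if sym in ("/", "\\"):
                self.record_direction(b, a, sym, pos)

    def organic_atom(self) -> None:
        for tok in ("Cl", "Br"):
            if self.text.startswith(tok, self.i):
                self.i += 2
                self.add_atom(Atom(atomic_number(tok)), False)
                return
        ch = self.peek()
        if ch in "BCNOPSFI":
            self.take()
            self.add_atom(Atom(atomic_number(ch)), False)
        elif ch in _AROMATIC_ORGANIC:
            self.take()
            self.add_atom(Atom(atomic_number(ch.upper()), aromatic=True), False)
        else:
            raise self.error(f"unexpected character {ch!r}")

    def bracket_atom(self) -> None:
        start = self.i
        self.take()  # '['
        isotope = None
        iso = self.digits()
        if iso:
            isotope = int(iso)
        # element symbol; prefer two-letter matches (Cl, Br, se, as ...)
        sym2 = self.text[self.i : self.i + 2]
        sym1 = self.peek()
        aromatic = False
        if sym2 in _AROMATIC_BRACKET:
            elem = atomic_number(sym2.capitalize())
            aromatic = True
            self.i += 2
        elif len(sym2) == 2 and sym2[0].isupper() and sym2[1].islower() and sym2 in ATOMIC_NUMBERS:
            elem = atomic_number(sym2)
            self.i += 2
        elif sym1 in _AROMATIC_BRACKET:
            elem = atomic_number(sym1.upper())
            aromatic = True
            self.i += 1
        elif sym1.isupper() and sym1 in ATOMIC_NUMBERS:
            elem = atomic_number(sym1)
            self.i += 1
        else:
            raise self.error("expected element symbol in bracket atom")
        if aromatic and elem not in AROMATIC_ELEMENTS:
            raise self.error(f"element {symbol(elem)} cannot be aromatic", start)
        # chirality
        chiral = 0
        if self.peek() == "@":
            self.take()
            if self.peek() == "@":
                self.take()
                chiral = CLOCKWISE
            else:
                chiral = ANTICLOCKWISE
        # hydrogen count
        hcount = 0
        if self.peek() == "H":
            self.take()
            ds = self.digits()
            hcount = int(ds) if ds else 1
        # charge
        charge = 0
        if self.peek() and self.peek() in "+-":
            sign = 1 if self.take() == "+" else -1
            ds = self.digits()
            if ds:
                charge = sign * int(ds)
            else:
                charge = sign
                while self.peek() and self.peek() in "+-":
                    nxt = self.take()
                    if (nxt == "+") != (sign > 0):
                        raise self.error("mixed charge signs")
                    charge += sign
        # atom class (parsed, not retained)
        if self.peek() == ":":
            self.take()
            if not self.digits():
                raise self.error("atom class ':' requires digits")
        if self.take() != "]":
            raise self.error("expected ']'", start)
        atom = Atom(elem, isotope=isotope, charge=charge, implicit_h=hcount, aromatic=aromatic)
        self.add_atom(atom, h_placeholder=chiral != 0 and hcount == 1)
        self.explicit_h.add(len(self.mol) - 1)
        if chiral:
            self.chiral[len(self.mol) - 1] = chiral

    # -- post-processing ---------------------------------------------

    def finish(self) -> Molecule:
        mol = self.mol
        if any(a.aromatic for a in mol.atoms) or any(
            b.order is BondOrder.UNSET for b in mol.bonds
        ):
            kekulize(mol)
        infer_implicit_hydrogens(mol)
        self.check_bracket_valences()
        self.build_tetrahedral()
        self.build_cis_trans()
        return mol

    def check_bracket_valences(self) -> None:
        for i in self.explicit_h:
            atom = self.mol.atoms[i]
            valences = legal_valences(atom.element, atom.charge)
            if valences is None:
                continue
            total = self.mol.bond_order_sum(i) + (atom.implicit_h or 0)
            if total not in valences:
                raise TypingError(
                    f"atom {i} ({atom.symbol}) has valence {total}; legal "
                    f"valences are {valences}",
                    i,
                )

    def build_tetrahedral(self) -> None:
        for idx, config in self.chiral.items():
            carriers = []
            for slot in self.slots[idx]:
                if slot == "H":
                    carriers.append(idx)
                elif isinstance(slot, _RingSlot):
                    carriers.append(slot.partner)
                else:
                    carriers.append(slot)
            if len(carriers) != 4:
                raise SmilesParseError(
                    f"tetrahedral atom {idx} has {len(carriers)} neighbors; "
                    "exactly 4 are required",
                    0,
                )
            self.mol.add_stereo(
                StereoElement(StereoType.TETRAHEDRAL, idx, tuple(carriers), config)
            )

    def _bond_dir(self, key: frozenset[int]) -> int | None:
        """Orientation t = u(min, max) for a directional bond; None if the
        bond carries no directional symbol."""
        records = self.directions.get(key)
        if records is None:
            return None
        lo = min(key)
        value = None
        for from_atom, sym, pos in records:
            f = 1 if sym == "/" else -1
            t = f if from_atom == lo else -f
            if value is None:
                value = t
            elif value != t:
                raise SmilesParseError("conflicting directional bonds", pos)
        return value

    def build_cis_trans(self) -> None:
        mol = self.mol
        for key in sorted(self.explicit_double, key=sorted):
            a, b = sorted(key)
            refs = []
            for focus_atom in (a, b):
                side = []
                for nb in mol.neighbors(focus_atom):
                    if nb in (a, b):
                        continue
                    t = self._bond_dir(frozenset((focus_atom, nb)))
                    if t is not None:
                        u = t if nb == min(nb, focus_atom) else -t
                        side.append((nb, u))
                side.sort()
                if len(side) == 2 and side[0][1] == side[1][1]:
                    raise SmilesParseError(
                        f"conflicting directional bonds around double bond "
                        f"{a}-{b}",
                        0,
                    )
                refs.append(side[0] if side else None)
            if refs[0] is None or refs[1] is None:
                continue
            (x1, u1), (x2, u2) = refs
            config = TOGETHER if u1 == u2 else OPPOSITE
            mol.add_stereo(
                StereoElement(StereoType.CIS_TRANS_DB, (a, b), (x1, x2), config)
            )


def parse(text: str) -> Molecule:
    """Parse a SMILES string into a kekulized molecule with inferred
    hydrogens and stereo elements."""
    return _Parser(text).parse()


# ----------------------------------------------------------------------
# Canonical ranks
# ----------------------------------------------------------------------


def _initial_invariants(mol: Molecule) -> list[tuple]:
    if any(b.in_ring is None for b in mol.bonds):
        mark_rings(mol)
    inv = []
    for i, atom in enumerate(mol.atoms):
        ring = any(b.in_ring for b in mol.bonds_of(i))
        inv.append((atom.element, atom.charge, mol.degree(i), ring, mol.total_h(i)))
    return inv


def _refine(mol: Molecule, keys: list) -> list[int]:
    """Iterated neighbourhood refinement; returns dense ranks."""
    ranks = _dense(keys)
    n = len(ranks)
    while True:
        keys2 = [
            (
                ranks[i],
                tuple(
                    sorted(
                        (int(b.order), ranks[b.other(i)]) for b in mol.bonds_of(i)
                    )
                ),
            )
            for i in range(n)
        ]
        new = _dense(keys2)
        if new == ranks:
            return ranks
        ranks = new


def _dense(keys: list) -> list[int]:
    order = sorted(set(keys))
    index = {k: r for r, k in enumerate(order)}
    return [index[k] for k in keys]


def canonical_ranks(mol: Molecule) -> list[int]:
    """Renumbering-invariant atom ranks from iterated refinement over
    (element, charge, degree, ring membership, attached hydrogens).

    Symmetric atoms (same orbit) share a rank; see the writer for the
    deterministic tie-breaking used to serialize."""
    if len(mol) == 0:
        return []
    return _refine(mol, _initial_invariants(mol))


def _rooted_signature(mol: Molecule, ranks: list[int], root: int) -> tuple:
    """An invariant fingerprint of the graph as seen from ``root``, used
    to pick which tied atom to individualize first."""
    dist = {root: 0}
    frontier = [root]
    while frontier:
        nxt = []
        for u in frontier:
            for v in mol.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    nodes = tuple(sorted((dist.get(i, -1), r) for i, r in enumerate(ranks)))
    edges = tuple(
        sorted(
            (
                min(dist.get(b.begin, -1), dist.get(b.end, -1)),
                max(dist.get(b.begin, -1), dist.get(b.end, -1)),
                int(b.order),
                min(ranks[b.begin], ranks[b.end]),
                max(ranks[b.begin], ranks[b.end]),
            )
            for b in mol.bonds
        )
    )
    return (nodes, edges)


def _discrete_ranks(mol: Molecule) -> list[int]:
    """Refinement ranks individualized to a discrete (all-distinct)
    ordering; ties are broken by the smallest rooted signature so the
    result is independent of input numbering (automorphic atoms excepted,
    where any choice yields the same serialization)."""
    n = len(mol)
    ranks = canonical_ranks(mol)
    while True:
        counts: dict[int, int] = {}
        for r in ranks:
            counts[r] = counts.get(r, 0) + 1
        tied = sorted(r for r, c in counts.items() if c > 1)
        if not tied:
            return ranks
        target = tied[0]
        members = [i for i in range(n) if ranks[i] == target]
        chosen = min(members, key=lambda i: _rooted_signature(mol, ranks, i))
        keys = [(ranks[i], 0 if i == chosen else 1) for i in range(n)]
        ranks = _refine(mol, keys)


# ----------------------------------------------------------------------
# Writer
# ----------------------------------------------------------------------


class _Writer:
    def __init__(self, mol: Molecule, flavor: SmilesFlavor) -> None:
        self.mol = mol
        self.flavor = flavor
        self.order = (
            _discrete_ranks(mol) if flavor.canonical else list(range(len(mol)))
        )
        self.tetra = (
            {e.focus: e for e in mol.stereo if e.stype is StereoType.TETRAHEDRAL}
            if flavor.stereo
            else {}
        )
        self.cis_trans = (
            [e for e in mol.stereo if e.stype is StereoType.CIS_TRANS_DB]
            if flavor.stereo
            else []
        )
        self.dir_values = self._solve_directions()
        self.pos: dict[int, int] = {}  # DFS visit order
        self.tree: dict[int, list[int]] = {}
        self.opens: dict[int, list[int]] = {}  # opener -> later partners
        self.closes: dict[int, list[int]] = {}  # closer -> earlier partners
        self.ring_digits: dict[frozenset[int], int] = {}
        self.free_digits = list(range(1, 100))
        self.token_index: dict[int, int] = {}
        self.pieces: list[str] = []

    # -- double-bond direction assignment ----------------------------

    def _lo(self, key: frozenset[int]) -> int:
        """Reference endpoint of a bond for direction bookkeeping: the one
        with the smaller output rank, so the assignment (and hence the
        emitted string) is invariant under input renumbering."""
        u, v = key
        return u if self.order[u] < self.order[v] else v

    def _solve_directions(self) -> dict[frozenset[int], int]:
        """2-colour the directional-bond constraint graph; a conflict means
        the stereo cannot be expressed consistently."""
        values: dict[frozenset[int], int] = {}
        # canonical processing order and orientation, so the free choice
        # of the first directional symbol is renumbering-invariant
        elements = sorted(
            self.cis_trans,
            key=lambda e: sorted(self.order[i] for i in e.focus),  # type: ignore[union-attr]
        )
        for element in elements:
            a, b = element.focus  # type: ignore[misc]
            x1, x2 = element.carriers
            if self.order[a] > self.order[b]:
                a, b = b, a
                x1, x2 = x2, x1
            k1 = frozenset((x1, a if x1 in self.mol.neighbors(a) else b))
            k2 = frozenset((x2, b if x2 in self.mol.neighbors(b) else a))
            s1 = 1 if x1 == self._lo(k1) else -1
            s2 = 1 if x2 == self._lo(k2) else -1
            rel = 1 if element.configuration == TOGETHER else -1
            # constraint: (s1*t1) == rel * (s2*t2)
            if k1 in values and k2 in values:
                if s1 * values[k1] != rel * s2 * values[k2]:
                    raise MolkitError(
                        "inconsistent double-bond stereo: directional bond "
                        "assignment has no solution"
                    )
            elif k1 in values:
                values[k2] = s2 * rel * s1 * values[k1]
            elif k2 in values:
                values[k1] = s1 * rel * s2 * values[k2]
            else:
                values[k1] = 1
                values[k2] = s2 * rel * s1
        return values

    # -- pass 1: plan the DFS tree and classify back edges -----------

    def _plan(self) -> list[int]:
        """Depth-first plan: tree children per atom (ordered by rank) and
        back-edge classification (the earlier-visited endpoint opens the
        ring digit).  Returns the component roots in emission order."""
        n = len(self.mol)
        roots = []
        classified: set[frozenset[int]] = set()
        for root in sorted(range(n), key=lambda i: self.order[i]):
            if root in self.pos:
                continue
            roots.append(root)
            stack: list[tuple[int, list[int]]] = [
                (root, self._sorted_neighbors(root))
            ]
            self.pos[root] = len(self.pos)
            while stack:
                u, nbs = stack[-1]
                if not nbs:
                    stack.pop()
                    continue
                v = nbs.pop(0)
                key = frozenset((u, v))
                if key in classified:
                    continue
                classified.add(key)
                if v in self.pos:
                    # back edge: v was visited first, so v opens the digit
                    self.opens.setdefault(v, []).append(u)
                    self.closes.setdefault(u, []).append(v)
                else:
                    self.pos[v] = len(self.pos)
                    self.tree.setdefault(u, []).append(v)
                    stack.append((v, self._sorted_neighbors(v)))
        for v, later in self.opens.items():
            later.sort(key=lambda u: self.pos[u])
        return roots

    def _sorted_neighbors(self, atom: int) -> list[int]:
        return sorted(self.mol.neighbors(atom), key=lambda v: self.order[v])

    # -- pass 2: emission --------------------------------------------

    def write(self) -> str:
        roots = self._plan()
        for k, root in enumerate(roots):
            if k:
                self.pieces.append(".")
            self._emit(root, None)
        return "".join(self.pieces)

    def _emit(self, atom: int, parent: int | None) -> None:
        slots: list = []
        if parent is not None:
            self.pieces.append(
                self._bond_symbol(self.mol.bond(parent, atom), parent, atom)
            )
            slots.append(parent)
        token, has_h_slot = self._atom_token(atom)
        self.token_index[atom] = len(self.pieces)
        self.pieces.append(token)
        if has_h_slot:
            slots.append("H")

        # close ring digits opened towards us (ascending digit order)
        closings = sorted(
            (self.ring_digits[frozenset((atom, e))], e)
            for e in self.closes.get(atom, ())
        )
        for digit, partner in closings:
            self.pieces.append(self._digit_token(digit))
            slots.append(partner)
            heapq.heappush(self.free_digits, digit)
        # open ring digits towards later atoms
        for v in self.opens.get(atom, ()):
            if not self.free_digits:
                raise MolkitError("more than 99 open ring closures")
            digit = heapq.heappop(self.free_digits)
            self.ring_digits[frozenset((atom, v))] = digit
            self.pieces.append(
                self._bond_symbol(self.mol.bond(atom, v), atom, v)
            )
            self.pieces.append(self._digit_token(digit))
            slots.append(v)

        children = self.tree.get(atom, [])
        for k, v in enumerate(children):
            last = k == len(children) - 1
            if not last:
                self.pieces.append("(")
            slots.append(v)
            self._emit(v, atom)
            if not last:
                self.pieces.append(")")

        self._patch_stereo(atom, slots)

    @staticmethod
    def _digit_token(digit: int) -> str:
        return str(digit) if digit < 10 else f"%{digit:02d}"

    def _bond_symbol(self, bond, frm: int, to: int) -> str:
        if bond is None:
            return ""
        key = frozenset((frm, to))
        if self.flavor.aromatic_output and bond.aromatic:
            return ""
        if bond.order is BondOrder.SINGLE:
            t = self.dir_values.get(key)
            if t is not None:
                f = t if frm == self._lo(key) else -t
                return "/" if f == 1 else "\\"
            if (
                self.flavor.aromatic_output
                and self.mol.atoms[frm].aromatic
                and self.mol.atoms[to].aromatic
            ):
                return "-"
            return ""
        if bond.order is BondOrder.DOUBLE:
            return "="
        if bond.order is BondOrder.TRIPLE:
            return "#"
        raise MolkitError(f"bond {frm}-{to} has unset order; kekulize before writing")

    def _default_h(self, atom_index: int) -> int:
        atom = self.mol.atoms[atom_index]
        total = self.mol.bond_order_sum(atom_index)
        if self.flavor.aromatic_output and atom.aromatic and atom.element != 6:
            return 0
        valences = legal_valences(atom.element, atom.charge)
        if not valences:
            return 0
        for v in valences:
            if v >= total:
                return v - total
        return 0

    def _atom_token(self, atom_index: int) -> tuple[str, bool]:
        atom = self.mol.atoms[atom_index]
        aromatic = self.flavor.aromatic_output and atom.aromatic
        sym = atom.symbol.lower() if aromatic else atom.symbol
        organic = atom.symbol in ORGANIC_SUBSET
        h = atom.implicit_h or 0
        stereo_here = atom_index in self.tetra
        isotope = atom.isotope if self.flavor.isotopes else None
        need_bracket = (
            not organic
            or atom.charge != 0
            or isotope is not None
            or stereo_here
            or h != self._default_h(atom_index)
        )
        if not need_bracket:
            return sym, False
        parts = ["["]
        if isotope is not None:
            parts.append(str(isotope))
        parts.append(sym)
        if stereo_here:
            parts.append("\x00")  # placeholder patched once order is known
        if h == 1:
            parts.append("H")
        elif h > 1:
            parts.append(f"H{h}")
        q = atom.charge
        if q:
            sign = "+" if q > 0 else "-"
            parts.append(sign if abs(q) == 1 else f"{sign}{abs(q)}")
        parts.append("]")
        return "".join(parts), stereo_here and h == 1

    def _patch_stereo(self, atom: int, slots: list) -> None:
        element = self.tetra.get(atom)
        if element is None:
            return
        written = [atom if s == "H" else s for s in slots]
        stored = list(element.carriers)
        if sorted(_pos(written)) != sorted(_pos(stored)):
            raise MolkitError(
                f"stereo carriers of atom {atom} do not match its neighbors"
            )
        parity = permutation_parity(_pos(stored), _pos(written))
        config = element.configuration if parity == 1 else 3 - element.configuration
        tag = "@" if config == ANTICLOCKWISE else "@@"
        i = self.token_index[atom]
        self.pieces[i] = self.pieces[i].replace("\x00", tag, 1)


def _pos(items: list[int]) -> list[tuple[int, int]]:
    seen: dict[int, int] = {}
    out = []
    for item in items:
        k = seen.get(item, 0)
        seen[item] = k + 1
        out.append((item, k))
    return out


def write(mol: Molecule, flavor: str | SmilesFlavor = "generic") -> str:
    """Serialize a molecule to SMILES in the requested flavour."""
    if isinstance(flavor, str):
        flavor = SmilesFlavor.named(flavor)
    return _Writer(mol, flavor).write()
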