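"""Molecular graph data model with relative stereochemistry.

A :class:`Molecule` is an indexed atom/bond graph.  Stereochemistry is
stored at the molecule level as :class:`StereoElement` records describing
local geometry by a type, a focus, an ordered list of carriers and a
configuration.  Only the type and focus are absolute: the carriers and the
configuration label are *relative* — reordering the carriers by an odd
permutation while flipping the configuration describes the same geometry.
For tetrahedral centres with a suppressed hydrogen the focus index is
reused inside the carrier list as a placeholder for that hydrogen.
"""

from __future__ import annotations


from dataclasses import dataclass
from enum import Enum, IntEnum
from typing import Iterable, Iterator, Sequence

from .elements import symbol

__all__ = [
    "BondOrder",
    "StereoType",
    "ANTICLOCKWISE",
    "CLOCKWISE",
    "TOGETHER",
    "OPPOSITE",
    "Isotope",
    "Atom",
    "Bond",
    "StereoElement",
    "Molecule",
    "permutation_parity",
    "stereo_equivalent",
    "heavy_atom_count",
]


class BondOrder(IntEnum):
    """Bond order; UNSET is legal only transiently between aromatic
    parsing and kekulization."""

    UNSET = 0
    SINGLE = 1
    DOUBLE = 2
    TRIPLE = 3


class StereoType(Enum):
    TETRAHEDRAL = "tetrahedral"
    CIS_TRANS_DB = "cis_trans_db"
    EXTENDED_TETRAHEDRAL = "extended_tetrahedral"
    # Reserved: representable but rejected by all algorithms.
    SQUARE_PLANAR = "square_planar"
    TRIGONAL_BIPYRAMIDAL = "trigonal_bipyramidal"
    OCTAHEDRAL = "octahedral"


#: Tetrahedral configurations (viewed from the first carrier).
ANTICLOCKWISE = 1
CLOCKWISE = 2
#: Double-bond configurations (the two carriers relative to the axis).
TOGETHER = 1
OPPOSITE = 2

_CARRIER_COUNT = {
    StereoType.TETRAHEDRAL: 4,
    StereoType.EXTENDED_TETRAHEDRAL: 4,
    StereoType.CIS_TRANS_DB: 2,
}


@dataclass(frozen=True)
class Isotope:
    """A nuclide: element, mass number, exact mass (Da) and natural
    abundance.  ``mass_number`` None denotes the natural mixture."""

    symbol: str
    atomic_number: int
    mass_number: int | None
    exact_mass: float
    abundance: float

    def __post_init__(self) -> None:
        if self.exact_mass <= 0:
            raise ValueError("exact_mass must be positive")
        if not 0.0 <= self.abundance <= 1.0:
            raise ValueError("abundance must lie in [0, 1]")


@dataclass
class Atom:
    element: int
    isotope: int | None = None
    charge: int = 0
    implicit_h: int | None = None
    aromatic: bool = False

    @property
    def symbol(self) -> str:
        return symbol(self.element)


@dataclass
class Bond:
    begin: int
    end: int
    order: BondOrder = BondOrder.SINGLE
    aromatic: bool = False
    in_ring: bool | None = None

    def other(self, index: int) -> int:
        if index == self.begin:
            return self.end
        if index == self.end:
            return self.begin
        raise ValueError(f"atom {index} is not an endpoint of this bond")


@dataclass(frozen=True)
class StereoElement:
    """Relative stereo descriptor.

    ``focus`` is an atom index for tetrahedral-like types and an
    ``(atom, atom)`` pair for double-bond stereo.  The focus index may
    appear once among the carriers of a tetrahedral element as a
    placeholder for a suppressed hydrogen.
    """

    stype: StereoType
    focus: int | tuple[int, int]
    carriers: tuple[int, ...]
    configuration: int

    def __post_init__(self) -> None:
        expected = _CARRIER_COUNT.get(self.stype)
        if expected is not None and len(self.carriers) != expected:
            raise ValueError(
                f"{self.stype.value} stereo requires {expected} carriers, "
                f"got {len(self.carriers)}"
            )
        if self.configuration not in (1, 2):
            raise ValueError("configuration must be 1 or 2")

    def with_carriers(self, carriers: Sequence[int], configuration: int) -> "StereoElement":
        return StereoElement(self.stype, self.focus, tuple(carriers), configuration)


class Molecule:
    """An indexed molecular graph.

    Atoms are addressed by their 0-based position; bonds keep begin/end
    indices and the adjacency is kept symmetric by construction.
    """

    def __init__(self, title: str = "") -> None:
        self.atoms: list[Atom] = []
        self.bonds: list[Bond] = []
        self.stereo: list[StereoElement] = []
        self.title = title
        self.properties: dict[str, str] = {}
        self._adj: list[dict[int, int]] = []  # neighbor -> bond index

    # -- construction ------------------------------------------------

    def add_atom(self, atom: Atom | int, **kwargs) -> int:
        if isinstance(atom, int):
            atom = Atom(atom, **kwargs)
        self.atoms.append(atom)
        self._adj.append({})
        return len(self.atoms) - 1

    def add_bond(
        self,
        begin: int,
        end: int,
        order: BondOrder = BondOrder.SINGLE,
        aromatic: bool = False,
    ) -> Bond:
        n = len(self.atoms)
        if begin == end:
            raise ValueError("self-bonds are not allowed")
        if not (0 <= begin < n and 0 <= end < n):
            raise IndexError("bond endpoint out of range")
        if end in self._adj[begin]:
            raise ValueError(f"duplicate bond {begin}-{end}")
        bond = Bond(begin, end, BondOrder(order), aromatic)
        self.bonds.append(bond)
        self._adj[begin][end] = len(self.bonds) - 1
        self._adj[end][begin] = len(self.bonds) - 1
        return bond

    def add_stereo(self, element: StereoElement) -> None:
        self._check_stereo(element)
        self.stereo.append(element)

    def _check_stereo(self, element: StereoElement) -> None:
        n = len(self.atoms)
        if element.stype is StereoType.CIS_TRANS_DB:
            a, b = element.focus  # type: ignore[misc]
            if self.bond(a, b) is None:
                raise ValueError(f"no double bond {a}-{b} for cis/trans stereo")
            ends = set(self.neighbors(a)) | set(self.neighbors(b))
            for c in element.carriers:
                if c not in ends:
                    raise ValueError(f"carrier {c} is not attached to the double bond")
        else:
            focus = element.focus
            if not isinstance(focus, int) or not 0 <= focus < n:
                raise ValueError("stereo focus out of range")
            allowed = set(self.neighbors(focus)) | {focus}
            if element.stype is StereoType.EXTENDED_TETRAHEDRAL:
                for nb in self.neighbors(focus):
                    allowed |= set(self.neighbors(nb))
            for c in element.carriers:
                if c not in allowed:
                    raise ValueError(f"carrier {c} is not the focus or a neighbor")

    # -- queries -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    def neighbors(self, index: int) -> list[int]:
        return list(self._adj[index])

    def degree(self, index: int) -> int:
        return len(self._adj[index])

    def bond(self, begin: int, end: int) -> Bond | None:
        idx = self._adj[begin].get(end)
        return None if idx is None else self.bonds[idx]

    def bonds_of(self, index: int) -> Iterator[Bond]:
        for bi in self._adj[index].values():
            yield self.bonds[bi]

    def bond_order_sum(self, index: int) -> int:
        """Sum of explicit bond orders at an atom; UNSET orders raise."""
        total = 0
        for bond in self.bonds_of(index):
            if bond.order is BondOrder.UNSET:
                raise ValueError(
                    f"atom {index} has a bond with unset order; kekulize first"
                )
            total += int(bond.order)
        return total

    def total_h(self, index: int) -> int:
        """Implicit plus explicit hydrogen neighbours."""
        atom = self.atoms[index]
        h = atom.implicit_h or 0
        h += sum(1 for nb in self.neighbors(index) if self.atoms[nb].element == 1)
        return h

    # -- transforms --------------------------------------------------

    def copy(self) -> "Molecule":
        out = Molecule(self.title)
        out.properties = dict(self.properties)
        for atom in self.atoms:
            out.add_atom(
                Atom(atom.element, atom.isotope, atom.charge, atom.implicit_h, atom.aromatic)
            )
        for bond in self.bonds:
            nb = out.add_bond(bond.begin, bond.end, bond.order, bond.aromatic)
            nb.in_ring = bond.in_ring
        out.stereo = list(self.stereo)
        return out

    def permuted(self, perm: Sequence[int]) -> "Molecule":
        """Renumber atoms: the atom currently at ``i`` moves to ``perm[i]``.

        Stereo elements are remapped index-wise; because carriers travel
        with their atoms the described geometry is unchanged.
        """
        n = len(self.atoms)
        if sorted(perm) != list(range(n)):
            raise ValueError("perm is not a permutation of atom indices")
        inv = [0] * n
        for old, new in enumerate(perm):
            inv[new] = old
        out = Molecule(self.title)
        out.properties = dict(self.properties)
        for new in range(n):
            atom = self.atoms[inv[new]]
            out.add_atom(
                Atom(atom.element, atom.isotope, atom.charge, atom.implicit_h, atom.aromatic)
            )
        for bond in self.bonds:
            nb = out.add_bond(perm[bond.begin], perm[bond.end], bond.order, bond.aromatic)
            nb.in_ring = bond.in_ring
        for el in self.stereo:
            if el.stype is StereoType.CIS_TRANS_DB:
                a, b = el.focus  # type: ignore[misc]
                focus: int | tuple[int, int] = (perm[a], perm[b])
            else:
                focus = perm[el.focus]  # type: ignore[index]
            out.stereo.append(
                StereoElement(el.stype, focus, tuple(perm[c] for c in el.carriers), el.configuration)
            )
        return out


def permutation_parity(a: Sequence, b: Sequence) -> int:
    """+1 if ``b`` is an even permutation of ``a``, -1 if odd.

    Items must be distinct; a placeholder appearing twice must be
    disambiguated by position before calling.
    """
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    pos = {}
    for i, item in enumerate(a):
        if item in pos:
            raise ValueError(f"duplicate item {item!r}")
        pos[item] = i
    try:
        mapping = [pos[item] for item in b]
    except KeyError as exc:
        raise ValueError(f"{exc.args[0]!r} not present in first sequence") from None
    if len(set(mapping)) != len(mapping):
        raise ValueError("second sequence is not a permutation of the first")
    # parity = (-1) ** (n - number of cycles)
    seen = [False] * len(mapping)
    cycles = 0
    for i in range(len(mapping)):
        if seen[i]:
            continue
        cycles += 1
        j = i
        while not seen[j]:
            seen[j] = True
            j = mapping[j]
    return 1 if (len(mapping) - cycles) % 2 == 0 else -1


def _positional(carriers: Iterable[int]) -> list[tuple[int, int]]:
    # Resolve placeholder duplicates (the focus reused for a suppressed H)
    # by pairing each item with its occurrence number.
    seen: dict[int, int] = {}
    out = []
    for c in carriers:
        k = seen.get(c, 0)
        seen[c] = k + 1
        out.append((c, k))
    return out


def stereo_equivalent(e1: StereoElement, e2: StereoElement) -> bool:
    """Whether two stereo descriptors of the same focus describe the same
    geometry: configurations must agree after multiplying by the parity of
    the carrier permutation."""
    if e1.stype is not e2.stype:
        raise ValueError("stereo elements have different types")
    if e1.focus != e2.focus:
        raise ValueError("stereo elements have different foci")
    parity = permutation_parity(_positional(e1.carriers), _positional(e2.carriers))
    if parity == 1:
        return e1.configuration == e2.configuration
    return e1.configuration != e2.configuration


def heavy_atom_count(mol: Molecule) -> int:
    """Number of non-hydrogen atoms."""
    return sum(1 for atom in mol.atoms if atom.element != 1)
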