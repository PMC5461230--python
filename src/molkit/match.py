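"""Substructure matching with immutable patterns and lazy iteration.

A :class:`Pattern` is compiled once from a query graph and can then be
matched against any number of targets.  Compilation inspects the query to
record which target invariants (ring flags, aromaticity) will be needed,
so only those are computed on each target.  Matching is a VF2-style
backtracking search that yields mappings lazily: requesting the first k
matches does no work beyond the k-th.  Query stereochemistry, when
present and enabled, is enforced by comparing configurations under the
permutation parity of the atom mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

from .aromaticity import find_aromatic
from .errors import MolkitError
from .model import (
    BondOrder,
    Molecule,
    StereoElement,
    StereoType,
    stereo_equivalent,
)
from .rings import mark_rings

__all__ = ["QueryAtom", "QueryBond", "Pattern"]


@dataclass(frozen=True)
class QueryAtom:
    """Conjunction of per-atom predicates; None means "any"."""

    element: int | None = None
    aromatic: bool | None = None
    in_ring: bool | None = None
    charge: int | None = None
    degree: int | None = None
    total_h: int | None = None
    wildcard: bool = False

    def __post_init__(self) -> None:
        if self.wildcard and any(
            p is not None
            for p in (self.element, self.aromatic, self.in_ring, self.charge,
                      self.degree, self.total_h)
        ):
            raise ValueError("a wildcard query atom excludes other predicates")

    def matches(self, mol: Molecule, index: int) -> bool:
        if self.wildcard:
            return True
        atom = mol.atoms[index]
        if self.element is not None and atom.element != self.element:
            return False
        if self.aromatic is not None and atom.aromatic != self.aromatic:
            return False
        if self.charge is not None and atom.charge != self.charge:
            return False
        if self.degree is not None and mol.degree(index) != self.degree:
            return False
        if self.total_h is not None and mol.total_h(index) != self.total_h:
            return False
        if self.in_ring is not None:
            ring = any(b.in_ring for b in mol.bonds_of(index))
            if ring != self.in_ring:
                return False
        return True


@dataclass(frozen=True)
class QueryBond:
    """Bond predicate: order (None = any) and aromaticity (None = any)."""

    order: BondOrder | None = BondOrder.SINGLE
    aromatic: bool | None = None

    def matches(self, mol: Molecule, a: int, b: int) -> bool:
        bond = mol.bond(a, b)
        if bond is None:
            return False
        if self.aromatic is not None and bond.aromatic != self.aromatic:
            return False
        if self.order is not None and bond.order != self.order:
            return False
        return True


class Pattern:
    """An immutable compiled substructure query."""

    def __init__(
        self,
        atoms: Sequence[QueryAtom],
        bonds: dict[tuple[int, int], QueryBond],
        stereo: Sequence[StereoElement] = (),
        enforce_stereo: bool = True,
    ) -> None:
        if not atoms:
            raise MolkitError("cannot compile an empty query")
        self._atoms = tuple(atoms)
        self._bonds = {
            (min(a, b), max(a, b)): qb for (a, b), qb in bonds.items()
        }
        self._adj: list[list[int]] = [[] for _ in atoms]
        for a, b in self._bonds:
            self._adj[a].append(b)
            self._adj[b].append(a)
        self._stereo = tuple(stereo) if enforce_stereo else ()
        self.required_invariants = frozenset(self._inspect())
        self._order = self._search_order()

    # -- compilation --------------------------------------------------

    @staticmethod
    def compile(
        query: Molecule,
        overrides: dict[int, QueryAtom] | None = None,
        enforce_stereo: bool = True,
    ) -> "Pattern":
        """Compile a molecule into a pattern.

        Each atom becomes an (element, aromatic, charge) predicate unless
        an override supplies a custom :class:`QueryAtom`; bonds match on
        order, aromatic bonds on aromaticity.
        """
        overrides = overrides or {}
        atoms = [
            overrides.get(
                i,
                QueryAtom(
                    element=a.element,
                    # aliphatic atoms leave aromaticity unconstrained so the
                    # pattern does not force target perception
                    aromatic=True if a.aromatic else None,
                    charge=a.charge,
                ),
            )
            for i, a in enumerate(query.atoms)
        ]
        bonds = {}
        for b in query.bonds:
            if b.aromatic:
                qb = QueryBond(order=None, aromatic=True)
            else:
                # match on kekulé order only; aromaticity left unconstrained
                # so purely aliphatic queries need no target invariants
                qb = QueryBond(order=b.order, aromatic=None)
            bonds[(b.begin, b.end)] = qb
        return Pattern(atoms, bonds, query.stereo, enforce_stereo)

    @staticmethod
    def from_smiles(smiles: str, enforce_stereo: bool = True) -> "Pattern":
        from .smiles import parse

        return Pattern.compile(parse(smiles), enforce_stereo=enforce_stereo)

    def _inspect(self) -> set[str]:
        needed = set()
        if any(a.in_ring is not None for a in self._atoms):
            needed.add("ring_flags")
        if any(a.aromatic is not None for a in self._atoms) or any(
            qb.aromatic is not None for qb in self._bonds.values()
        ):
            needed.add("aromaticity")
        return needed

    def _rarity(self, qa: QueryAtom) -> tuple:
        # rarest-first heuristic: specific predicates before wildcards
        specificity = sum(
            p is not None
            for p in (qa.element, qa.aromatic, qa.in_ring, qa.charge,
                      qa.degree, qa.total_h)
        )
        common = qa.element in (6, 1)
        return (qa.wildcard, common, -specificity)

    def _search_order(self) -> list[tuple[int, int | None]]:
        """Query atom visit order as (atom, connected-parent-or-None),
        starting from the rarest atom and growing connectedly."""
        n = len(self._atoms)
        remaining = set(range(n))
        order: list[tuple[int, int | None]] = []
        placed: set[int] = set()
        while remaining:
            frontier = [
                (q, p)
                for q in remaining
                for p in self._adj[q]
                if p in placed
            ]
            if frontier:
                q, p = min(
                    frontier, key=lambda t: (self._rarity(self._atoms[t[0]]), t[0])
                )
            else:
                q = min(remaining, key=lambda i: (self._rarity(self._atoms[i]), i))
                p = None
            order.append((q, p))
            placed.add(q)
            remaining.remove(q)
        return order

    # -- matching -----------------------------------------------------

    def _prepare(self, target: Molecule) -> None:
        if "ring_flags" in self.required_invariants or "aromaticity" in self.required_invariants:
            if any(b.in_ring is None for b in target.bonds):
                mark_rings(target)
        if "aromaticity" in self.required_invariants:
            if not getattr(target, "_aromaticity_perceived", False):
                find_aromatic(target)
                target._aromaticity_perceived = True  # type: ignore[attr-defined]

    def match_iter(
        self, target: Molecule, counter: list[int] | None = None
    ) -> Iterator[dict[int, int]]:
        """Lazily yield injective, bond-preserving query->target mappings.

        ``counter`` (if given) accumulates the number of candidate node
        visits in ``counter[0]`` — an instrumentation hook for verifying
        the lazy contract.
        """
        self._prepare(target)
        n = len(self._atoms)
        mapping: dict[int, int] = {}
        used: set[int] = set()

        def candidates(step: int) -> Iterator[int]:
            q, p = self._order[step]
            if p is not None:
                return iter(sorted(target.neighbors(mapping[p])))
            return iter(range(len(target)))

        def extend(step: int) -> Iterator[dict[int, int]]:
            if step == n:
                if self._stereo_ok(target, mapping):
                    yield dict(mapping)
                return
            q, _ = self._order[step]
            qa = self._atoms[q]
            for t in candidates(step):
                if counter is not None:
                    counter[0] += 1
                if t in used or not qa.matches(target, t):
                    continue
                ok = True
                for qn in self._adj[q]:
                    if qn in mapping:
                        qb = self._bonds[(min(q, qn), max(q, qn))]
                        if not qb.matches(target, t, mapping[qn]):
                            ok = False
                            break
                if not ok:
                    continue
                mapping[q] = t
                used.add(t)
                yield from extend(step + 1)
                del mapping[q]
                used.discard(t)

        return extend(0)

    def matches(self, target: Molecule) -> bool:
        return next(self.match_iter(target), None) is not None

    def count(self, target: Molecule) -> int:
        return sum(1 for _ in self.match_iter(target))

    def match_sets(self, target: Molecule) -> set[frozenset[int]]:
        """Distinct matched atom sets (automorphic duplicates collapsed)."""
        return {frozenset(m.values()) for m in self.match_iter(target)}

    # -- stereo -------------------------------------------------------

    def _stereo_ok(self, target: Molecule, mapping: dict[int, int]) -> bool:
        if not self._stereo:
            return True
        target_tetra = {
            e.focus: e for e in target.stereo if e.stype is StereoType.TETRAHEDRAL
        }
        target_db = {
            frozenset(e.focus): e  # type: ignore[arg-type]
            for e in target.stereo
            if e.stype is StereoType.CIS_TRANS_DB
        }
        for e in self._stereo:
            if e.stype is StereoType.TETRAHEDRAL:
                focus_t = mapping[e.focus]  # type: ignore[index]
                te = target_tetra.get(focus_t)
                if te is None:
                    return False
                carriers = tuple(
                    focus_t if c == e.focus else mapping[c] for c in e.carriers
                )
                translated = StereoElement(
                    e.stype, focus_t, carriers, e.configuration
                )
                if not stereo_equivalent(te, translated):
                    return False
            elif e.stype is StereoType.CIS_TRANS_DB:
                a, b = e.focus  # type: ignore[misc]
                key = frozenset((mapping[a], mapping[b]))
                te = target_db.get(key)
                if te is None:
                    return False
                x1, x2 = e.carriers
                if te.focus == (mapping[a], mapping[b]):
                    carriers = (mapping[x1], mapping[x2])
                else:
                    carriers = (mapping[x2], mapping[x1])
                translated = StereoElement(
                    e.stype, te.focus, carriers, e.configuration
                )
                if not stereo_equivalent(te, translated):
                    return False
            else:
                raise MolkitError(
                    f"stereo type {e.stype.value} is not supported in matching"
                )
        return True
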