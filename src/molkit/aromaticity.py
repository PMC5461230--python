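"""Pluggable aromaticity perception and kekulization.

Aromaticity is treated as a model choice: an electron-donation rule maps
each atom to -1 (cannot be aromatic) or the number of pi electrons it
donates (0, 1 or 2), and a cycle-set choice supplies the candidate rings.
Each candidate cycle is aromatic when no member donates -1 and the summed
donation satisfies Hueckel's 4n+2 rule; flags close over fused systems.

Three electron-donation models are provided.  ``daylight_like`` follows
the OpenSMILES donation table expressed over the local graph.  The two
CDK-flavoured models differ only in how a ring atom whose sole double
bond is exocyclic is handled: ``cdk_like`` lets any such atom stay in the
ring donating 0 electrons, while ``cdk_exocyclic`` accepts only exocyclic
double bonds to O or S (carbonyl/thiocarbonyl) and disqualifies the rest.

Kekulization assigns alternating orders to aromatic bonds via a maximum
(blossom) matching over the atoms that require a double bond, then
verifies the claimed aromatic atoms really are aromatic under the
all-cycles Daylight-like model; failing either step rejects the input.
"""

from __future__ import annotations



import networkx as nx

from .errors import KekulizationError
from .model import Bond, BondOrder, Molecule
from .rings import Ring, all_rings, mark_rings, sssr
from .typing import infer_implicit_hydrogens

__all__ = [
    "MODELS",
    "electron_contribution",
    "find_aromatic",
    "kekulize",
]

MODELS = ("daylight_like", "cdk_like", "cdk_exocyclic")
CYCLE_SETS = ("mcb", "all_bounded")

_AROMATIC_CAPABLE = {5, 6, 7, 8, 15, 16, 34}

_ALIASES = {
    "daylight": "daylight_like",
    "cdk": "cdk_like",
    "cdk-exo": "cdk_exocyclic",
}


def _norm_model(model: str) -> str:
    model = _ALIASES.get(model, model)
    if model not in MODELS:
        raise ValueError(f"unknown aromaticity model {model!r}")
    return model


def _ensure_ring_flags(mol: Molecule) -> None:
    if any(b.in_ring is None for b in mol.bonds):
        mark_rings(mol)


def _in_ring(mol: Molecule, index: int) -> bool:
    return any(b.in_ring for b in mol.bonds_of(index))


def electron_contribution(mol: Molecule, index: int, model: str = "daylight_like") -> int:
    """Pi electrons atom ``index`` would donate to an aromatic ring.

    -1 means the atom cannot take part in an aromatic ring at all.
    Requires kekulized bond orders and inferred hydrogens.
    """
    model = _norm_model(model)
    _ensure_ring_flags(mol)
    atom = mol.atoms[index]
    if not _in_ring(mol, index):
        return -1
    if atom.element not in _AROMATIC_CAPABLE:
        return -1

    endo = exo = 0
    exo_partner_elements = []
    for bond in mol.bonds_of(index):
        if bond.order is BondOrder.UNSET:
            raise ValueError(f"atom {index}: bond order unset; kekulize first")
        if bond.order is BondOrder.TRIPLE:
            return -1
        if bond.order is BondOrder.DOUBLE:
            partner = bond.other(index)
            if _in_ring(mol, partner):
                endo += 1
            else:
                exo += 1
                exo_partner_elements.append(mol.atoms[partner].element)
    if endo + exo > 1:
        return -1

    z, q = atom.element, atom.charge
    if endo == 1:
        # One double bond inside the ring system: classic 1-electron donor.
        if (z, q) in {(6, 0), (6, -1), (7, 0), (7, 1), (15, 0), (15, 1),
                      (8, 1), (16, 1), (34, 1)}:
            return 1
        return -1
    if exo == 1:
        if model == "cdk_exocyclic" and exo_partner_elements[0] not in (8, 16):
            return -1
        return 0

    # Saturated ring atom: lone-pair donors give 2, cations 0.
    conn = mol.degree(index) + (atom.implicit_h or 0)
    if z == 6:
        return {1: 0, -1: 2}.get(q, -1)
    if z in (7, 15):
        if q == 0:
            return 2 if conn == 3 else -1
        if q == -1:
            return 2 if conn == 2 else -1
        return -1
    if z in (8, 16, 34):
        if q == 0:
            return 2 if conn == 2 else -1
        if q == 1:
            return 2 if conn == 3 else -1
        return -1
    if z == 5 and q == 0:
        return 0 if conn == 3 else -1
    return -1


def _cycle_set(mol: Molecule, cycles: str) -> list[Ring]:
    if cycles == "mcb":
        return sssr(mol)
    if cycles in ("all_bounded", "all"):
        return list(all_rings(mol).rings)
    raise ValueError(f"unknown cycle set {cycles!r}")


def find_aromatic(
    mol: Molecule,
    model: str = "daylight_like",
    cycles: str = "all_bounded",
) -> tuple[set[int], set[frozenset[int]]]:
    """Perceive aromatic atoms and bonds; flags are written in place.

    A candidate cycle is aromatic iff no member donates -1 electrons and
    the donation sum is 4n+2.  The cycle list is re-scanned until no new
    flags appear so fused systems close.
    """
    model = _norm_model(model)
    _ensure_ring_flags(mol)
    contributions = [electron_contribution(mol, i, model) for i in range(len(mol))]

    arom_atoms: set[int] = set()
    arom_bonds: set[frozenset[int]] = set()
    candidates = _cycle_set(mol, cycles)
    changed = True
    while changed:
        changed = False
        for ring in candidates:
            if set(ring.atoms) <= arom_atoms:
                continue
            contribs = [contributions[i] for i in ring.atoms]
            if any(c < 0 for c in contribs):
                continue
            total = sum(contribs)
            if total >= 2 and total % 4 == 2:
                arom_atoms |= set(ring.atoms)
                arom_bonds |= ring.edges()
                changed = True

    for atom in mol.atoms:
        atom.aromatic = False
    for i in arom_atoms:
        mol.atoms[i].aromatic = True
    for bond in mol.bonds:
        bond.aromatic = frozenset((bond.begin, bond.end)) in arom_bonds
    return arom_atoms, arom_bonds


def _needs_double_bond(mol: Molecule, index: int) -> bool:
    """Whether an aromatic atom must receive one double bond during
    kekulization (i.e. it donates its electron through a pi bond)."""
    atom = mol.atoms[index]
    for bond in mol.bonds_of(index):
        if bond.order in (BondOrder.DOUBLE, BondOrder.TRIPLE):
            return False  # already unsaturated (e.g. exocyclic C=O)
    conn = mol.degree(index) + (atom.implicit_h or 0)
    z, q = atom.element, atom.charge
    if z == 6:
        return q == 0
    if z in (7, 15):
        if q == 0:
            return conn != 3  # pyrrole-type NH/NR donates the lone pair
        if q == 1:
            return conn <= 3
        return False
    if z in (8, 16, 34):
        return q == 1
    return False


def kekulize(mol: Molecule) -> Molecule:
    """Assign single/double orders to aromatic (unset-order) bonds.

    Every aromatic atom that must donate an electron through a pi bond
    gets exactly one double bond, found as a perfect matching on the
    subgraph of such atoms.  After assignment, implicit hydrogens are
    inferred and the claimed aromatic atoms are verified against the
    all-cycles Daylight-like perception; any failure raises
    :class:`KekulizationError`.
    """
    claimed = {i for i, a in enumerate(mol.atoms) if a.aromatic}
    unset = [b for b in mol.bonds if b.order is BondOrder.UNSET]
    for bond in unset:
        if not (mol.atoms[bond.begin].aromatic and mol.atoms[bond.end].aromatic):
            raise KekulizationError(
                f"bond {bond.begin}-{bond.end} has unset order outside an "
                "aromatic system",
                (bond.begin, bond.end),
            )

    needy = {i for i in claimed if _needs_double_bond(mol, i)}
    g = nx.Graph()
    g.add_nodes_from(needy)
    for bond in mol.bonds:
        if bond.aromatic and bond.begin in needy and bond.end in needy:
            g.add_edge(bond.begin, bond.end)
    matching = nx.max_weight_matching(g, maxcardinality=True)
    matched = {a for pair in matching for a in pair}
    if matched != needy:
        missing = tuple(sorted(needy - matched))
        raise KekulizationError(
            f"aromatic system cannot be kekulized; no double bond available "
            f"for atoms {missing}",
            missing,
        )
    matched_edges = {frozenset(pair) for pair in matching}
    for bond in unset:
        key = frozenset((bond.begin, bond.end))
        bond.order = BondOrder.DOUBLE if key in matched_edges else BondOrder.SINGLE

    infer_implicit_hydrogens(mol)
    if claimed:
        perceived, _ = find_aromatic(mol.copy(), "daylight_like", "all_bounded")
        bad = claimed - perceived
        if bad:
            raise KekulizationError(
                f"atoms {tuple(sorted(bad))} are marked aromatic but no "
                "4n+2 cycle supports them",
                tuple(sorted(bad)),
            )
    return mol
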