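"""Deterministic random molecule generator for tests and benchmarks.

Molecules are assembled from valence-respecting building blocks (chain
atoms and ring templates, including aromatic and charged ones) joined at
atoms with spare hydrogens, then decorated with double/triple bonds,
charges and stereo centres — each decoration is committed only if the
resulting atom environments still match the packaged atom-type table, so
every generated molecule passes type validation by construction.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .elements import atomic_number
from .model import (
    Atom,
    BondOrder,
    Molecule,
    StereoElement,
    StereoType,
)
from .smiles import canonical_ranks, parse
from .typing import load_type_table, perceive_type

__all__ = ["FixtureSpec", "generate_fixtures"]

_RING_TEMPLATES = [
    "C1CC1",
    "C1CCC1",
    "C1CCCC1",
    "C1CCCCC1",
    "C1CCOC1",
    "C1CCNC1",
    "c1ccccc1",
    "c1ccncc1",
    "c1cc[nH]c1",
    "c1ccoc1",
    "c1ccsc1",
    "c1ccc2ccccc2c1",
]

_AROMATIC_TEMPLATES = {"c1ccccc1", "c1ccncc1", "c1cc[nH]c1", "c1ccoc1", "c1ccsc1",
                       "c1ccc2ccccc2c1"}


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_molecules: int = 100
    min_atoms: int = 3
    max_atoms: int = 18
    ring_probability: float = 0.35
    element_palette: tuple[str, ...] = ("C", "C", "C", "C", "N", "O", "O", "S", "F", "Cl")
    charge_probability: float = 0.08
    unsaturation_probability: float = 0.25
    stereo_probability: float = 0.5


def _merge(mol: Molecule, fragment: Molecule, rng: random.Random) -> None:
    """Graft a fragment onto the molecule with one single bond between
    randomly chosen atoms that both have a spare hydrogen."""
    offset = len(mol)
    for atom in fragment.atoms:
        mol.add_atom(
            Atom(atom.element, atom.isotope, atom.charge, atom.implicit_h, atom.aromatic)
        )
    for bond in fragment.bonds:
        mol.add_bond(
            bond.begin + offset, bond.end + offset, bond.order, bond.aromatic
        )
    if offset == 0:
        return
    hosts = [i for i in range(offset) if (mol.atoms[i].implicit_h or 0) >= 1]
    guests = [
        i for i in range(offset, len(mol)) if (mol.atoms[i].implicit_h or 0) >= 1
    ]
    if not hosts or not guests:
        return
    a = rng.choice(hosts)
    b = rng.choice(guests)
    mol.add_bond(a, b, BondOrder.SINGLE)
    mol.atoms[a].implicit_h -= 1
    mol.atoms[b].implicit_h -= 1


def _typed_ok(mol: Molecule, *indices: int) -> bool:
    return all(perceive_type(mol, i) is not None for i in indices)


def _raise_order(mol: Molecule, rng: random.Random, prob: float) -> None:
    """Turn eligible single bonds into double (rarely triple) bonds,
    keeping every touched atom inside the type table."""
    for bond in mol.bonds:
        if bond.order is not BondOrder.SINGLE or bond.aromatic:
            continue
        a, b = bond.begin, bond.end
        aa, ab = mol.atoms[a], mol.atoms[b]
        if aa.aromatic or ab.aromatic:
            continue
        if rng.random() >= prob:
            continue
        steps = 2 if (
            (aa.implicit_h or 0) >= 2 and (ab.implicit_h or 0) >= 2 and rng.random() < 0.2
        ) else 1
        if (aa.implicit_h or 0) < steps or (ab.implicit_h or 0) < steps:
            continue
        old = bond.order
        bond.order = BondOrder.DOUBLE if steps == 1 else BondOrder.TRIPLE
        aa.implicit_h -= steps
        ab.implicit_h -= steps
        if not _typed_ok(mol, a, b):
            bond.order = old
            aa.implicit_h += steps
            ab.implicit_h += steps


def _apply_charges(mol: Molecule, rng: random.Random, prob: float) -> None:
    for i, atom in enumerate(mol.atoms):
        if rng.random() >= prob or atom.aromatic:
            continue
        if atom.element == 8 and atom.charge == 0 and (atom.implicit_h or 0) >= 1:
            atom.charge = -1
            atom.implicit_h -= 1
        elif atom.element == 7 and atom.charge == 0 and (atom.implicit_h or 0) >= 1:
            atom.charge = 1
            atom.implicit_h += 1
        else:
            continue
        if not _typed_ok(mol, i):  # pragma: no cover - defensive
            atom.charge = 0


def _add_stereo(mol: Molecule, rng: random.Random, prob: float) -> None:
    ranks = canonical_ranks(mol)
    for i, atom in enumerate(mol.atoms):
        if atom.element != 6 or atom.aromatic or rng.random() >= prob:
            continue
        nbs = mol.neighbors(i)
        h = atom.implicit_h or 0
        if any(mol.bond(i, nb).order is not BondOrder.SINGLE for nb in nbs):
            continue
        if len(nbs) == 4 and h == 0:
            carriers = tuple(nbs)
        elif len(nbs) == 3 and h == 1:
            carriers = (nbs[0], i, nbs[1], nbs[2])
        else:
            continue
        # only real stereocentres: all carriers structurally distinct
        carrier_ranks = [(-1 if c == i else ranks[c]) for c in carriers]
        if len(set(carrier_ranks)) != 4:
            continue
        mol.add_stereo(
            StereoElement(
                StereoType.TETRAHEDRAL, i, carriers, rng.choice((1, 2))
            )
        )
    # double-bond stereo on acyclic C=C with distinguishable ends
    for bond in mol.bonds:
        if bond.order is not BondOrder.DOUBLE or bond.in_ring:
            continue
        a, b = bond.begin, bond.end
        if mol.atoms[a].element != 6 or mol.atoms[b].element != 6:
            continue
        if any(e.stype is StereoType.CIS_TRANS_DB and set(e.focus) & {a, b}
               for e in mol.stereo):
            continue
        sides: list[int] | None = []
        for end, other in ((a, b), (b, a)):
            subs = [
                v
                for v in mol.neighbors(end)
                if v != other and mol.bond(end, v).order is BondOrder.SINGLE
            ]
            if len(subs) != len(mol.neighbors(end)) - 1:
                sides = None  # cumulated or otherwise unsaturated end
                break
            if not subs or (len(subs) == 2 and ranks[subs[0]] == ranks[subs[1]]):
                sides = None
                break
            sides.append(min(subs))
        if sides is not None and rng.random() < prob:
            mol.add_stereo(
                StereoElement(
                    StereoType.CIS_TRANS_DB, (a, b), tuple(sides), rng.choice((1, 2))
                )
            )


def generate_fixtures(spec: FixtureSpec) -> list[Molecule]:
    """Generate ``spec.n_molecules`` deterministic random molecules."""
    rng = random.Random(spec.seed)
    load_type_table()
    out = []
    for k in range(spec.n_molecules):
        target = rng.randint(spec.min_atoms, spec.max_atoms)
        mol = Molecule(title=f"fixture-{spec.seed}-{k}")
        while len(mol) < target:
            if rng.random() < spec.ring_probability:
                template = rng.choice(_RING_TEMPLATES)
                _merge(mol, parse(template), rng)
            else:
                sym = rng.choice(spec.element_palette)
                frag = Molecule()
                frag.add_atom(Atom(atomic_number(sym)))
                from .typing import infer_implicit_hydrogens

                infer_implicit_hydrogens(frag)
                _merge(mol, frag, rng)
        if any(b.in_ring is None for b in mol.bonds):
            from .rings import mark_rings

            mark_rings(mol)
        _raise_order(mol, rng, spec.unsaturation_probability)
        _apply_charges(mol, rng, spec.charge_probability)
        _add_stereo(mol, rng, spec.stereo_probability)
        out.append(mol)
    return out
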