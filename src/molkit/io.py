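"""File I/O: molfile/SDF V2000, SMILES line files, and FPS output.

Readers are streaming: SDF records are yielded one at a time and never
accumulated, so memory use is constant in the record count.  The molfile
reader accepts bond orders 1-3 plus the aromatic order 4 (kekulized on
read) and rejects CTfile query features (orders 5-8) and V3000
connection tables.  The writer emits V2000 with zero coordinates,
charges as ``M  CHG`` lines only, and 1-based atom numbering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

from .aromaticity import kekulize
from .elements import ATOMIC_NUMBERS, atomic_number
from .errors import FormatError, MolkitError
from .fingerprints import BitFingerprint
from .model import Atom, BondOrder, Molecule
from .typing import infer_implicit_hydrogens

__all__ = [
    "SdfRecord",
    "read_molfile_v2000",
    "read_sdf_tolerant",
    "write_molfile_v2000",
    "read_sdf",
    "write_sdf",
    "read_smiles_file",
    "write_smiles_file",
    "write_fps",
]

log = logging.getLogger("molkit")

_QUERY_BOND_ORDERS = {5, 6, 7, 8}


@dataclass
class SdfRecord:
    molecule: Molecule
    data_items: dict[str, str] = field(default_factory=dict)


def read_molfile_v2000(text: str) -> Molecule:
    """Parse a V2000 molfile connection table."""
    lines = text.splitlines()
    if len(lines) < 4:
        raise FormatError("molfile too short")
    title = lines[0].strip()
    counts = lines[3]
    if "V3000" in counts:
        raise FormatError("V3000 connection tables are not supported")
    if "V2000" not in counts:
        raise FormatError("counts line does not declare V2000")
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except ValueError:
        raise FormatError("malformed counts line") from None
    mol = Molecule(title)
    atom_lines = lines[4 : 4 + n_atoms]
    bond_lines = lines[4 + n_atoms : 4 + n_atoms + n_bonds]
    if len(atom_lines) < n_atoms or len(bond_lines) < n_bonds:
        raise FormatError("truncated atom or bond block")
    for ln in atom_lines:
        sym = ln[31:34].strip()
        if sym not in ATOMIC_NUMBERS:
            raise FormatError(f"unknown element symbol {sym!r} in atom block")
        mol.add_atom(Atom(atomic_number(sym)))
    aromatic_bonds = []
    for ln in bond_lines:
        try:
            a = int(ln[0:3]) - 1
            b = int(ln[3:6]) - 1
            order = int(ln[6:9])
        except ValueError:
            raise FormatError(f"malformed bond line {ln!r}") from None
        if order in _QUERY_BOND_ORDERS:
            raise FormatError(
                f"bond {a + 1}-{b + 1} uses CTfile query bond order {order}; "
                "query features are rejected"
            )
        if order == 4:
            bond = mol.add_bond(a, b, BondOrder.UNSET, aromatic=True)
            aromatic_bonds.append(bond)
        elif order in (1, 2, 3):
            mol.add_bond(a, b, BondOrder(order))
        else:
            raise FormatError(f"illegal bond order {order}")
    for ln in lines[4 + n_atoms + n_bonds :]:
        if ln.startswith("M  END"):
            break
        if ln.startswith("M  CHG"):
            fields = ln.split()
            count = int(fields[2])
            pairs = fields[3 : 3 + 2 * count]
            for i in range(count):
                mol.atoms[int(pairs[2 * i]) - 1].charge = int(pairs[2 * i + 1])
        elif ln.startswith("M  ISO"):
            fields = ln.split()
            count = int(fields[2])
            pairs = fields[3 : 3 + 2 * count]
            for i in range(count):
                mol.atoms[int(pairs[2 * i]) - 1].isotope = int(pairs[2 * i + 1])
    if aromatic_bonds:
        for bond in aromatic_bonds:
            mol.atoms[bond.begin].aromatic = True
            mol.atoms[bond.end].aromatic = True
        kekulize(mol)
    infer_implicit_hydrogens(mol)
    return mol


def write_molfile_v2000(mol: Molecule) -> str:
    """Serialize to V2000 with zero coordinates (kekulized orders only)."""
    if len(mol) > 999:
        raise FormatError("V2000 supports at most 999 atoms")
    out = [mol.title, "  molkit", "", ""]
    out[3] = f"{len(mol.atoms):3d}{len(mol.bonds):3d}  0  0  0  0  0  0  0  0999 V2000"
    for atom in mol.atoms:
        out.append(
            f"{0.0:10.4f}{0.0:10.4f}{0.0:10.4f} {atom.symbol:<3s} 0  0  0  0  0"
            "  0  0  0  0  0  0  0"
        )
    for bond in mol.bonds:
        if bond.order is BondOrder.UNSET:
            raise FormatError(
                f"bond {bond.begin}-{bond.end} has unset order; kekulize first"
            )
        out.append(f"{bond.begin + 1:3d}{bond.end + 1:3d}{int(bond.order):3d}  0")
    charged = [(i + 1, a.charge) for i, a in enumerate(mol.atoms) if a.charge]
    for k in range(0, len(charged), 8):
        chunk = charged[k : k + 8]
        out.append(
            f"M  CHG{len(chunk):3d}"
            + "".join(f"{i:4d}{q:4d}" for i, q in chunk)
        )
    isotopes = [(i + 1, a.isotope) for i, a in enumerate(mol.atoms) if a.isotope]
    for k in range(0, len(isotopes), 8):
        chunk = isotopes[k : k + 8]
        out.append(
            f"M  ISO{len(chunk):3d}"
            + "".join(f"{i:4d}{m:4d}" for i, m in chunk)
        )
    out.append("M  END")
    return "\n".join(out) + "\n"


def _sdf_chunks(stream: IO[str]) -> Iterator[tuple[list[str], dict[str, str]]]:
    mol_lines: list[str] = []
    data: dict[str, str] = {}
    current_name: str | None = None
    in_data = False
    pending = False

    for raw in stream:
        line = raw.rstrip("\n")
        if line.startswith("$$$$"):
            if pending:
                yield mol_lines, data
            mol_lines, data, current_name, in_data, pending = [], {}, None, False, False
            continue
        pending = True
        if in_data:
            if line.startswith("> "):
                current_name = _data_header_name(line)
                data[current_name] = ""
            elif line.strip() == "":
                current_name = None
            elif current_name is not None:
                data[current_name] = (
                    data[current_name] + "\n" + line if data[current_name] else line
                )
            continue
        mol_lines.append(line)
        if line.startswith("M  END"):
            in_data = True
    if pending and (mol_lines or data):
        log.warning("SDF record at end of file missing '$$$$' terminator")
        yield mol_lines, data


def read_sdf(stream: IO[str]) -> Iterator[SdfRecord]:
    """Stream SDF records; constant memory in the record count.  Raises
    on the first malformed record (see :func:`read_sdf_tolerant`)."""
    for mol_lines, data in _sdf_chunks(stream):
        yield SdfRecord(read_molfile_v2000("\n".join(mol_lines)), data)


def read_sdf_tolerant(stream: IO[str]) -> Iterator[SdfRecord | None]:
    """Like :func:`read_sdf` but yields None for records that fail to
    parse (the failure is logged), mirroring skip-and-continue
    processing."""
    for mol_lines, data in _sdf_chunks(stream):
        try:
            yield SdfRecord(read_molfile_v2000("\n".join(mol_lines)), data)
        except MolkitError as exc:
            log.warning("skipping SDF record: %s", exc)
            yield None


def _data_header_name(line: str) -> str:
    start = line.find("<")
    end = line.find(">", start + 1)
    if start == -1 or end == -1 or end - start <= 1:
        raise FormatError(f"malformed SDF data header {line!r}")
    return line[start + 1 : end]


def write_sdf(records: Iterable[SdfRecord], stream: IO[str]) -> None:
    for record in records:
        stream.write(write_molfile_v2000(record.molecule))
        for name, value in record.data_items.items():
            if not name:
                raise FormatError("SDF data item names must be non-empty")
            stream.write(f"> <{name}>\n{value}\n\n")
        stream.write("$$$$\n")


# ----------------------------------------------------------------------
# SMILES line files
# ----------------------------------------------------------------------


def read_smiles_file(stream: IO[str]) -> Iterator[tuple[str, str]]:
    """Yield (smiles, title) per record line.

    '#'-prefixed lines are comments; an empty line is an empty record
    (an empty molecule, not a skip).  A trailing CXSMILES block between
    pipe characters is treated as part of the opaque title.
    """
    for raw in stream:
        line = raw.rstrip("\n")
        if line.lstrip().startswith("#"):
            continue
        if not line.strip():
            yield "", ""
            continue
        parts = line.split(None, 1)
        yield parts[0], parts[1].strip() if len(parts) > 1 else ""


def write_smiles_file(
    records: Iterable[tuple[str, str]], stream: IO[str]
) -> None:
    for smiles, title in records:
        stream.write(f"{smiles} {title}\n" if title else f"{smiles}\n")


# ----------------------------------------------------------------------
# FPS
# ----------------------------------------------------------------------


def write_fps(
    fingerprints: Iterable[tuple[BitFingerprint, str]],
    stream: IO[str],
    fp_type: str = "molkit",
) -> None:
    """chemfp-style FPS: header then one ``hex<TAB>id`` line per record.

    The hex encoding is little-endian byte order: bit 0 is the least
    significant bit of the first byte.
    """
    width: int | None = None
    header_done = False
    for fp, ident in fingerprints:
        if width is None:
            width = fp.width
        elif fp.width != width:
            raise FormatError(
                f"FPS requires uniform width: {fp.width} != {width}"
            )
        if not header_done:
            stream.write("#FPS1\n")
            stream.write(f"#num_bits={width}\n")
            stream.write(f"#type={fp_type}\n")
            header_done = True
        stream.write(f"{fp.hex()}\t{ident}\n")
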