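"""Molecular fingerprints: hashed paths, circular neighborhoods, and
structural keys, in bit and count variants.

All hashing uses 32-bit FNV-1a over integer invariant streams with a
fixed seed, so fingerprints are bit-for-bit reproducible across runs and
platforms.  The path fingerprint encodes every simple path of 0-7 bonds
(read in its lexicographically smaller direction) and folds into a fixed
width, which preserves the screening property: the bits of a
substructure are a subset of the bits of any molecule containing it.
The circular fingerprint is an ECFP-style iterative neighborhood hash;
its bit variant folds to 1024 while the count variant keeps unfolded
32-bit indices with occurrence counts.  The key fingerprint is a
MACCS-like dictionary of 166 structural keys expressed in the restricted
query language; keys that would need constructs outside that language
are permanently unset (see the packaged key table).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .aromaticity import find_aromatic
from .errors import FormatError, MolkitError
from .match import Pattern
from .model import Molecule
from .rings import mark_rings, sssr
from .typing import infer_implicit_hydrogens

__all__ = [
    "BitFingerprint",
    "CountFingerprint",
    "path_fingerprint",
    "circular_fingerprint",
    "maccs_fingerprint",
    "tanimoto",
    "MACCS_WIDTH",
]

MACCS_WIDTH = 166

_FNV_OFFSET = 0x811C9DC5
_FNV_PRIME = 0x01000193
_MASK32 = 0xFFFFFFFF


def _fnv(values, seed: int = _FNV_OFFSET) -> int:
    """32-bit FNV-1a over a stream of integers (4 bytes each)."""
    h = seed
    for v in values:
        v &= _MASK32
        for shift in (0, 8, 16, 24):
            h ^= (v >> shift) & 0xFF
            h = (h * _FNV_PRIME) & _MASK32
    return h


@dataclass(frozen=True)
class BitFingerprint:
    """Fixed-width bit vector as a sorted index set."""

    width: int
    bits: frozenset[int]

    def __post_init__(self) -> None:
        if any(not 0 <= b < self.width for b in self.bits):
            raise ValueError("bit index out of range")

    def __and__(self, other: "BitFingerprint") -> "BitFingerprint":
        self._check(other)
        return BitFingerprint(self.width, self.bits & other.bits)

    def __or__(self, other: "BitFingerprint") -> "BitFingerprint":
        self._check(other)
        return BitFingerprint(self.width, self.bits | other.bits)

    def __len__(self) -> int:
        return len(self.bits)

    def _check(self, other: "BitFingerprint") -> None:
        if self.width != other.width:
            raise MolkitError(
                f"fingerprint widths differ: {self.width} != {other.width}"
            )

    def to_bytes(self) -> bytes:
        """Little-endian byte order: bit i is bit (i % 8) of byte (i // 8)."""
        n = (self.width + 7) // 8
        buf = bytearray(n)
        for b in self.bits:
            buf[b // 8] |= 1 << (b % 8)
        return bytes(buf)

    def hex(self) -> str:
        return self.to_bytes().hex()


@dataclass(frozen=True)
class CountFingerprint:
    """Sparse 32-bit-index -> positive count map."""

    entries: tuple[tuple[int, int], ...]

    @staticmethod
    def from_dict(counts: dict[int, int]) -> "CountFingerprint":
        if any(c < 1 for c in counts.values()):
            raise ValueError("counts must be >= 1")
        return CountFingerprint(tuple(sorted(counts.items())))

    @property
    def as_dict(self) -> dict[int, int]:
        return dict(self.entries)


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """|a & b| / |a | b|; 1.0 when both are empty (by convention)."""
    if a.width != b.width:
        raise MolkitError(f"fingerprint widths differ: {a.width} != {b.width}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


# ----------------------------------------------------------------------
# Shared invariants
# ----------------------------------------------------------------------


def _ensure_perceived(mol: Molecule) -> None:
    if any(b.in_ring is None for b in mol.bonds):
        mark_rings(mol)
    if not getattr(mol, "_aromaticity_perceived", False):
        find_aromatic(mol)
        mol._aromaticity_perceived = True  # type: ignore[attr-defined]
    if any(a.implicit_h is None for a in mol.atoms):
        infer_implicit_hydrogens(mol)


def _atom_invariant(mol: Molecule, i: int) -> int:
    atom = mol.atoms[i]
    return (atom.element << 8) | ((atom.charge + 8) << 1) | int(atom.aromatic)


def _bond_invariant(bond) -> int:
    return 4 if bond.aromatic else int(bond.order)


# ----------------------------------------------------------------------
# Path fingerprint
# ----------------------------------------------------------------------


def path_fingerprint(
    mol: Molecule, width: int = 1024, max_depth: int = 7
) -> BitFingerprint:
    """Daylight-like hashed path fingerprint over simple paths of
    0..``max_depth`` bonds."""
    _ensure_perceived(mol)
    n = len(mol)
    ainv = [_atom_invariant(mol, i) for i in range(n)]
    bits: set[int] = set()
    seen_paths: set[tuple[int, ...]] = set()

    def invariant_seq(path: list[int]) -> tuple[int, ...]:
        seq = [ainv[path[0]]]
        for a, b in zip(path, path[1:]):
            seq.append(_bond_invariant(mol.bond(a, b)))
            seq.append(ainv[b])
        return tuple(seq)

    def record(path: list[int]) -> None:
        key = min(tuple(path), tuple(reversed(path)))
        if key in seen_paths:
            return
        seen_paths.add(key)
        seq = min(invariant_seq(path), invariant_seq(path[::-1]))
        bits.add(_fnv(seq) % width)

    def dfs(path: list[int], onpath: set[int]) -> None:
        record(path)
        if len(path) > max_depth:
            return
        for nb in mol.neighbors(path[-1]):
            if nb not in onpath:
                path.append(nb)
                onpath.add(nb)
                dfs(path, onpath)
                onpath.discard(nb)
                path.pop()

    for start in range(n):
        dfs([start], {start})
    return BitFingerprint(width, frozenset(bits))


# ----------------------------------------------------------------------
# Circular (ECFP-style) fingerprint
# ----------------------------------------------------------------------


def _circular_features(mol: Molecule, radius: int) -> list[int]:
    """Feature hashes, deduplicated by (hash, covered atom set)."""
    _ensure_perceived(mol)
    n = len(mol)
    current = []
    coverage = []
    for i in range(n):
        atom = mol.atoms[i]
        ring = any(b.in_ring for b in mol.bonds_of(i))
        current.append(
            _fnv(
                (
                    atom.element,
                    mol.degree(i),
                    mol.total_h(i),
                    atom.charge + 8,
                    int(ring),
                    int(atom.aromatic),
                )
            )
        )
        coverage.append(frozenset((i,)))
    features: list[int] = []
    seen: set[tuple[int, frozenset[int]]] = set()
    for i in range(n):
        seen.add((current[i], coverage[i]))
        features.append(current[i])
    for r in range(1, radius + 1):
        nxt, ncov = [], []
        for i in range(n):
            env = sorted(
                (_bond_invariant(mol.bond(i, nb)), current[nb])
                for nb in mol.neighbors(i)
            )
            stream = [r, current[i]]
            for bi, ah in env:
                stream.extend((bi, ah))
            nxt.append(_fnv(stream))
            cov = set(coverage[i])
            for nb in mol.neighbors(i):
                cov |= coverage[nb]
            ncov.append(frozenset(cov))
        current, coverage = nxt, ncov
        for i in range(n):
            key = (current[i], coverage[i])
            if key in seen:
                continue
            seen.add(key)
            features.append(current[i])
    return features


def circular_fingerprint(
    mol: Molecule,
    radius: int = 2,
    width: int = 1024,
    counted: bool = False,
) -> BitFingerprint | CountFingerprint:
    """Extended-connectivity fingerprint; the bit variant folds to
    ``width``, the count variant keeps unfolded 32-bit feature indices."""
    features = _circular_features(mol, radius)
    if counted:
        counts: dict[int, int] = {}
        for h in features:
            counts[h] = counts.get(h, 0) + 1
        return CountFingerprint.from_dict(counts)
    return BitFingerprint(width, frozenset(h % width for h in features))


# ----------------------------------------------------------------------
# MACCS-like structural keys
# ----------------------------------------------------------------------

_maccs_cache: list[tuple[int, str, tuple[str, ...], int]] | None = None


def _load_maccs_keys():
    global _maccs_cache
    if _maccs_cache is not None:
        return _maccs_cache
    text = resources.files("molkit.data").joinpath("maccs_keys.tsv").read_text()
    keys = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"maccs_keys.tsv line {lineno}: expected 3 fields")
        idx_s, defn, min_count_s = parts
        idx = int(idx_s)
        if not 1 <= idx <= MACCS_WIDTH:
            raise FormatError(f"maccs_keys.tsv line {lineno}: key {idx} out of range")
        kind, *args = defn.split(":")
        keys.append((idx, kind, tuple(args), int(min_count_s)))
    _maccs_cache = keys
    return keys


def maccs_supported_keys() -> list[int]:
    """1-based indices of keys with an active definition."""
    return sorted(i for i, kind, _, _ in _load_maccs_keys() if kind != "unsupported")


_pattern_cache: dict[str, Pattern] = {}


def _maccs_count(mol: Molecule, kind: str, args: tuple[str, ...]) -> int:
    from .elements import atomic_number

    if kind == "unsupported":
        return 0
    if kind == "element":
        z = atomic_number(args[0])
        return sum(1 for a in mol.atoms if a.element == z)
    if kind == "elementh":
        z = atomic_number(args[0])
        want = int(args[1])
        op = args[2]
        hits = 0
        for i, a in enumerate(mol.atoms):
            if a.element != z:
                continue
            h = mol.total_h(i)
            if (op == "eq" and h == want) or (op == "ge" and h >= want):
                hits += 1
        return hits
    if kind == "pattern":
        pat = _pattern_cache.get(args[0])
        if pat is None:
            pat = Pattern.from_smiles(args[0], enforce_stereo=False)
            _pattern_cache[args[0]] = pat
        return len(pat.match_sets(mol))
    if kind == "ring":
        size = int(args[0])
        return sum(1 for r in sssr(mol) if r.size == size)
    if kind == "hetring":
        size = int(args[0])
        return sum(
            1
            for r in sssr(mol)
            if r.size == size
            and any(mol.atoms[i].element not in (1, 6) for i in r.atoms)
        )
    if kind == "aromring":
        _ensure_perceived(mol)
        return sum(
            1
            for r in sssr(mol)
            if all(mol.atoms[i].aromatic for i in r.atoms)
        )
    if kind == "aromatom":
        _ensure_perceived(mol)
        return sum(1 for a in mol.atoms if a.aromatic)
    if kind == "ringatom":
        if any(b.in_ring is None for b in mol.bonds):
            mark_rings(mol)
        return sum(
            1
            for i in range(len(mol))
            if any(b.in_ring for b in mol.bonds_of(i))
        )
    if kind == "elementring":
        z = atomic_number(args[0])
        if any(b.in_ring is None for b in mol.bonds):
            mark_rings(mol)
        return sum(
            1
            for i in range(len(mol))
            if mol.atoms[i].element == z
            and any(b.in_ring for b in mol.bonds_of(i))
        )
    if kind == "fragments":
        n = len(mol)
        seen: set[int] = set()
        comps = 0
        for i in range(n):
            if i in seen:
                continue
            comps += 1
            stack = [i]
            seen.add(i)
            while stack:
                u = stack.pop()
                for v in mol.neighbors(u):
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
        return comps
    if kind == "charged":
        return sum(1 for a in mol.atoms if a.charge != 0)
    if kind == "isotope":
        return sum(1 for a in mol.atoms if a.isotope is not None)
    if kind == "hetpair":
        hits = 0
        for b in mol.bonds:
            za = mol.atoms[b.begin].element
            zb = mol.atoms[b.end].element
            if za not in (1, 6) and zb not in (1, 6):
                hits += 1
        return hits
    raise FormatError(f"unknown MACCS key kind {kind!r}")


def maccs_fingerprint(mol: Molecule) -> BitFingerprint:
    """166-key structural-key fingerprint.

    Bit i-1 is set when key i's definition matches; keys marked
    unsupported in the packaged table are always 0.
    """
    _ensure_perceived(mol)
    bits = set()
    for idx, kind, args, min_count in _load_maccs_keys():
        if kind == "unsupported":
            continue
        if _maccs_count(mol, kind, args) >= min_count:
            bits.add(idx - 1)
    return BitFingerprint(MACCS_WIDTH, frozenset(bits))
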