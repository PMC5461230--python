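"""Molecular formulas, exact masses, isotope patterns and mass
decomposition.

Mass decomposition answers: which element-count vectors have a
monoisotopic mass inside ``[target - tol, target + tol]``?  Two
algorithms share one result contract.  The Round Robin path discretizes
the problem into an integer knapsack at 1e-5 Da per unit, builds an
extended residue table (per element prefix, the minimal achievable
integer mass in each residue class modulo the lightest element's integer
mass) and backtracks through it; the residue table is an exact
reachability bound for unbounded counts, so it prunes without losing
candidates, and a final real-valued mass filter restores exactness.  The
fallback is an optimized bounded enumeration used for very large masses
(above 400,000 Da) or mass windows wider than 1 Da, where the
discretization is unsuitable.  Both return formulas sorted by ascending
exact mass (ties: lexicographic Hill-order counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from .errors import FormatError, MolkitError
from .model import Isotope, Molecule

__all__ = [
    "MolecularFormula",
    "DecompositionQuery",
    "IsotopePattern",
    "load_isotopes",
    "monoisotopic",
    "formula_of",
    "exact_mass",
    "rdbe",
    "filter_rdbe",
    "decompose",
    "decompose_round_robin",
    "decompose_enumerate",
    "choose_algorithm",
    "isotope_pattern",
    "isotope_distribution",
]

ELECTRON_MASS = 0.000548580
ROUND_ROBIN_MAX_MASS = 400_000.0
ROUND_ROBIN_MAX_SPAN = 1.0
_PRECISION = 1e-5  # Da per integer unit of the knapsack discretization

#: Standard valences used for ring-plus-double-bond equivalents.
_RDBE_VALENCES = {
    "H": 1, "F": 1, "Cl": 1, "Br": 1, "I": 1, "Na": 1, "K": 1,
    "O": 2, "S": 2, "N": 3, "P": 3, "C": 4, "Si": 4,
}


def _hill_key(sym: str, has_carbon: bool) -> tuple:
    if has_carbon:
        return {"C": (0,), "H": (1,)}.get(sym, (2, sym))
    return (2, sym)


@dataclass(frozen=True)
class MolecularFormula:
    """Element-symbol -> count vector with a net charge."""

    items: tuple[tuple[str, int], ...]
    charge: int = 0

    @staticmethod
    def from_counts(counts: dict[str, int], charge: int = 0) -> "MolecularFormula":
        cleaned = {s: c for s, c in counts.items() if c}
        if any(c < 0 for c in cleaned.values()):
            raise ValueError("element counts must be non-negative")
        has_c = "C" in cleaned
        items = tuple(
            sorted(cleaned.items(), key=lambda kv: _hill_key(kv[0], has_c))
        )
        return MolecularFormula(items, charge)

    @property
    def counts(self) -> dict[str, int]:
        return dict(self.items)

    def __str__(self) -> str:
        body = "".join(s if c == 1 else f"{s}{c}" for s, c in self.items)
        if self.charge:
            sign = "+" if self.charge > 0 else "-"
            body += sign if abs(self.charge) == 1 else f"{sign}{abs(self.charge)}"
        return body or "(empty)"


@dataclass(frozen=True)
class DecompositionQuery:
    target_mass: float
    tolerance: float
    bounds: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        for sym, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"bounds for {sym}: min {lo} > max {hi}")


@dataclass(frozen=True)
class IsotopePattern:
    """(mass, relative abundance) peaks, tallest peak normalized to 1."""

    peaks: tuple[tuple[float, float], ...]


@lru_cache(maxsize=1)
def load_isotopes() -> dict[str, tuple[Isotope, ...]]:
    text = resources.files("molkit.data").joinpath("isotopes.tsv").read_text()
    table: dict[str, list[Isotope]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise FormatError(f"isotopes.tsv line {lineno}: expected 5 fields")
        sym, z, mass_number, mass, abundance = parts
        table.setdefault(sym, []).append(
            Isotope(sym, int(z), int(mass_number), float(mass), float(abundance))
        )
    out = {}
    for sym, isotopes in table.items():
        total = sum(i.abundance for i in isotopes)
        if total > 1 + 1e-9:
            raise FormatError(f"abundances of {sym} sum to {total} > 1")
        out[sym] = tuple(sorted(isotopes, key=lambda i: i.exact_mass))
    return out


def monoisotopic(sym: str) -> Isotope:
    """The most abundant isotope of an element."""
    try:
        isotopes = load_isotopes()[sym]
    except KeyError:
        raise MolkitError(f"no isotope data for element {sym!r}") from None
    return max(isotopes, key=lambda i: i.abundance)


def formula_of(mol: Molecule) -> MolecularFormula:
    """Formula of a molecule, counting implicit and explicit hydrogens."""
    counts: dict[str, int] = {}
    charge = 0
    for i, atom in enumerate(mol.atoms):
        counts[atom.symbol] = counts.get(atom.symbol, 0) + 1
        if atom.implicit_h:
            counts["H"] = counts.get("H", 0) + atom.implicit_h
        charge += atom.charge
    return MolecularFormula.from_counts(counts, charge)


def exact_mass(f: MolecularFormula) -> float:
    """Monoisotopic mass with electron-mass correction per unit charge."""
    total = sum(monoisotopic(sym).exact_mass * c for sym, c in f.items)
    return total - f.charge * ELECTRON_MASS


def rdbe(f: MolecularFormula) -> float:
    """Ring plus double bond equivalents: 1 + sum n_i (v_i - 2) / 2."""
    total = 1.0
    for sym, c in f.items:
        v = _RDBE_VALENCES.get(sym)
        if v is None:
            raise MolkitError(f"no standard valence for element {sym!r}")
        total += c * (v - 2) / 2.0
    return total


def filter_rdbe(
    formulas: list[MolecularFormula], min_rdbe: float = 0.0, max_rdbe: float = 20.0
) -> list[MolecularFormula]:
    return [f for f in formulas if min_rdbe <= rdbe(f) <= max_rdbe]


# ----------------------------------------------------------------------
# Mass decomposition
# ----------------------------------------------------------------------


def _prepared(q: DecompositionQuery):
    """Capped per-element bounds, mandatory baseline subtracted.

    Returns (symbols desc by mass, masses, caps, base_counts, lo, hi).
    """
    if not q.bounds:
        raise MolkitError("decomposition query needs a non-empty element set")
    hi_real = q.target_mass + q.tolerance
    lo_real = q.target_mass - q.tolerance
    syms, masses, caps, base = [], [], [], []
    for sym in sorted(q.bounds):
        mn, mx = q.bounds[sym]
        mass = monoisotopic(sym).exact_mass
        cap = min(mx, math.floor(hi_real / mass)) if mass > 0 else mx
        if cap < mn:
            return None  # mandatory atoms alone overshoot: empty result
        syms.append(sym)
        masses.append(mass)
        caps.append(cap - mn)
        base.append(mn)
    lo = lo_real - sum(b * m for b, m in zip(base, masses))
    hi = hi_real - sum(b * m for b, m in zip(base, masses))
    if hi < 0:
        return None
    order = sorted(range(len(syms)), key=lambda i: -masses[i])
    return (
        [syms[i] for i in order],
        [masses[i] for i in order],
        [caps[i] for i in order],
        [base[i] for i in order],
        lo,
        hi,
    )


def _finalize(
    raw: list[tuple[int, ...]],
    syms: list[str],
    masses: list[float],
    base: list[int],
    lo: float,
    hi: float,
) -> list[MolecularFormula]:
    out = []
    for counts in raw:
        m = sum(c * mm for c, mm in zip(counts, masses))
        if lo - 1e-12 <= m <= hi + 1e-12:
            f = MolecularFormula.from_counts(
                {s: c + b for s, c, b in zip(syms, counts, base)}
            )
            out.append((m, tuple(cc for _, cc in f.items), f))
    out.sort(key=lambda t: (t[0], t[1]))
    return [f for _, _, f in out]


def decompose_enumerate(q: DecompositionQuery) -> list[MolecularFormula]:
    """Bounded depth-first enumeration over real-valued masses."""
    prep = _prepared(q)
    if prep is None:
        return []
    syms, masses, caps, base, lo, hi = prep
    n = len(syms)
    results: list[tuple[int, ...]] = []
    counts = [0] * n

    def rec(i: int, lo_r: float, hi_r: float) -> None:
        if i == n - 1:
            m = masses[i]
            c_min = max(0, math.ceil((lo_r - 1e-9) / m))
            c_max = min(caps[i], math.floor((hi_r + 1e-9) / m))
            for c in range(c_min, c_max + 1):
                counts[i] = c
                results.append(tuple(counts))
            counts[i] = 0
            return
        m = masses[i]
        top = min(caps[i], math.floor((hi_r + 1e-9) / m))
        for c in range(top + 1):
            counts[i] = c
            rec(i + 1, lo_r - c * m, hi_r - c * m)
        counts[i] = 0

    rec(0, lo, hi)
    return _finalize(results, syms, masses, base, lo, hi)


@lru_cache(maxsize=8)
def _residue_table(weights: tuple[int, ...]) -> list[list[float]]:
    """Extended residue table for weights ordered heaviest..lightest.

    ERT[k][r] = minimal integer mass congruent to r (mod the lightest
    weight) achievable with unbounded counts of the k lightest elements
    (suffix of the ordering).  Built with the round-robin update: each
    new weight relaxes every residue class along its gcd-cycles.
    """
    a = weights[-1]
    inf = math.inf
    ert = [inf] * a
    ert[0] = 0.0
    tables = [list(ert)]
    for w in reversed(weights[:-1]):
        d = math.gcd(w, a)
        steps = a // d
        for r0 in range(d):
            cycle = [(r0 + k * w) % a for k in range(steps)]
            start = min(range(steps), key=lambda k: ert[cycle[k]])
            best = inf
            for k in range(steps):
                r = cycle[(start + k) % steps]
                if best is not inf:
                    best += w
                if ert[r] < best:
                    best = ert[r]
                ert[r] = best
        tables.append(list(ert))
    # tables[k] covers the k+1 lightest elements
    return tables


def decompose_round_robin(q: DecompositionQuery) -> list[MolecularFormula]:
    """Integer-knapsack decomposition via the extended residue table."""
    if q.target_mass > ROUND_ROBIN_MAX_MASS or 2 * q.tolerance > ROUND_ROBIN_MAX_SPAN:
        raise MolkitError(
            "query outside the Round Robin operating range; use the "
            "enumeration fallback"
        )
    prep = _prepared(q)
    if prep is None:
        return []
    syms, masses, caps, base, lo, hi = prep
    n = len(syms)
    weights = tuple(max(1, math.floor(m / _PRECISION)) for m in masses)
    a = weights[-1]
    tables = _residue_table(weights)

    # Integer window: floor weights only under-estimate, by at most one
    # unit per atom; slack the lower edge by the maximal atom count.
    min_mass = min(masses)
    slack = math.floor(max(hi, 0) / min_mass) + 1
    lo_int = max(0, math.floor(lo / _PRECISION) - slack)
    hi_int = math.floor(hi / _PRECISION)
    if hi_int < 0:
        return []

    results: list[tuple[int, ...]] = []
    counts = [0] * n

    def feasible(k: int, lo_i: int, hi_i: int) -> bool:
        # any integer in [lo_i, hi_i] reachable with the k lightest elements?
        if hi_i < 0:
            return False
        lo_i = max(lo_i, 0)
        if hi_i - lo_i >= a:
            return True
        ert = tables[k - 1]
        for m in range(lo_i, hi_i + 1):
            if ert[m % a] <= m:
                return True
        return False

    def rec(i: int, lo_i: int, hi_i: int) -> None:
        if i == n - 1:
            c_min = max(0, -(-lo_i // a))
            c_max = min(caps[i], hi_i // a)
            for c in range(c_min, c_max + 1):
                counts[i] = c
                results.append(tuple(counts))
            counts[i] = 0
            return
        w = weights[i]
        top = min(caps[i], hi_i // w)
        remaining = n - 1 - i
        for c in range(top + 1):
            nlo, nhi = lo_i - c * w, hi_i - c * w
            if nhi < 0:
                break
            if nhi - nlo < 256 and not feasible(remaining, nlo, nhi):
                continue
            counts[i] = c
            rec(i + 1, nlo, nhi)
        counts[i] = 0

    rec(0, lo_int, hi_int)
    return _finalize(results, syms, masses, base, lo, hi)


def choose_algorithm(q: DecompositionQuery) -> str:
    """Dispatch rule: Round Robin unless the mass is very large or the
    window spans more than 1 Da."""
    if q.target_mass > ROUND_ROBIN_MAX_MASS or 2 * q.tolerance > ROUND_ROBIN_MAX_SPAN:
        return "enumerate"
    return "round_robin"


def decompose(q: DecompositionQuery) -> list[MolecularFormula]:
    if choose_algorithm(q) == "round_robin":
        return decompose_round_robin(q)
    return decompose_enumerate(q)


# ----------------------------------------------------------------------
# Isotope patterns
# ----------------------------------------------------------------------

_MERGE_WINDOW = 1e-5
_HARD_PRUNE = 1e-12


def _merge(peaks: list[tuple[float, float]]) -> list[tuple[float, float]]:
    peaks.sort()
    out: list[tuple[float, float]] = []
    for mass, ab in peaks:
        if out and mass - out[-1][0] < _MERGE_WINDOW:
            m0, a0 = out[-1]
            total = a0 + ab
            out[-1] = ((m0 * a0 + mass * ab) / total, total)
        else:
            out.append((mass, ab))
    return out


def _convolve(
    a: list[tuple[float, float]], b: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    prod = [(ma + mb, xa * xb) for ma, xa in a for mb, xb in b]
    return [(m, x) for m, x in _merge(prod) if x > _HARD_PRUNE]


def isotope_distribution(f: MolecularFormula) -> list[tuple[float, float]]:
    """Unnormalized isotopologue distribution by iterative convolution of
    per-element isotope abundances (peaks merged within 1e-5 Da)."""
    table = load_isotopes()
    dist: list[tuple[float, float]] = [(0.0, 1.0)]
    for sym, count in f.items:
        if sym not in table:
            raise MolkitError(f"no isotope data for element {sym!r}")
        single = [(i.exact_mass, i.abundance) for i in table[sym]]
        power = single
        c = count
        while c:  # exponentiation by squaring over convolution
            if c & 1:
                dist = _convolve(dist, power)
            c >>= 1
            if c:
                power = _convolve(power, power)
    return dist


def isotope_pattern(f: MolecularFormula, min_abundance: float = 1e-4) -> IsotopePattern:
    """Relative isotope pattern: tallest peak 1, peaks below
    ``min_abundance`` (after normalization) pruned."""
    if not 0 < min_abundance < 1:
        raise ValueError("min_abundance must lie in (0, 1)")
    dist = isotope_distribution(f)
    if not dist:
        return IsotopePattern(())
    top = max(x for _, x in dist)
    peaks = tuple(
        (m, x / top) for m, x in dist if x / top >= min_abundance
    )
    return IsotopePattern(peaks)
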