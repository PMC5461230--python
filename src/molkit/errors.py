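"""Exception hierarchy."""

from __future__ import annotations


class MolkitError(Exception):
    """Base class for all toolkit errors."""


class TypingError(MolkitError):
    """Atom typing / valence failure; names the offending atom."""

    def __init__(self, message: str, atom_index: int | None = None) -> None:
        super().__init__(message)
        self.atom_index = atom_index


class KekulizationError(MolkitError):
    """No valid alternating single/double assignment exists for an
    aromatic system."""

    def __init__(self, message: str, atoms: tuple[int, ...] = ()) -> None:
        super().__init__(message)
        self.atoms = atoms


class SmilesParseError(MolkitError):
    """SMILES syntax or semantic error with a character offset."""

    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"position {position}: {message}")
        self.position = position
        self.diagnostic = message


class FormatError(MolkitError):
    """Malformed or unsupported file content (molfile, SDF, FPS, tables)."""
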