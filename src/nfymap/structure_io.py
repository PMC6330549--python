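"""Pragmatic PDB reader/writer and residue selection.

Reads the fixed-column subset of the PDB format needed for interface
analysis of protein/DNA complexes: ``ATOM``/``HETATM`` records of the
first model, heavy atoms only.  Hydrogens and waters are dropped,
alternate locations are resolved by occupancy, and residues keep their
author numbering (including insertion codes) so that segment names such
as NF-YB-51-57 refer directly to deposited coordinates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, Union

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "ResidueSet",
    "PDBParseError",
    "UnknownChainError",
    "parse_pdb",
    "write_pdb",
    "select",
]

# three-letter -> one-letter codes for the 20 standard amino acids
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
STANDARD_AA = frozenset(AA3_TO_1)

# deoxy- and ribonucleotide residue names accepted as nucleic
NUCLEOTIDE_NAMES = frozenset({"DA", "DC", "DG", "DT", "DU", "A", "C", "G", "U"})

# modified residues remapped to their standard parent
HET_TO_STANDARD = {"MSE": "MET"}

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

_TWO_LETTER_ELEMENTS = frozenset({"FE", "ZN", "MG", "MN", "CA", "NA", "CL", "BR", "SE", "CU", "NI", "CO"})


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input."""


class UnknownChainError(KeyError):
    """Raised when a selection names a chain absent from the structure."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


@dataclass
class Residue:
    """One author-numbered residue with its heavy atoms."""

    chain_id: str
    seq_id: int
    icode: str
    name: str
    kind: str  # "protein" | "nucleic" | "other"
    atoms: list[Atom] = field(default_factory=list)

    @property
    def token(self) -> str:
        """Author residue number with insertion-code suffix (e.g. ``52A``)."""
        return f"{self.seq_id}{self.icode}"

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.icode)

    @property
    def one_letter(self) -> str:
        return AA3_TO_1.get(self.name, "X")

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Structure:
    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains.values():
            yield from chain

    def residue(self, chain_id: str, seq_id: int, icode: str = "") -> Residue:
        for res in self.chains[chain_id]:
            if res.seq_id == seq_id and res.icode == icode:
                return res
        raise KeyError((chain_id, seq_id, icode))

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())


@dataclass
class ResidueSet:
    """Ordered selection of residues from one structure."""

    structure: Structure
    members: tuple[Residue, ...]

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.members)

    @property
    def keys(self) -> tuple[tuple[str, int, str], ...]:
        return tuple(r.key for r in self.members)

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.members)

    @classmethod
    def from_keys(cls, structure: Structure,
                  keys: Iterable[tuple[str, int, str]]) -> "ResidueSet":
        members = []
        for chain_id, seq_id, icode in keys:
            if chain_id not in structure.chains:
                raise UnknownChainError(chain_id)
            members.append(structure.residue(chain_id, seq_id, icode))
        return cls(structure, tuple(members))


def _infer_element(atom_name: str) -> str:
    """Infer the element from an atom label when column 77-78 is blank."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    two = stripped[:2].upper()
    if two in _TWO_LETTER_ELEMENTS:
        return two
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _residue_kind(name: str) -> str:
    if name in STANDARD_AA:
        return "protein"
    if name in NUCLEOTIDE_NAMES:
        return "nucleic"
    return "other"


def parse_pdb(text: Union[str, io.TextIOBase], structure_id: str = "") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Only ``ATOM``/``HETATM`` records of the first model are used.
    Hydrogens (and deuteriums) and water residues are dropped; alternate
    locations keep the highest-occupancy copy (ties: first encountered);
    MSE is remapped to MET.  Residues within a chain are ordered by
    author number regardless of record order in the file.
    """
    if hasattr(text, "read"):
        text = text.read()
    if not text.strip():
        raise PDBParseError("empty input: no ATOM/HETATM records")

    # (chain, seq, icode) -> {"name": resname, "atoms": {atom_name: (occ, order, Atom)}}
    residues: dict[tuple[str, int, str], dict] = {}
    chain_order: list[str] = []
    past_first_model = False
    order_counter = 0

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "ENDMDL":
            past_first_model = True
            continue
        if rec not in ("ATOM", "HETATM") or past_first_model:
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated {rec} record")
        try:
            atom_name = line[12:16].strip()
            altloc = line[16].strip()
            resname = line[17:20].strip()
            chain_id = line[21].strip() or " "
            seq_id = int(line[22:26])
            icode = line[26].strip()
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            occ_field = line[54:60].strip() if len(line) >= 60 else ""
            occupancy = float(occ_field) if occ_field else 1.0
            element = line[76:78].strip() if len(line) >= 78 else ""
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: malformed {rec} record ({exc})") from exc

        if not element:
            element = _infer_element(atom_name)
        element = element.upper()
        if element in ("H", "D"):
            continue
        if resname in WATER_NAMES:
            continue
        resname = HET_TO_STANDARD.get(resname, resname)

        key = (chain_id, seq_id, icode)
        entry = residues.setdefault(key, {"name": resname, "atoms": {}})
        atom = Atom(atom_name, element, (x, y, z))
        prev = entry["atoms"].get(atom_name)
        if prev is None or (altloc and occupancy > prev[0]):
            keep_order = order_counter if prev is None else prev[1]
            entry["atoms"][atom_name] = (occupancy, keep_order, atom)
        order_counter += 1
        if chain_id not in chain_order:
            chain_order.append(chain_id)

    if not residues:
        raise PDBParseError("no ATOM/HETATM records found")

    structure = Structure(id=structure_id, chains={c: [] for c in chain_order})
    for key in sorted(residues, key=lambda k: (chain_order.index(k[0]), k[1], k[2])):
        chain_id, seq_id, icode = key
        entry = residues[key]
        atoms = [a for _, _, a in sorted(entry["atoms"].values(), key=lambda t: t[1])]
        structure.chains[chain_id].append(
            Residue(chain_id, seq_id, icode, entry["name"], _residue_kind(entry["name"]), atoms)
        )
    return structure


def write_pdb(structure: Structure) -> str:
    """Render a structure back to PDB text (coordinates to 3 decimals)."""
    lines = []
    serial = 0
    for chain_id, chain in structure.chains.items():
        for res in chain:
            record = "ATOM" if res.kind in ("protein", "nucleic") else "HETATM"
            for atom in res.atoms:
                serial += 1
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                x, y, z = atom.coord
                lines.append(
                    f"{record:<6s}{serial:>5d} {name:<4s} {res.name:<3s} {chain_id}"
                    f"{res.seq_id:>4d}{res.icode or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {atom.element:>2s}"
                )
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def select(structure: Structure, chain: str,
           span: Union[str, tuple[int, int], Sequence[int]] = "all") -> ResidueSet:
    """Select residues of one chain by an author-numbered inclusive span.

    ``span`` is either the string ``"all"`` or a ``(start, end)`` pair of
    1-based inclusive author residue numbers.  Residues missing from the
    span are silently absent; insertion codes compare on the integer part.
    """
    if chain not in structure.chains:
        raise UnknownChainError(f"unknown chain {chain!r} in structure {structure.id!r}")
    residues = sorted(structure.chains[chain], key=lambda r: (r.seq_id, r.icode))
    if span == "all":
        picked = residues
    else:
        start, end = span
        if start > end:
            raise ValueError(f"invalid span {start}..{end}")
        picked = [r for r in residues if start <= r.seq_id <= end]
    return ResidueSet(structure, tuple(picked))
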