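"""Residue polarity classes and the atom groups behind each interaction type.

The six polarity/hydrophobicity classes partition the 20 standard amino
acids: aliphatic {G,A,V,L,I,M}, negatively charged {D,E}, positively
charged {K,R,H}, polar {S,T,N,Q,C}, aromatic {F,W,Y} and proline {P}.
:func:`chem_groups` exposes, per residue, the heavy-atom groups between
which each interaction type is measured: side-chain carbons (plus Met SD)
for hydrophobic contacts, donor/acceptor atoms for hydrogen bonds,
ionizable side-chain atoms for salt bridges, and cation centres / ring
centroids for cation-pi detection.

Histidine is deliberately promiscuous: it is classed as positive and
participates as cation centre, aromatic ring, donor and acceptor, since
no protonation state is assigned; typed contact records let users filter
afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .structure_io import AA3_TO_1, STANDARD_AA, Atom, Residue

logger = logging.getLogger(__name__)

__all__ = ["ResidueClass", "ChemGroups", "classify_residue", "classify_letter", "chem_groups"]

ResidueClass = str  # one of the labels below

_CLASS_BY_LETTER = {
    **{aa: "aliphatic" for aa in "GAVLIM"},
    **{aa: "negative" for aa in "DE"},
    **{aa: "positive" for aa in "KRH"},
    **{aa: "polar" for aa in "STNQC"},
    **{aa: "aromatic" for aa in "FWY"},
    "P": "proline",
}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

# side-chain N/O/S that carry a polar hydrogen in the parent amino acid
SIDECHAIN_DONORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "CYS": ("SG",),
    "LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2"),
    "ASN": ("ND2",), "GLN": ("NE2",), "TRP": ("NE1",),
}

# side-chain lone-pair bearers; Met SD is a weak sulfur acceptor
SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "ASN": ("OD1",),
    "GLN": ("OE1",), "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "HIS": ("ND1", "NE2"), "MET": ("SD",),
}

# charged-group heavy atoms used for the ionic (salt-bridge) distance
IONIZABLE_ATOMS = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
    "LYS": ("NZ",), "ARG": ("NE", "CZ", "NH1", "NH2"), "HIS": ("ND1", "CE1", "NE2"),
}

RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

# residues contributing a cation centre: atom name, or ring/guanidinium centroid
_CATION_SPEC = {
    "LYS": ("atom", ("NZ",)),
    "ARG": ("centroid", ("NE", "CZ", "NH1", "NH2")),
    "HIS": ("centroid", RING_ATOMS["HIS"]),
}


def classify_residue(name: str) -> ResidueClass:
    """Polarity/hydrophobicity class of a standard amino acid (3-letter code)."""
    if name not in STANDARD_AA:
        raise ValueError(f"not a standard amino acid: {name!r}")
    return _CLASS_BY_LETTER[AA3_TO_1[name]]


def classify_letter(letter: str) -> ResidueClass:
    """Same classification keyed on the one-letter code."""
    try:
        return _CLASS_BY_LETTER[letter.upper()]
    except KeyError:
        raise ValueError(f"not a standard amino acid letter: {letter!r}") from None


@dataclass
class ChemGroups:
    """Interaction-defining atom groups of one protein residue."""

    hydrophobic_atoms: list[Atom] = field(default_factory=list)
    donors: list[tuple[Atom, str]] = field(default_factory=list)
    acceptors: list[tuple[Atom, str]] = field(default_factory=list)
    ionizable_atoms: list[Atom] = field(default_factory=list)
    cation_centers: list[np.ndarray] = field(default_factory=list)
    ring_centroid: np.ndarray | None = None


def _named_atoms(residue: Residue, names: tuple[str, ...], warn_context: str) -> list[Atom]:
    found = []
    missing = []
    for name in names:
        atom = residue.atom(name)
        if atom is None:
            missing.append(name)
        else:
            found.append(atom)
    if missing:
        logger.warning("%s %s%s: missing %s atoms %s; using available atoms",
                       residue.name, residue.chain_id, residue.token, warn_context, missing)
    return found


def chem_groups(residue: Residue) -> ChemGroups:
    """Compute the per-type atom groups of a protein residue.

    Missing side-chain atoms are tolerated (groups are computed from the
    atoms present, with a logged warning).
    """
    if residue.kind != "protein":
        raise ValueError(f"chem_groups requires a protein residue, got {residue.name!r}")

    groups = ChemGroups()

    for atom in residue.atoms:
        if atom.name in BACKBONE_ATOMS:
            continue
        if atom.element == "C":
            groups.hydrophobic_atoms.append(atom)
    sd = residue.atom("SD")
    if residue.name == "MET" and sd is not None:
        groups.hydrophobic_atoms.append(sd)

    backbone_n = residue.atom("N")
    if backbone_n is not None:
        groups.donors.append((backbone_n, backbone_n.element))
    for atom in _named_atoms(residue, SIDECHAIN_DONORS.get(residue.name, ()), "donor"):
        groups.donors.append((atom, atom.element))

    backbone_o = residue.atom("O")
    if backbone_o is not None:
        groups.acceptors.append((backbone_o, backbone_o.element))
    for atom in _named_atoms(residue, SIDECHAIN_ACCEPTORS.get(residue.name, ()), "acceptor"):
        groups.acceptors.append((atom, atom.element))

    groups.ionizable_atoms = _named_atoms(
        residue, IONIZABLE_ATOMS.get(residue.name, ()), "ionizable")

    if residue.name in RING_ATOMS:
        ring = _named_atoms(residue, RING_ATOMS[residue.name], "ring")
        if ring:
            groups.ring_centroid = np.mean([a.coord for a in ring], axis=0)

    spec = _CATION_SPEC.get(residue.name)
    if spec is not None:
        mode, names = spec
        atoms = _named_atoms(residue, names, "cation")
        if atoms:
            if mode == "atom":
                groups.cation_centers = [a.xyz for a in atoms]
            else:
                groups.cation_centers = [np.mean([a.coord for a in atoms], axis=0)]

    return groups
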