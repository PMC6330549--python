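"""Synthetic fixtures with exactly known ground truth.

Three generators cover every pipeline stage without any external data:

* :func:`make_toy_structure` — a PDB-format two-chain "interface" in which
  each planted residue pair realizes exactly one interaction type at an
  exact target distance, decoy pairs sit outside every cutoff, and an
  optional DNA stub drives the DNA-contact flag.
* :func:`make_motif_db` — a FASTA database with planted motif instances
  and optional exclusion-tagged records, background-cleaned so the truth
  table is exact.
* :func:`make_alignment_block` — an ungapped alignment block sampled from
  a consensus pattern such that the pattern is recoverable column-wise.

Residues are built from synthetic idealized side-chain templates laid out
along a local x axis: bond lengths are plausible but the only controlled
quantity is the distance between the type-defining atom groups, which is
exact by construction.  Each planted pair lives in its own spatial cell
30 A from every other, so no cross-cell pair approaches any cutoff.  The
templates place each type's anchor atom (or group centroid) at the
maximal-x tip of the side chain, which guarantees the anchor pair is the
global minimum-distance atom pair across the interface.

Every generator is a pure function of its arguments and the seed:
identical calls yield byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .contact_map import (InteractionCutoffs, ResidueId, TypedContact,
                          detect_contact_types)
from .motif import AlignmentBlock, ConsensusPattern, MotifHit, SequenceRecord, \
    write_fasta
from .structure_io import Atom, Residue, Structure, write_pdb

__all__ = [
    "PlantedContactSpec",
    "ContactTruth",
    "MotifDBTruth",
    "BlockTruth",
    "PairedFixture",
    "make_toy_structure",
    "make_paired_structures",
    "make_random_interface",
    "make_motif_db",
    "make_alignment_block",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

# ---------------------------------------------------------------------------
# residue templates: synthetic idealized geometry along a local +x side chain
# ---------------------------------------------------------------------------

_BACKBONE = [
    ("N", (-1.46, 0.75, 0.0)),
    ("CA", (0.0, 0.0, 0.0)),
    ("C", (-0.55, -1.41, 0.0)),
    ("O", (-1.78, -1.55, 0.0)),
]


def _ring(center_x: float, radius: float, names: Sequence[str]) -> list[tuple]:
    """Ring atoms on a circle in the y-z plane (plane normal along x)."""
    out = []
    for k, name in enumerate(names):
        theta = 2 * np.pi * k / len(names)
        out.append((name, (center_x, radius * np.cos(theta), radius * np.sin(theta))))
    return out


_SIDECHAINS: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [("CB", (1.50, 0.0, 0.0))],
    "VAL": [("CB", (1.50, 0.25, 0.0)), ("CG1", (2.95, 0.0, 0.0)),
            ("CG2", (1.95, 1.65, 0.20))],
    "LEU": [("CB", (1.50, 0.30, 0.0)), ("CG", (2.85, -0.20, 0.0)),
            ("CD1", (4.30, 0.0, 0.0)), ("CD2", (3.20, -1.60, 0.30))],
    "ILE": [("CB", (1.50, 0.30, 0.0)), ("CG1", (2.90, -0.10, 0.0)),
            ("CG2", (1.95, 1.70, 0.0)), ("CD1", (4.35, 0.0, 0.0))],
    "MET": [("CB", (1.50, 0.30, 0.0)), ("CG", (2.90, -0.10, 0.0)),
            ("SD", (4.40, 0.50, 0.0)), ("CE", (5.90, 0.0, 0.0))],
    "CYS": [("CB", (1.50, 0.30, 0.0)), ("SG", (3.00, 0.0, 0.0))],
    "SER": [("CB", (1.50, 0.40, 0.0)), ("OG", (2.90, 0.0, 0.0))],
    "THR": [("CB", (1.50, 0.30, 0.0)), ("OG1", (2.95, 0.0, 0.0)),
            ("CG2", (1.95, 1.70, 0.0))],
    "ASN": [("CB", (1.50, 0.30, 0.0)), ("CG", (2.85, -0.10, 0.0)),
            ("OD1", (3.40, -1.20, 0.0)), ("ND2", (4.10, 0.0, 0.0))],
    "GLN": [("CB", (1.50, 0.30, 0.0)), ("CG", (2.90, 0.0, 0.0)),
            ("CD", (4.30, -0.20, 0.0)), ("OE1", (4.90, -1.30, 0.0)),
            ("NE2", (5.55, 0.0, 0.0))],
    "ASP": [("CB", (1.50, 0.30, 0.0)), ("CG", (2.90, -0.10, 0.0)),
            ("OD1", (4.15, 0.0, 0.0)), ("OD2", (3.30, -1.30, 0.0))],
    "GLU": [("CB", (1.50, 0.30, 0.0)), ("CG", (2.90, 0.0, 0.0)),
            ("CD", (4.30, -0.20, 0.0)), ("OE1", (5.55, 0.0, 0.0)),
            ("OE2", (4.70, -1.45, 0.0))],
    "LYS": [("CB", (1.50, 0.30, 0.0)), ("CG", (2.90, 0.0, 0.0)),
            ("CD", (4.30, 0.30, 0.0)), ("CE", (5.70, 0.0, 0.0)),
            ("NZ", (7.20, 0.0, 0.0))],
    "ARG": [("CB", (1.50, 0.30, 0.0)), ("CG", (2.90, 0.0, 0.0)),
            ("CD", (4.30, 0.90, 0.0)), ("NE", (5.80, 1.33, 0.0)),
            ("CZ", (5.80, 0.0, 0.0)), ("NH1", (5.80, -0.67, 1.15)),
            ("NH2", (5.80, -0.67, -1.15))],
    "PHE": [("CB", (2.20, 1.00, 0.0))] + _ring(3.60, 1.39,
            ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]),
    "TYR": [("CB", (2.20, 1.00, 0.0))] + _ring(3.60, 1.39,
            ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]) + [("OH", (3.60, -2.78, 0.0))],
    "TRP": [("CB", (2.40, 1.20, 0.0))] + _ring(3.70, 1.60,
            ["CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ2", "CZ3", "CH2"]),
    "HIS": [("CB", (2.10, 1.00, 0.0))] + _ring(3.40, 1.14,
            ["CG", "ND1", "CE1", "NE2", "CD2"]),
    "PRO": [("CB", (1.40, 0.50, 0.0)), ("CG", (1.10, 1.80, 0.40)),
            ("CD", (-0.30, 1.90, 0.20))],
}

# per-residue anchor for each interaction role; ("atom", name) or ("centroid", names)
_ANCHORS: dict[str, dict[str, tuple]] = {
    "ALA": {"hydrophobic": ("atom", "CB")},
    "VAL": {"hydrophobic": ("atom", "CG1")},
    "LEU": {"hydrophobic": ("atom", "CD1")},
    "ILE": {"hydrophobic": ("atom", "CD1")},
    "MET": {"hydrophobic": ("atom", "CE"), "acceptor": ("atom", "SD")},
    "CYS": {"donor": ("atom", "SG")},
    "SER": {"donor": ("atom", "OG"), "acceptor": ("atom", "OG")},
    "THR": {"donor": ("atom", "OG1"), "acceptor": ("atom", "OG1")},
    "ASN": {"donor": ("atom", "ND2")},
    "GLN": {"donor": ("atom", "NE2")},
    "ASP": {"ionic": ("atom", "OD1"), "acceptor": ("atom", "OD1")},
    "GLU": {"ionic": ("atom", "OE1"), "acceptor": ("atom", "OE1")},
    "LYS": {"ionic": ("atom", "NZ"), "donor": ("atom", "NZ"),
            "cation": ("atom", "NZ")},
    "ARG": {"ionic": ("atom", "CZ"),
            "cation": ("centroid", ("NE", "CZ", "NH1", "NH2"))},
    "PHE": {"ring": ("centroid", ("CG", "CD1", "CE1", "CZ", "CE2", "CD2"))},
    "TYR": {"ring": ("centroid", ("CG", "CD1", "CE1", "CZ", "CE2", "CD2"))},
    "TRP": {"ring": ("centroid", ("CG", "CD1", "NE1", "CE2", "CD2",
                                  "CE3", "CZ2", "CZ3", "CH2"))},
    "HIS": {"ring": ("centroid", ("CG", "ND1", "CE1", "NE2", "CD2"))},
}

_ROLE_BY_TYPE = {
    "hydrophobic": ("hydrophobic", "hydrophobic"),
    "ionic": ("ionic", "ionic"),
    "hbond": ("donor", "acceptor"),
    "cation_pi": ("cation", "ring"),
}

_NUCLEOTIDE_ATOMS = [
    ("P", (0.0, 0.0, 0.0)), ("O5'", (0.8, 1.2, 0.0)),
    ("C5'", (2.0, 1.6, 0.4)), ("C1'", (3.0, 0.8, 0.8)),
    ("N1", (3.5, -0.5, 0.4)),
]

_CELL_SPACING = 30.0
_DECOY_SEPARATION = 7.5  # beyond every default cutoff plus the default margin


def _template_atoms(resname: str) -> list[tuple[str, np.ndarray]]:
    if resname not in _SIDECHAINS:
        raise ValueError(f"no synthetic template for residue {resname!r}")
    atoms = _BACKBONE + _SIDECHAINS[resname]
    return [(name, np.asarray(xyz, dtype=float)) for name, xyz in atoms]


def _anchor_point(resname: str, role: str,
                  atoms: dict[str, np.ndarray]) -> np.ndarray:
    spec = _ANCHORS.get(resname, {}).get(role)
    if spec is None:
        raise ValueError(f"{resname} cannot anchor a {role!r} interaction "
                         "in the synthetic templates")
    mode, names = spec
    if mode == "atom":
        return atoms[names]
    return np.mean([atoms[n] for n in names], axis=0)


def _tip_x(atoms: dict[str, np.ndarray]) -> np.ndarray:
    """Coordinate of the maximal-x atom (used to separate decoy pairs)."""
    return max(atoms.values(), key=lambda p: p[0])


def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _build_residue(chain: str, seq_id: int, resname: str,
                   anchor: np.ndarray, target: np.ndarray,
                   mirror: bool, kind: str = "protein") -> Residue:
    """Place a template so that ``anchor`` (template frame, possibly
    mirrored) lands exactly on ``target``."""
    atoms = []
    flip = -1.0 if mirror else 1.0
    a = anchor.copy()
    a[0] *= flip
    shift = target - a
    template = (_template_atoms(resname) if kind == "protein"
                else [(n, np.asarray(x)) for n, x in _NUCLEOTIDE_ATOMS])
    for name, xyz in template:
        pos = xyz.copy()
        pos[0] *= flip
        pos = pos + shift
        atoms.append(Atom(name, _element_of(name), tuple(np.round(pos, 3))))
    return Residue(chain, seq_id, "", resname, kind, atoms)


@dataclass(frozen=True)
class PlantedContactSpec:
    """One residue pair to build at an exact interaction distance.

    ``res_a`` carries the first role of the type (donor for hbond, the
    cation for cation-pi); ``distance`` is the type-defining group
    distance in Angstrom.  ``margin`` documents how far the pair stays
    from the cutoff and is validated against it.
    """

    type: str
    res_a: str
    res_b: str
    distance: float
    margin: float = 0.5

    def __post_init__(self) -> None:
        if self.type not in _ROLE_BY_TYPE:
            raise ValueError(f"unknown interaction type {self.type!r}")
        if self.margin <= 0:
            raise ValueError("margin must be positive")


def _cutoff_for(spec: PlantedContactSpec, cutoffs: InteractionCutoffs) -> float:
    if spec.type == "hbond":
        donor_anchor = _ANCHORS[spec.res_a]["donor"][1]
        sulfur = donor_anchor.startswith("S") or \
            _ANCHORS[spec.res_b]["acceptor"][1].startswith("S")
        return cutoffs.hbond_S_donor if sulfur else cutoffs.hbond_NO_donor
    return getattr(cutoffs, spec.type)


@dataclass
class ContactTruth:
    """Exact expected output for a planted-contact structure."""

    contacts: tuple[TypedContact, ...]
    dna_flags: dict[tuple[str, int, str], bool]
    side_a_keys: tuple[tuple[str, int, str], ...]
    side_b_keys: tuple[tuple[str, int, str], ...]

    def to_tsv(self) -> str:
        lines = ["chain_a\tseq_a\tresname_a\tchain_b\tseq_b\tresname_b\ttype\tdistance_angstrom"]
        for c in self.contacts:
            lines.append(f"{c.res_a.chain}\t{c.res_a.token}\t{c.res_a.name}"
                         f"\t{c.res_b.chain}\t{c.res_b.token}\t{c.res_b.name}"
                         f"\t{c.type}\t{c.distance:.3f}")
        return "\n".join(lines) + "\n"


def _assemble(specs: Sequence[PlantedContactSpec], active: Sequence[bool],
              decoys: int, dna: bool, rng: np.random.Generator,
              structure_id: str, cutoffs: InteractionCutoffs
              ) -> tuple[str, ContactTruth]:
    chain_a_res: list[Residue] = []
    chain_b_res: list[Residue] = []
    dna_res: list[Residue] = []
    truths: list[TypedContact] = []

    decoy_names = [n for n in _SIDECHAINS if n != "GLY"]
    cell = 0

    for spec, is_active in zip(specs, active):
        origin = np.array([0.0, cell * _CELL_SPACING, 0.0])
        cell += 1
        role_a, role_b = _ROLE_BY_TYPE[spec.type]
        atoms_a = dict(_template_atoms(spec.res_a))
        atoms_b = dict(_template_atoms(spec.res_b))
        anchor_a = _anchor_point(spec.res_a, role_a, atoms_a)
        anchor_b = _anchor_point(spec.res_b, role_b, atoms_b)

        cutoff = _cutoff_for(spec, cutoffs)
        if is_active:
            distance = spec.distance
            if not (0 < distance <= cutoff - spec.margin + 1e-9):
                raise ValueError(
                    f"planted {spec.type} distance {distance} does not stay "
                    f"{spec.margin} A inside the {cutoff} A cutoff")
        else:
            distance = cutoff + 2.0

        seq_a, seq_b = len(chain_a_res) + 1, len(chain_b_res) + 1
        res_a = _build_residue("A", seq_a, spec.res_a, anchor_a, origin, mirror=False)
        res_b = _build_residue("B", seq_b, spec.res_b, anchor_b,
                               origin + np.array([distance, 0.0, 0.0]), mirror=True)
        chain_a_res.append(res_a)
        chain_b_res.append(res_b)

        realized = {c.type: c for c in detect_contact_types(res_a, res_b, cutoffs)}
        if is_active:
            if set(realized) != {spec.type}:
                raise ValueError(
                    f"spec {spec} is not cleanly satisfiable: realized types "
                    f"{sorted(realized)}")
            truths.append(TypedContact(
                ResidueId("A", seq_a, "", spec.res_a),
                ResidueId("B", seq_b, "", spec.res_b),
                spec.type, realized[spec.type].distance, structure_id))
        elif realized:
            raise ValueError(f"inactive pair {spec} still realizes {sorted(realized)}")

    for _ in range(decoys):
        origin = np.array([0.0, cell * _CELL_SPACING, 0.0])
        cell += 1
        name_a, name_b = (str(n) for n in rng.choice(decoy_names, size=2))
        separation = _DECOY_SEPARATION + float(rng.uniform(0.0, 2.0))
        atoms_a = dict(_template_atoms(name_a))
        atoms_b = dict(_template_atoms(name_b))
        res_a = _build_residue("A", len(chain_a_res) + 1, name_a,
                               _tip_x(atoms_a), origin, mirror=False)
        res_b = _build_residue("B", len(chain_b_res) + 1, name_b,
                               _tip_x(atoms_b), origin + np.array([separation, 0, 0]),
                               mirror=True)
        chain_a_res.append(res_a)
        chain_b_res.append(res_b)

    dna_flags: dict[tuple[str, int, str], bool] = {}
    if dna:
        origin = np.array([0.0, cell * _CELL_SPACING, 0.0])
        for i, nt in enumerate(("DA", "DT", "DG", "DC")):
            dna_res.append(_build_residue(
                "D", i + 1, nt, np.zeros(3), origin + np.array([i * 4.5, 0.0, 0.0]),
                mirror=False, kind="nucleic"))
        # one extra protein residue with its CA exactly 4.0 A from the
        # nearest DNA heavy atom (the 5'-most phosphate)
        gly_atoms = dict(_template_atoms("GLY"))
        near = _build_residue("A", len(chain_a_res) + 1, "GLY",
                              gly_atoms["CA"], origin + np.array([-4.0, 0.0, 0.0]),
                              mirror=False)
        chain_a_res.append(near)
        dna_flags[near.key] = True

    for res in chain_a_res + chain_b_res:
        dna_flags.setdefault(res.key, False)

    structure = Structure(id=structure_id, chains={
        "A": chain_a_res, "B": chain_b_res, **({"D": dna_res} if dna else {})})
    truth = ContactTruth(
        tuple(truths), dna_flags,
        tuple(r.key for r in chain_a_res), tuple(r.key for r in chain_b_res))
    return write_pdb(structure), truth


def make_toy_structure(specs: Sequence[PlantedContactSpec], decoys: int = 0,
                       dna: bool = False, seed: int = 0,
                       structure_id: str = "toy",
                       cutoffs: InteractionCutoffs | None = None
                       ) -> tuple[str, ContactTruth]:
    """Build PDB text with planted typed contacts and an exact truth table.

    Each planted pair is constructed in its own spatial cell with the
    type-defining group distance equal to ``spec.distance`` exactly; decoy
    pairs are separated beyond every cutoff.  With ``dna=True`` a
    4-nucleotide stub is added plus one protein residue 4.0 A from it.
    """
    rng = np.random.default_rng(seed)
    return _assemble(specs, [True] * len(specs), decoys, dna, rng,
                     structure_id, cutoffs or InteractionCutoffs())


@dataclass
class PairedFixture:
    pdb_a: str
    truth_a: ContactTruth
    pdb_b: str
    truth_b: ContactTruth
    mapping: dict[tuple[str, int, str], tuple[str, int, str]]


def make_paired_structures(shared: Sequence[PlantedContactSpec],
                           a_only: Sequence[PlantedContactSpec],
                           b_only: Sequence[PlantedContactSpec],
                           decoys: int = 0, seed: int = 0,
                           cutoffs: InteractionCutoffs | None = None) -> PairedFixture:
    """Two structures over the same residue layout whose contact maps
    intersect exactly on ``shared``.

    Pairs absent from one structure are rebuilt there beyond every cutoff
    (the residues exist in both, so the identity residue mapping covers
    every contact)."""
    cutoffs = cutoffs or InteractionCutoffs()
    specs = list(shared) + list(a_only) + list(b_only)
    active_a = [True] * len(shared) + [True] * len(a_only) + [False] * len(b_only)
    active_b = [True] * len(shared) + [False] * len(a_only) + [True] * len(b_only)
    pdb_a, truth_a = _assemble(specs, active_a, decoys, False,
                               np.random.default_rng(seed), "synthA", cutoffs)
    pdb_b, truth_b = _assemble(specs, active_b, decoys, False,
                               np.random.default_rng(seed), "synthB", cutoffs)
    mapping = {key: key for key in truth_a.side_a_keys + truth_a.side_b_keys}
    return PairedFixture(pdb_a, truth_a, pdb_b, truth_b, mapping)


def make_random_interface(n_a: int, n_b: int, seed: int = 0,
                          box: float = 16.0, structure_id: str = "rand") -> Structure:
    """Randomly posed residues on two chains, for oracle-equivalence tests.

    Unlike the planted fixtures nothing is controlled here: residues get
    random identities, rotations and positions inside a cube of side
    ``box``; the resulting contact map is whatever the rules say.
    """
    rng = np.random.default_rng(seed)
    names = [n for n in _SIDECHAINS]
    chains: dict[str, list[Residue]] = {"A": [], "B": []}
    for chain_id, count in (("A", n_a), ("B", n_b)):
        for i in range(count):
            resname = str(rng.choice(names))
            # random rotation via QR decomposition of a Gaussian matrix
            q, r = np.linalg.qr(rng.normal(size=(3, 3)))
            q *= np.sign(np.diag(r))
            shift = rng.uniform(0.0, box, size=3)
            atoms = [Atom(name, _element_of(name), tuple(np.round(q @ xyz + shift, 3)))
                     for name, xyz in _template_atoms(resname)]
            chains[chain_id].append(Residue(chain_id, i + 1, "", resname, "protein", atoms))
    return Structure(id=structure_id, chains=chains)


# ---------------------------------------------------------------------------
# motif database and alignment-block fixtures
# ---------------------------------------------------------------------------


@dataclass
class MotifDBTruth:
    records: tuple[SequenceRecord, ...]
    # per planted pattern: the hits an exclusion-filtered scan must return
    expected_by_pattern: tuple[tuple[MotifHit, ...], ...]
    carrier_ids: tuple[str, ...]  # records carrying any planted query motif
    excluded_ids: tuple[str, ...]  # carriers additionally holding the exclusion motif

    @property
    def expected_hits(self) -> tuple[MotifHit, ...]:
        return self.expected_by_pattern[0] if self.expected_by_pattern else ()


def _realize(pattern: ConsensusPattern, rng: np.random.Generator) -> str:
    letters = []
    for pos in pattern.positions:
        choices = list(pos) if pos is not None else list(AA_ORDER)
        letters.append(str(rng.choice(choices)))
    return "".join(letters)


def _plant(seq: list[str], window: str, start: int) -> None:
    seq[start:start + len(window)] = list(window)


def make_motif_db(n_records: int, planted: Sequence[tuple[ConsensusPattern, int]],
                  exclusion_pattern: ConsensusPattern | None = None,
                  exclusion_tagged: int = 0,
                  length_range: tuple[int, int] = (40, 60),
                  seed: int = 0) -> tuple[str, MotifDBTruth]:
    """FASTA database with planted motif instances and exact expected hits.

    ``planted`` lists (pattern, number of carrier records); each carrier
    holds one instance.  ``exclusion_tagged`` of the first pattern's
    carriers additionally receive one instance of ``exclusion_pattern``
    (those records must not be reported by an exclusion-filtered scan).
    Background windows that accidentally match any involved pattern are
    re-drawn, so the truth table is exact.
    """
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    for pattern, count in planted:
        if count > n_records:
            raise ValueError("more carriers requested than records")
        if len(pattern) > lo:
            raise ValueError("pattern longer than the shortest record")
    if exclusion_tagged and exclusion_pattern is None:
        raise ValueError("exclusion_tagged requires an exclusion pattern")

    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(n_records)]
    seqs = [[str(ch) for ch in rng.choice(list(AA_ORDER), size=ln)] for ln in lengths]

    all_patterns = [p for p, _ in planted] + \
        ([exclusion_pattern] if exclusion_pattern is not None else [])
    planted_windows: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n_records)}
    planted_hits: dict[int, list[tuple[ConsensusPattern, int]]] = \
        {i: [] for i in range(n_records)}

    carriers_by_pattern: list[list[int]] = []
    for pattern, count in planted:
        carriers = sorted(int(i) for i in
                          rng.choice(n_records, size=count, replace=False))
        carriers_by_pattern.append(carriers)
        for idx in carriers:
            start = _free_start(lengths[idx], len(pattern), planted_windows[idx], rng)
            _plant(seqs[idx], _realize(pattern, rng), start)
            planted_windows[idx].append((start, start + len(pattern)))
            planted_hits[idx].append((pattern, start))

    excluded: list[int] = []
    if exclusion_pattern is not None and exclusion_tagged:
        first_carriers = carriers_by_pattern[0] if carriers_by_pattern else []
        if exclusion_tagged > len(first_carriers):
            raise ValueError("exclusion_tagged exceeds the first pattern's carriers")
        for idx in first_carriers[:exclusion_tagged]:
            start = _free_start(lengths[idx], len(exclusion_pattern),
                                planted_windows[idx], rng)
            _plant(seqs[idx], _realize(exclusion_pattern, rng), start)
            planted_windows[idx].append((start, start + len(exclusion_pattern)))
            planted_hits[idx].append((exclusion_pattern, start))
            excluded.append(idx)

    records = []
    for i in range(n_records):
        rid = f"rec{i + 1:03d}"
        seq = _scrub_accidentals(seqs[i], all_patterns, planted_hits[i],
                                 planted_windows[i], rng)
        records.append(SequenceRecord(rid, seq, f"synthetic record {i + 1}"))

    excluded_set = set(excluded)
    expected_by_pattern = []
    for pattern, carriers in zip((p for p, _ in planted), carriers_by_pattern):
        expected: list[MotifHit] = []
        for idx in carriers:
            if idx in excluded_set:
                continue
            for pat, start in planted_hits[idx]:
                if pat is pattern:
                    expected.append(MotifHit(
                        records[idx].id, start + 1,
                        records[idx].seq[start:start + len(pat)]))
        expected.sort(key=lambda h: (h.record_id, h.start))
        expected_by_pattern.append(tuple(expected))

    truth = MotifDBTruth(
        tuple(records), tuple(expected_by_pattern),
        tuple(records[i].id for i in sorted({i for c in carriers_by_pattern for i in c})),
        tuple(records[i].id for i in sorted(excluded_set)))
    return write_fasta(records), truth


def _free_start(length: int, width: int, taken: list[tuple[int, int]],
                rng: np.random.Generator) -> int:
    candidates = [s for s in range(length - width + 1)
                  if all(s + width <= a or s >= b for a, b in taken)]
    if not candidates:
        raise ValueError("no room to plant a motif window")
    return int(rng.choice(candidates))


def _scrub_accidentals(seq: list[str], patterns: list[ConsensusPattern],
                       planted: list[tuple[ConsensusPattern, int]],
                       windows: list[tuple[int, int]],
                       rng: np.random.Generator, max_rounds: int = 200) -> str:
    """Redraw background letters until the only matches are the planted ones."""
    planted_starts = {(id(p), s) for p, s in planted}
    in_window = [any(a <= i < b for a, b in windows) for i in range(len(seq))]
    for _ in range(max_rounds):
        dirty = False
        text = "".join(seq)
        for pattern in patterns:
            for start in range(len(text) - len(pattern) + 1):
                if not pattern.matches_at(text, start):
                    continue
                if (id(pattern), start) in planted_starts:
                    continue
                background = [i for i in range(start, start + len(pattern))
                              if not in_window[i]]
                if not background:
                    raise ValueError("accidental match entirely inside planted windows")
                for i in background:
                    seq[i] = str(rng.choice(list(AA_ORDER)))
                dirty = True
        if not dirty:
            return "".join(seq)
    raise ValueError("could not scrub accidental motif matches")


@dataclass
class BlockTruth:
    block: AlignmentBlock
    expected_pattern: ConsensusPattern
    realized_columns: tuple[tuple[str, ...], ...]  # distinct letters per column


def make_alignment_block(pattern: ConsensusPattern, n_rows: int, seed: int = 0,
                         max_alternatives: int = 3) -> BlockTruth:
    """Sample an ungapped block from a pattern so that column-wise
    consensus derivation recovers it.

    Every alternative set is fully witnessed across rows (requires
    ``n_rows`` >= the largest set).  Wildcard columns are sampled
    uniformly; the realized distinct letters per column are recorded, and
    the expected pattern is computed from them with the stated column
    rule (a wildcard column may legitimately come back as a set when few
    distinct letters were sampled).
    """
    if n_rows < 2:
        raise ValueError("need at least 2 rows")
    widest = max((len(p) for p in pattern.positions if p is not None), default=1)
    if n_rows < widest:
        raise ValueError(f"n_rows={n_rows} cannot witness a set of {widest} alternatives")

    rng = np.random.default_rng(seed)
    columns: list[list[str]] = []
    for pos in pattern.positions:
        if pos is None:
            col = [str(rng.choice(list(AA_ORDER))) for _ in range(n_rows)]
        else:
            col = list(pos) + [str(rng.choice(list(pos)))
                               for _ in range(n_rows - len(pos))]
            rng.shuffle(col)
        columns.append(col)

    rows = tuple("".join(columns[c][r] for c in range(len(columns)))
                 for r in range(n_rows))
    block = AlignmentBlock(rows, tuple((f"row{r + 1}", 1) for r in range(n_rows)))

    expected_positions = []
    realized = []
    for col in columns:
        counts = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        distinct = sorted(counts)
        realized.append(tuple(distinct))
        if len(distinct) == 1:
            expected_positions.append((distinct[0],))
        elif len(distinct) <= max_alternatives:
            expected_positions.append(tuple(
                sorted(distinct, key=lambda ch: (-counts[ch], ch))))
        else:
            expected_positions.append(None)
    expected = ConsensusPattern(tuple(expected_positions))
    return BlockTruth(block, expected, tuple(realized))
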