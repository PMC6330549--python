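"""Typed residue-residue interaction detection across an interface.

Interactions between two residue sets are typed by heavy-atom (or
group-centroid) minimum distances under fixed cutoffs: 5 A for
hydrophobic contacts, 6 A for ionic and cation-pi interactions, and
3.5 A / 4.0 A for hydrogen bonds depending on whether the donor is
oxygen/nitrogen or sulphur.  Residues within 5 A of any DNA heavy atom
are flagged as DNA contacts.  No angular criterion is applied to
hydrogen bonds: the rules are purely distance-based, and a residue pair
may carry several interaction types at once (e.g. a salt bridge is both
ionic and hydrogen bonded).

Two maps over homologous structures can be compared through a
one-to-one residue mapping, partitioning contacts into shared /
first-only / second-only, mirroring the solid / broken / dashed
line convention used for such interface diagrams.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .residue_chemistry import ChemGroups, chem_groups, classify_residue
from .structure_io import Residue, ResidueSet

__all__ = [
    "InteractionCutoffs",
    "ResidueId",
    "TypedContact",
    "ContactMap",
    "ComparativeMap",
    "detect_contact_types",
    "build_contact_map",
    "interface_character",
    "compare_maps",
    "mapping_from_alignment",
    "write_contact_tsv",
    "write_comparative_tsv",
]

INTERACTION_TYPES = ("hydrophobic", "ionic", "hbond", "cation_pi")


@dataclass(frozen=True)
class InteractionCutoffs:
    """Distance cutoffs (Angstrom) per interaction type.

    ``sulfur_acceptor_extends`` applies the 4.0 A sulfur threshold also
    when the *acceptor* atom is sulphur (e.g. Met SD), not only the donor.
    """

    hydrophobic: float = 5.0
    ionic: float = 6.0
    cation_pi: float = 6.0
    hbond_NO_donor: float = 3.5
    hbond_S_donor: float = 4.0
    dna_contact: float = 5.0
    sulfur_acceptor_extends: bool = True

    def __post_init__(self) -> None:
        for name in ("hydrophobic", "ionic", "cation_pi",
                     "hbond_NO_donor", "hbond_S_donor", "dna_contact"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cutoff {name} must be positive")


class ResidueId(NamedTuple):
    chain: str
    seq: int
    icode: str
    name: str

    @property
    def token(self) -> str:
        return f"{self.seq}{self.icode}"

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seq, self.icode)


def _rid(res: Residue) -> ResidueId:
    return ResidueId(res.chain_id, res.seq_id, res.icode, res.name)


@dataclass(frozen=True)
class TypedContact:
    res_a: ResidueId
    res_b: ResidueId
    type: str
    distance: float
    source: str = ""

    @property
    def pair_key(self) -> tuple:
        return (self.res_a.key, self.res_b.key, self.type)


@dataclass
class ContactMap:
    contacts: tuple[TypedContact, ...]
    side_a: ResidueSet
    side_b: ResidueSet
    dna_flags: dict[tuple[str, int, str], bool]
    source: str = ""
    cutoffs: InteractionCutoffs = field(default_factory=InteractionCutoffs)

    def __len__(self) -> int:
        return len(self.contacts)


@dataclass
class ComparativeMap:
    """Contacts shared by two maps vs. unique to either, after residue translation."""

    shared: tuple[tuple[TypedContact, TypedContact], ...]  # (a-version, b-version)
    only_a: tuple[TypedContact, ...]
    only_b: tuple[TypedContact, ...]
    mapping: dict[tuple[str, int, str], tuple[str, int, str]]

    def memberships(self) -> list[tuple[TypedContact, str]]:
        """All contacts in first-structure coordinates where translatable.

        ``only_b`` contacts are expressed in second-structure coordinates
        (their residues may be unmapped).
        """
        rows = [(ca, "both") for ca, _ in self.shared]
        rows += [(c, "a_only") for c in self.only_a]
        rows += [(c, "b_only") for c in self.only_b]
        return rows


def _min_distance(xyz_a: np.ndarray, xyz_b: np.ndarray) -> float:
    if len(xyz_a) == 0 or len(xyz_b) == 0:
        return float("inf")
    diff = xyz_a[:, None, :] - xyz_b[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=-1)).min())


def _group_coords(atoms: Iterable) -> np.ndarray:
    pts = [a.coord for a in atoms]
    return np.asarray(pts, dtype=float).reshape(len(pts), 3)


def _hbond_distance(ga: ChemGroups, gb: ChemGroups, cutoffs: InteractionCutoffs) -> float | None:
    """Minimal qualifying donor-acceptor distance across both directions."""
    best = None
    for donors, acceptors in ((ga.donors, gb.acceptors), (gb.donors, ga.acceptors)):
        for donor, d_elem in donors:
            for acceptor, a_elem in acceptors:
                is_s = d_elem == "S" or (cutoffs.sulfur_acceptor_extends and a_elem == "S")
                limit = cutoffs.hbond_S_donor if is_s else cutoffs.hbond_NO_donor
                d = float(np.linalg.norm(donor.xyz - acceptor.xyz))
                if d <= limit and (best is None or d < best):
                    best = d
    return best


def detect_contact_types(res_a: Residue, res_b: Residue,
                         cutoffs: InteractionCutoffs | None = None,
                         source: str = "") -> set[TypedContact]:
    """Evaluate all four interaction rules for one cross-interface residue pair."""
    cutoffs = cutoffs or InteractionCutoffs()
    if res_a.kind != "protein" or res_b.kind != "protein":
        raise ValueError("contact typing requires two protein residues")
    return _detect(res_a, res_b, chem_groups(res_a), chem_groups(res_b),
                   cutoffs, source)


def _detect(res_a: Residue, res_b: Residue, ga: ChemGroups, gb: ChemGroups,
            cutoffs: InteractionCutoffs, source: str) -> set[TypedContact]:
    ida, idb = _rid(res_a), _rid(res_b)
    out: set[TypedContact] = set()

    d = _min_distance(_group_coords(ga.hydrophobic_atoms), _group_coords(gb.hydrophobic_atoms))
    if d <= cutoffs.hydrophobic:
        out.add(TypedContact(ida, idb, "hydrophobic", d, source))

    classes = (classify_residue(res_a.name), classify_residue(res_b.name))
    if set(classes) == {"negative", "positive"}:
        d = _min_distance(_group_coords(ga.ionizable_atoms), _group_coords(gb.ionizable_atoms))
        if d <= cutoffs.ionic:
            out.add(TypedContact(ida, idb, "ionic", d, source))

    d = _hbond_distance(ga, gb, cutoffs)
    if d is not None:
        out.add(TypedContact(ida, idb, "hbond", d, source))

    best_cpi = None
    for cations, ring in ((ga.cation_centers, gb.ring_centroid),
                          (gb.cation_centers, ga.ring_centroid)):
        if ring is None:
            continue
        for center in cations:
            d = float(np.linalg.norm(center - ring))
            if d <= cutoffs.cation_pi and (best_cpi is None or d < best_cpi):
                best_cpi = d
    if best_cpi is not None:
        out.add(TypedContact(ida, idb, "cation_pi", best_cpi, source))

    return out


def _contact_sort_key(c: TypedContact) -> tuple:
    return (c.res_a.chain, c.res_a.seq, c.res_a.icode,
            c.res_b.chain, c.res_b.seq, c.res_b.icode, c.type)


def build_contact_map(side_a: ResidueSet, side_b: ResidueSet,
                      cutoffs: InteractionCutoffs | None = None,
                      dna: ResidueSet | None = None,
                      source: str = "") -> ContactMap:
    """Evaluate all cross-pairs between two disjoint residue sets.

    Non-protein residues in either side contribute no typed contacts but
    still receive a DNA flag.  ``dna_flags[res] = True`` iff any heavy
    atom of the residue lies within the DNA-contact cutoff of any heavy
    atom of the ``dna`` set.
    """
    cutoffs = cutoffs or InteractionCutoffs()
    keys_a, keys_b = set(side_a.keys), set(side_b.keys)
    overlap = keys_a & keys_b
    if overlap:
        raise ValueError(f"sides overlap on residues {sorted(overlap)}")

    groups: dict[int, ChemGroups] = {}

    def groups_of(res: Residue) -> ChemGroups:
        key = id(res)
        if key not in groups:
            groups[key] = chem_groups(res)
        return groups[key]

    contacts: dict[tuple, TypedContact] = {}
    for ra in side_a:
        if ra.kind != "protein":
            continue
        for rb in side_b:
            if rb.kind != "protein":
                continue
            for contact in _detect(ra, rb, groups_of(ra), groups_of(rb),
                                   cutoffs, source):
                prev = contacts.get(contact.pair_key)
                if prev is None or contact.distance < prev.distance:
                    contacts[contact.pair_key] = contact

    dna_coords = None
    if dna is not None and len(dna) > 0:
        dna_coords = np.vstack([r.coords() for r in dna])
    flags: dict[tuple[str, int, str], bool] = {}
    for res in list(side_a) + list(side_b):
        if dna_coords is None:
            flags[res.key] = False
        else:
            flags[res.key] = _min_distance(res.coords(), dna_coords) <= cutoffs.dna_contact

    ordered = tuple(sorted(contacts.values(), key=_contact_sort_key))
    return ContactMap(ordered, side_a, side_b, flags, source, cutoffs)


@dataclass
class SideSummary:
    n_contacts: int
    n_contacting_residues: int
    class_counts: dict[str, int]
    hydrophobic_fraction: float
    label: str | None


def interface_character(cmap: ContactMap) -> dict[str, SideSummary]:
    """Per-side interface character: contacting-residue class counts and
    the fraction of contacts that are hydrophobic-type.

    A side is labelled ``"predominantly hydrophobic"`` iff more than half
    of its contacts are hydrophobic-type.
    """
    out = {}
    for side_name, getter in (("a", lambda c: c.res_a), ("b", lambda c: c.res_b)):
        residues = {getter(c) for c in cmap.contacts}
        counts = Counter(classify_residue(r.name) for r in residues)
        n = len(cmap.contacts)
        n_hydro = sum(1 for c in cmap.contacts if c.type == "hydrophobic")
        frac = n_hydro / n if n else 0.0
        label = "predominantly hydrophobic" if n and n_hydro > n / 2 else None
        out[side_name] = SideSummary(n, len(residues), dict(counts), frac, label)
    return out


def _check_injective(mapping: dict) -> None:
    values = list(mapping.values())
    if len(set(values)) != len(values):
        raise ValueError("residue mapping is not one-to-one")


def compare_maps(map_a: ContactMap, map_b: ContactMap,
                 mapping: dict[tuple[str, int, str], tuple[str, int, str]]) -> ComparativeMap:
    """Partition two contact maps into shared and structure-specific contacts.

    A contact of the first map is *shared* iff a contact with the same
    mapped residue pair and the same interaction type exists in the
    second map (distances are ignored).  Contacts on unmapped residues
    are structure-specific by definition.
    """
    _check_injective(mapping)

    def translated_key(contact: TypedContact):
        ka = mapping.get(contact.res_a.key)
        kb = mapping.get(contact.res_b.key)
        if ka is None or kb is None:
            return None
        return (frozenset((ka, kb)), contact.type)

    b_index: dict[tuple, TypedContact] = {}
    for cb in map_b.contacts:
        b_index[(frozenset((cb.res_a.key, cb.res_b.key)), cb.type)] = cb

    shared, only_a = [], []
    matched_b_keys = set()
    for ca in map_a.contacts:
        key = translated_key(ca)
        if key is not None and key in b_index:
            shared.append((ca, b_index[key]))
            matched_b_keys.add(key)
        else:
            only_a.append(ca)
    only_b = [cb for cb in map_b.contacts
              if (frozenset((cb.res_a.key, cb.res_b.key)), cb.type) not in matched_b_keys]

    return ComparativeMap(tuple(shared), tuple(only_a), tuple(only_b), dict(mapping))


def mapping_from_alignment(side_a: ResidueSet, side_b: ResidueSet
                           ) -> dict[tuple[str, int, str], tuple[str, int, str]]:
    """Build a residue mapping from the best ungapped alignment of two
    residue sets' one-letter sequences (identity scoring, ties to the
    smallest offset).  Convenience for homologous chains with different
    author numbering."""
    short, long_, swapped = (side_a, side_b, False)
    if len(side_a) > len(side_b):
        short, long_, swapped = side_b, side_a, True
    s, t = short.sequence(), long_.sequence()
    best_offset, best_score = 0, -1
    for off in range(len(t) - len(s) + 1):
        score = sum(1 for i, ch in enumerate(s) if t[off + i] == ch)
        if score > best_score:
            best_offset, best_score = off, score
    pairs = [(short.members[i].key, long_.members[best_offset + i].key)
             for i in range(len(s))]
    if swapped:
        pairs = [(b, a) for a, b in pairs]
    return dict(pairs)


_TSV_HEADER = ("structure_id\tchain_a\tseq_a\tresname_a\tchain_b\tseq_b\tresname_b"
               "\ttype\tdistance_angstrom\tdna_flag_a\tdna_flag_b")


def _contact_row(c: TypedContact, flags: dict, source: str) -> str:
    fa = int(flags.get(c.res_a.key, False))
    fb = int(flags.get(c.res_b.key, False))
    return (f"{source}\t{c.res_a.chain}\t{c.res_a.token}\t{c.res_a.name}"
            f"\t{c.res_b.chain}\t{c.res_b.token}\t{c.res_b.name}"
            f"\t{c.type}\t{c.distance:.3f}\t{fa}\t{fb}")


def write_contact_tsv(cmap: ContactMap) -> str:
    lines = [_TSV_HEADER]
    for c in cmap.contacts:
        lines.append(_contact_row(c, cmap.dna_flags, cmap.source or c.source))
    return "\n".join(lines) + "\n"


def write_comparative_tsv(comp: ComparativeMap) -> str:
    lines = [_TSV_HEADER + "\tmembership"]
    rows = []
    for contact, membership in comp.memberships():
        rows.append((_contact_sort_key(contact), membership,
                     _contact_row(contact, {}, contact.source) + f"\t{membership}"))
    order = {"both": 0, "a_only": 1, "b_only": 2}
    rows.sort(key=lambda r: (order[r[1]], r[0]))
    lines += [r[2] for r in rows]
    return "\n".join(lines) + "\n"
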