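"""Independent brute-force oracles used to cross-check the implementation.

These re-state the interaction rules from scratch: every atom pair is
enumerated and each rule applied literally, with their own residue
tables.  They intentionally share no code with the package beyond the
data classes they inspect.
"""

from __future__ import annotations

import math
from itertools import product

ORACLE_CLASS = {
    "GLY": "aliphatic", "ALA": "aliphatic", "VAL": "aliphatic",
    "LEU": "aliphatic", "ILE": "aliphatic", "MET": "aliphatic",
    "ASP": "negative", "GLU": "negative",
    "LYS": "positive", "ARG": "positive", "HIS": "positive",
    "SER": "polar", "THR": "polar", "ASN": "polar", "GLN": "polar", "CYS": "polar",
    "PHE": "aromatic", "TRP": "aromatic", "TYR": "aromatic",
    "PRO": "proline",
}

_BACKBONE = {"N", "CA", "C", "O", "OXT"}

_DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "TRP": {"NE1"},
}
_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"},
}
_IONIZABLE = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "LYS": {"NZ"}, "ARG": {"NE", "CZ", "NH1", "NH2"}, "HIS": {"ND1", "CE1", "NE2"},
}
_RINGS = {
    "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TRP": ["CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ2", "CZ3", "CH2"],
    "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
}


def _dist(p, q):
    return math.dist(p, q)


def _centroid(points):
    n = len(points)
    return tuple(sum(p[i] for p in points) / n for i in range(3))


def _cation_centers(res):
    coords = {a.name: a.coord for a in res.atoms}
    if res.name == "LYS" and "NZ" in coords:
        return [coords["NZ"]]
    if res.name == "ARG":
        pts = [coords[n] for n in ("NE", "CZ", "NH1", "NH2") if n in coords]
        return [_centroid(pts)] if pts else []
    if res.name == "HIS":
        pts = [coords[n] for n in _RINGS["HIS"] if n in coords]
        return [_centroid(pts)] if pts else []
    return []


def _ring_centroid(res):
    names = _RINGS.get(res.name)
    if not names:
        return None
    coords = {a.name: a.coord for a in res.atoms}
    pts = [coords[n] for n in names if n in coords]
    return _centroid(pts) if pts else None


def brute_force_pair(res_a, res_b, hydrophobic=5.0, ionic=6.0, cation_pi=6.0,
                     hbond_no=3.5, hbond_s=4.0, sulfur_acceptor_extends=True):
    """All interaction types of one residue pair, by literal enumeration.

    Returns a dict type -> minimal qualifying distance.
    """
    out = {}

    def side_chain_carbons(res):
        atoms = [a for a in res.atoms
                 if a.name not in _BACKBONE and a.element == "C"]
        if res.name == "MET":
            atoms += [a for a in res.atoms if a.name == "SD"]
        return atoms

    best = None
    for a, b in product(side_chain_carbons(res_a), side_chain_carbons(res_b)):
        d = _dist(a.coord, b.coord)
        if d <= hydrophobic and (best is None or d < best):
            best = d
    if best is not None:
        out["hydrophobic"] = best

    pair_classes = {ORACLE_CLASS[res_a.name], ORACLE_CLASS[res_b.name]}
    if pair_classes == {"negative", "positive"}:
        best = None
        ion_a = [a for a in res_a.atoms if a.name in _IONIZABLE.get(res_a.name, ())]
        ion_b = [a for a in res_b.atoms if a.name in _IONIZABLE.get(res_b.name, ())]
        for a, b in product(ion_a, ion_b):
            d = _dist(a.coord, b.coord)
            if d <= ionic and (best is None or d < best):
                best = d
        if best is not None:
            out["ionic"] = best

    def donors(res):
        atoms = [a for a in res.atoms if a.name == "N"]
        atoms += [a for a in res.atoms if a.name in _DONORS.get(res.name, ())]
        return atoms

    def acceptors(res):
        atoms = [a for a in res.atoms if a.name == "O"]
        atoms += [a for a in res.atoms if a.name in _ACCEPTORS.get(res.name, ())]
        return atoms

    best = None
    for don_res, acc_res in ((res_a, res_b), (res_b, res_a)):
        for d_at, a_at in product(donors(don_res), acceptors(acc_res)):
            sulfur = d_at.element == "S" or \
                (sulfur_acceptor_extends and a_at.element == "S")
            limit = hbond_s if sulfur else hbond_no
            d = _dist(d_at.coord, a_at.coord)
            if d <= limit and (best is None or d < best):
                best = d
    if best is not None:
        out["hbond"] = best

    best = None
    for cat_res, ring_res in ((res_a, res_b), (res_b, res_a)):
        ring = _ring_centroid(ring_res)
        if ring is None:
            continue
        for center in _cation_centers(cat_res):
            d = _dist(center, ring)
            if d <= cation_pi and (best is None or d < best):
                best = d
    if best is not None:
        out["cation_pi"] = best

    return out


def brute_force_map(side_a, side_b, **cutoffs):
    """type-resolved contacts over all cross pairs: {(key_a, key_b, type): distance}."""
    out = {}
    for ra in side_a:
        if ra.kind != "protein":
            continue
        for rb in side_b:
            if rb.kind != "protein":
                continue
            for typ, dist in brute_force_pair(ra, rb, **cutoffs).items():
                out[(ra.key, rb.key, typ)] = dist
    return out


def naive_scan(pattern_positions, seq):
    """Position-by-position motif scan oracle: list of 1-based starts."""
    hits = []
    m = len(pattern_positions)
    for start in range(len(seq) - m + 1):
        ok = True
        for i, pos in enumerate(pattern_positions):
            ch = seq[start + i]
            if pos is None:
                continue
            if ch not in pos:
                ok = False
                break
        if ok:
            hits.append(start + 1)
    return hits
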