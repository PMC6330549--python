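import numpy as np
import pytest

from nfymap.contact_map import (ContactMap, InteractionCutoffs,
                                build_contact_map, compare_maps,
                                detect_contact_types, interface_character,
                                mapping_from_alignment, write_contact_tsv)
from nfymap.structure_io import Atom, Residue, ResidueSet, parse_pdb, select
from nfymap.synthetic_data import make_random_interface

from conftest import build_maps
from oracles import brute_force_map


def _residue(name, chain, seq, atom_coords):
    atoms = [Atom(n, n.lstrip("0123456789'")[0], tuple(c))
             for n, c in atom_coords.items()]
    return Residue(chain, seq, "", name, "protein", atoms)


def _lys_glu_pair(separation):
    lys = _residue("LYS", "A", 1, {"N": (-10, 0, 0), "CA": (-9, 0, 0),
                                   "NZ": (0.0, 0.0, 0.0)})
    glu = _residue("GLU", "B", 1, {"N": (separation + 10, 0, 0),
                                   "CA": (separation + 9, 0, 0),
                                   "OE1": (separation, 0.0, 0.0),
                                   "OE2": (separation + 1.0, 1.0, 0.0)})
    return lys, glu


def test_salt_bridge_detected_at_5_5_angstrom():
    contacts = detect_contact_types(*_lys_glu_pair(5.5))
    assert {c.type for c in contacts} == {"ionic"}
    (contact,) = contacts
    assert contact.distance == pytest.approx(5.5)


def test_salt_bridge_beyond_cutoff_is_empty():
    assert detect_contact_types(*_lys_glu_pair(6.5)) == set()


@pytest.mark.parametrize("d, expected", [(3.4, {"hbond"}), (3.8, set())])
def test_hbond_distance_rule_for_on_donors(d, expected):
    ser = _residue("SER", "A", 1, {"N": (-10, 0, 0), "CA": (-9, 0, 0),
                                   "OG": (0.0, 0.0, 0.0)})
    asp = _residue("ASP", "B", 1, {"N": (d + 10, 0, 0), "CA": (d + 9, 0, 0),
                                   "OD1": (d, 0.0, 0.0)})
    contacts = detect_contact_types(ser, asp)
    assert {c.type for c in contacts} == expected
    if expected:
        assert next(iter(contacts)).distance == pytest.approx(d)


def test_sulfur_donor_uses_4A_cutoff():
    cys = _residue("CYS", "A", 1, {"N": (-10, 0, 0), "SG": (0.0, 0.0, 0.0)})
    asp = _residue("ASP", "B", 1, {"N": (13.8, 0, 0), "OD1": (3.8, 0.0, 0.0)})
    assert {c.type for c in detect_contact_types(cys, asp)} == {"hbond"}
    # the same geometry with an oxygen donor is beyond the 3.5 A limit
    ser = _residue("SER", "A", 1, {"N": (-10, 0, 0), "OG": (0.0, 0.0, 0.0)})
    assert detect_contact_types(ser, asp) == set()


def test_non_protein_rejected():
    dna = Residue("D", 1, "", "DA", "nucleic", [Atom("P", "P", (0, 0, 0))])
    ser = _residue("SER", "A", 1, {"OG": (0, 0, 0)})
    with pytest.raises(ValueError):
        detect_contact_types(ser, dna)


def test_planted_contacts_recovered_exactly(toy_map):
    cmap, truth = toy_map
    got = {(c.res_a.key, c.res_b.key, c.type, round(c.distance, 3))
           for c in cmap.contacts}
    want = {(c.res_a.key, c.res_b.key, c.type, round(c.distance, 3))
            for c in truth.contacts}
    assert got == want


def test_dna_flags_match_truth(toy_map):
    cmap, truth = toy_map
    assert cmap.dna_flags == truth.dna_flags
    assert sum(cmap.dna_flags.values()) == 1


def test_empty_dna_set_flags_all_false(toy_fixture):
    structure, _ = toy_fixture
    cmap = build_contact_map(select(structure, "A", "all"),
                             select(structure, "B", "all"))
    assert not any(cmap.dna_flags.values())


def test_symmetry_under_side_swap(toy_fixture):
    structure, _ = toy_fixture
    a, b = select(structure, "A", "all"), select(structure, "B", "all")
    forward = build_contact_map(a, b)
    backward = build_contact_map(b, a)
    fwd = {(c.res_a.key, c.res_b.key, c.type) for c in forward.contacts}
    bwd = {(c.res_b.key, c.res_a.key, c.type) for c in backward.contacts}
    assert fwd == bwd


def test_overlapping_sides_rejected(toy_fixture):
    structure, _ = toy_fixture
    a = select(structure, "A", "all")
    with pytest.raises(ValueError, match="overlap"):
        build_contact_map(a, a)


def test_monotone_in_cutoffs(toy_fixture):
    structure, _ = toy_fixture
    a, b = select(structure, "A", "all"), select(structure, "B", "all")
    base = build_contact_map(a, b)
    base_keys = {(c.res_a.key, c.res_b.key, c.type) for c in base.contacts}
    rng = np.random.default_rng(0)
    for _ in range(25):
        grown = InteractionCutoffs(
            hydrophobic=5.0 + rng.uniform(0, 3),
            ionic=6.0 + rng.uniform(0, 3),
            cation_pi=6.0 + rng.uniform(0, 3),
            hbond_NO_donor=3.5 + rng.uniform(0, 2),
            hbond_S_donor=4.0 + rng.uniform(0, 2),
        )
        bigger = build_contact_map(a, b, grown)
        keys = {(c.res_a.key, c.res_b.key, c.type) for c in bigger.contacts}
        assert base_keys <= keys


def test_matches_brute_force_on_random_structures():
    for seed in range(20):
        structure = make_random_interface(4, 4, seed=seed)
        a, b = select(structure, "A", "all"), select(structure, "B", "all")
        cmap = build_contact_map(a, b)
        got = {(c.res_a.key, c.res_b.key, c.type): c.distance
               for c in cmap.contacts}
        want = brute_force_map(a, b)
        assert got.keys() == want.keys()
        for key in got:
            assert got[key] == pytest.approx(want[key])


def test_interface_character_fractions(toy_map):
    cmap, _ = toy_map
    summary = interface_character(cmap)
    for side in ("a", "b"):
        assert summary[side].n_contacts == 6
        assert summary[side].hydrophobic_fraction == pytest.approx(2 / 6)
        assert summary[side].label is None
    # restrict to the hydrophobic contacts only: fraction 1.0 and labelled
    hydro = ContactMap(tuple(c for c in cmap.contacts if c.type == "hydrophobic"),
                       cmap.side_a, cmap.side_b, cmap.dna_flags)
    only = interface_character(hydro)
    assert only["a"].hydrophobic_fraction == 1.0
    assert only["a"].label == "predominantly hydrophobic"
    empty = ContactMap((), cmap.side_a, cmap.side_b, cmap.dna_flags)
    zeros = interface_character(empty)
    assert zeros["a"].n_contacts == 0 and zeros["a"].class_counts == {}
    assert zeros["a"].label is None


def test_compare_identity(toy_map):
    cmap, _ = toy_map
    mapping = {k: k for k in cmap.side_a.keys + cmap.side_b.keys}
    comp = compare_maps(cmap, cmap, mapping)
    assert comp.only_a == () and comp.only_b == ()
    assert len(comp.shared) == len(cmap.contacts)


def test_compare_missing_contact_goes_to_only_a(toy_map):
    cmap, _ = toy_map
    reduced = ContactMap(cmap.contacts[1:], cmap.side_a, cmap.side_b,
                         cmap.dna_flags)
    mapping = {k: k for k in cmap.side_a.keys + cmap.side_b.keys}
    comp = compare_maps(cmap, reduced, mapping)
    assert [c.pair_key for c in comp.only_a] == [cmap.contacts[0].pair_key]
    assert len(comp.shared) + len(comp.only_a) == len(cmap.contacts)
    assert len(comp.shared) + len(comp.only_b) == len(reduced.contacts)


def test_paired_fixture_partition_matches_truth(paired_fixture):
    map_a, map_b = build_maps(paired_fixture)
    comp = compare_maps(map_a, map_b, paired_fixture.mapping)
    def keyset(contacts):
        return {(c.res_a.key, c.res_b.key, c.type) for c in contacts}
    truth_a = keyset(paired_fixture.truth_a.contacts)
    truth_b = keyset(paired_fixture.truth_b.contacts)
    assert keyset(c for c, _ in comp.shared) == truth_a & truth_b
    assert keyset(comp.only_a) == truth_a - truth_b
    assert keyset(comp.only_b) == truth_b - truth_a
    assert len(comp.shared) + len(comp.only_a) == len(map_a.contacts)
    assert len(comp.shared) + len(comp.only_b) == len(map_b.contacts)


def test_non_injective_mapping_rejected(toy_map):
    cmap, _ = toy_map
    keys = cmap.side_a.keys
    mapping = {keys[0]: ("B", 1, ""), keys[1]: ("B", 1, "")}
    with pytest.raises(ValueError, match="one-to-one"):
        compare_maps(cmap, cmap, mapping)


def test_mapping_from_ungapped_alignment():
    lines = []
    seqs = {"A": [("GLY", i) for i in range(1, 6)],
            "B": [("GLY", i) for i in range(41, 46)]}
    serial = 0
    for chain, residues in seqs.items():
        for name, seq in residues:
            serial += 1
            lines.append(f"ATOM  {serial:>5d}  CA  {name} {chain}{seq:>4d}    "
                         f"{float(seq):8.3f}{0.0:8.3f}{0.0:8.3f}{1.0:6.2f}  0.00"
                         f"           C")
    structure = parse_pdb("\n".join(lines))
    mapping = mapping_from_alignment(select(structure, "A", "all"),
                                     select(structure, "B", "all"))
    assert mapping[("A", 1, "")] == ("B", 41, "")
    assert mapping[("A", 5, "")] == ("B", 45, "")


def test_contact_tsv_has_stated_columns(toy_map):
    cmap, _ = toy_map
    text = write_contact_tsv(cmap)
    header = text.splitlines()[0].split("\t")
    assert header == ["structure_id", "chain_a", "seq_a", "resname_a",
                      "chain_b", "seq_b", "resname_b", "type",
                      "distance_angstrom", "dna_flag_a", "dna_flag_b"]
    assert len(text.splitlines()) == 1 + len(cmap.contacts)
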