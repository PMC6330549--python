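import pytest
from hypothesis import given
from hypothesis import strategies as st

from nfymap.motif import (AlignmentBlock, PatternError, SequenceRecord,
                          align_segment, derive_consensus, parse_pattern,
                          read_fasta, scan_database, scan_sequence, write_fasta)
from nfymap.residue_chemistry import classify_letter
from nfymap.synthetic_data import make_motif_db

from oracles import naive_scan

AA = "ACDEFGHIKLMNPQRSTVWY"

CONSENSUS_1 = "R[E/D]Q[D/E]-[Y/F/W][L/V]"
CONSENSUS_2 = "[V/I]-R[L/I]M[K/R]-[I/V/L]"


def test_parse_consensus_motif_1():
    pattern = parse_pattern(CONSENSUS_1)
    assert len(pattern) == 7
    assert pattern.positions == (("R",), ("E", "D"), ("Q",), ("D", "E"),
                                 None, ("Y", "F", "W"), ("L", "V"))
    assert pattern.text == CONSENSUS_1


def test_parse_single_letter_pattern():
    pattern = parse_pattern("A")
    assert pattern.positions == (("A",),)


@pytest.mark.parametrize("bad", ["[A/]", "[A", "A]4", "", "[A]", "[A/A]", "a"])
def test_malformed_patterns_rejected(bad):
    with pytest.raises(PatternError):
        parse_pattern(bad)


@st.composite
def patterns(draw):
    positions = draw(st.lists(
        st.one_of(
            st.none(),
            st.lists(st.sampled_from(AA), min_size=1, max_size=4,
                     unique=True).map(tuple)),
        min_size=1, max_size=8))
    return "".join(
        "-" if p is None else (p[0] if len(p) == 1 else "[" + "/".join(p) + "]")
        for p in positions)


@given(patterns())
def test_parse_render_roundtrip(text):
    assert parse_pattern(text).text == text


def test_derive_consensus_from_two_rows():
    block = AlignmentBlock(("REQEIYV", "RDQDAWL"))
    pattern = derive_consensus(block, max_alternatives=3)
    # two-row columns tie in frequency, so alternatives order alphabetically
    assert pattern.text == "R[D/E]Q[D/E][A/I][W/Y][L/V]"
    narrow = derive_consensus(block, max_alternatives=1)
    assert narrow.text == "R-Q----"  # 7 columns, 5 degenerate
    for row in block.rows:
        assert pattern.matches_at(row, 0)


def test_identical_rows_give_fixed_pattern():
    block = AlignmentBlock(("REQ", "REQ"))
    assert derive_consensus(block).text == "REQ"


def test_too_many_alternatives_become_wildcard():
    block = AlignmentBlock(("A", "C", "D", "E"))
    assert derive_consensus(block, max_alternatives=3).text == "-"


def test_single_row_block_rejected():
    with pytest.raises(ValueError):
        AlignmentBlock(("REQ",))


@given(st.lists(st.text(alphabet=AA, min_size=5, max_size=5),
                min_size=2, max_size=6))
def test_consensus_matches_every_input_row(rows):
    block = AlignmentBlock(tuple(rows))
    pattern = derive_consensus(block)
    for row in rows:
        assert pattern.matches_at(row, 0)


def test_scan_motif_in_its_source_peptide():
    hits = scan_sequence(parse_pattern(CONSENSUS_1), SequenceRecord("qqs", "REQEIYV"))
    assert [(h.start, h.match) for h in hits] == [(1, "REQEIYV")]


def test_scan_no_hits_in_poly_alanine():
    assert scan_sequence(parse_pattern(CONSENSUS_1),
                         SequenceRecord("a7", "AAAAAAA")) == []


def test_overlapping_hits_all_reported():
    hits = scan_sequence(parse_pattern("AA"), SequenceRecord("a4", "AAAA"))
    assert [h.start for h in hits] == [1, 2, 3]


def test_wildcard_matches_x_but_sets_do_not():
    assert scan_sequence(parse_pattern("-A"), SequenceRecord("r", "XA"))
    assert not scan_sequence(parse_pattern("AA"), SequenceRecord("r", "XA"))
    assert not scan_sequence(parse_pattern("[A/C]A"), SequenceRecord("r", "XA"))


@given(st.text(alphabet=AA + "X", min_size=1, max_size=60), patterns(),
       st.integers(0, 100))
def test_scan_equals_naive_oracle(seq, pattern_text, _salt):
    pattern = parse_pattern(pattern_text)
    record = SequenceRecord("r", seq)
    got = [h.start for h in scan_sequence(pattern, record)]
    assert got == naive_scan(pattern.positions, seq)


def test_database_scan_respects_exclusions():
    query = parse_pattern(CONSENSUS_1)
    exclusion = parse_pattern("[K/R][K/R][K/R]A")
    fasta, truth = make_motif_db(10, [(query, 4)], exclusion_pattern=exclusion,
                                 exclusion_tagged=1, seed=3)
    import io
    hits = scan_database(query, io.StringIO(fasta), [exclusion])
    assert tuple(hits) == truth.expected_hits
    assert len({h.record_id for h in hits}) == 3
    # exclusion list monotonicity: more exclusions never add hits
    unfiltered = scan_database(query, truth.records, [])
    assert len(unfiltered) >= len(hits)


def test_both_consensus_patterns_absent_from_unrelated_record():
    record = SequenceRecord("r", "GGGGGGGGGGGGGGGGGGGG")
    for text in (CONSENSUS_1, CONSENSUS_2):
        assert scan_sequence(parse_pattern(text), record) == []


def test_align_identity_substring():
    alignment = align_segment(SequenceRecord("p", "DEF"),
                              SequenceRecord("t", "ACDEFGH"))
    assert alignment.target_start == 3
    assert alignment.labels == ("identity",) * 3
    assert alignment.score == 6


def test_align_class_aware_hand_scored():
    # vs RDQDAWL: R=R identity(2), E~D class(1), Q=Q(2), E~D(1),
    # I~A aliphatic(1), Y~W aromatic(1), V~L aliphatic(1) -> 9
    peptide = SequenceRecord("qqs5_11", "REQEIYV")
    target = SequenceRecord("nfyb", "GGGGRDQDAWLGGGG")
    alignment = align_segment(peptide, target, class_aware=True)
    hand_scores = []
    for off in range(len(target.seq) - 7 + 1):
        s = 0
        for i, p in enumerate(peptide.seq):
            t = target.seq[off + i]
            if p == t:
                s += 2
            elif classify_letter(p) == classify_letter(t):
                s += 1
        hand_scores.append(s)
    assert alignment.score == max(hand_scores) == 9
    assert alignment.offset == hand_scores.index(max(hand_scores)) == 4
    assert alignment.labels == ("identity", "class", "identity", "class",
                                "class", "class", "class")


def test_align_tie_prefers_smallest_offset():
    alignment = align_segment(SequenceRecord("p", "AA"),
                              SequenceRecord("t", "AAAA"))
    assert alignment.offset == 0


def test_align_empty_sequence_rejected():
    with pytest.raises(ValueError):
        align_segment(SequenceRecord("p", ""), SequenceRecord("t", "AAA"))


def test_fasta_roundtrip(tmp_path):
    records = [SequenceRecord("r1", "ACDE" * 30, "long record"),
               SequenceRecord("r2", "WWWW")]
    path = tmp_path / "db.fasta"
    text = write_fasta(records, path)
    assert max(len(l) for l in text.splitlines()) <= 61  # 60-column wrap
    back = read_fasta(path)
    assert [(r.id, r.seq) for r in back] == [(r.id, r.seq) for r in records]


def test_invalid_fasta_letters_name_the_record(tmp_path):
    path = tmp_path / "bad.fasta"
    path.write_text(">weird\nACDB1\n")
    with pytest.raises(ValueError, match="weird"):
        read_fasta(path)
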